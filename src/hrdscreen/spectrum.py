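"""SBS96 mutational spectra and cosine similarity to reference signatures.

Single-base substitutions are classified into the standard 96 channels:
six pyrimidine-centred substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases. Substitutions
reported on the purine strand are reverse-complemented into the pyrimidine
convention. Channel order is substitution-class major, then 5' flank, then
3' flank, each in A, C, G, T order — the same order as the packaged
signature file.

The similarity statistic is the plain cosine between a sample's raw
96-channel count vector and a reference signature's probability vector;
no per-channel normalisation is applied by default, but a weighting hook
is exposed on :func:`cosine_to_signature`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import packaged_data_path

logger = logging.getLogger(__name__)

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)
CHANNEL_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(CHANNELS)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SYNTHETIC_SIGNATURES_FILE = "synthetic_v2_style_signatures.tsv"


class SpectrumError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SnvRecord:
    """One single-nucleotide variant with an optional trinucleotide context."""

    sample_id: str
    chromosome: str
    position: int
    ref_base: str
    alt_base: str
    context: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise SpectrumError(
                f"{self.sample_id} {self.chromosome}:{self.position}: ref equals alt"
            )
        for base in (self.ref_base, self.alt_base):
            if base not in _BASES:
                raise SpectrumError(
                    f"{self.sample_id} {self.chromosome}:{self.position}: "
                    f"invalid base {base!r}"
                )
        if self.context is not None:
            if len(self.context) != 3 or any(b not in _BASES for b in self.context):
                raise SpectrumError(
                    f"{self.sample_id} {self.chromosome}:{self.position}: "
                    f"invalid 3-mer context {self.context!r}"
                )
            if self.context[1] != self.ref_base:
                raise SpectrumError(
                    f"{self.sample_id} {self.chromosome}:{self.position}: context "
                    f"middle base {self.context[1]!r} != ref {self.ref_base!r}"
                )


@dataclass(frozen=True)
class SBS96Spectrum:
    """96-channel substitution count vector for one sample."""

    sample_id: str
    counts: np.ndarray  # shape (96,), non-negative integers

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (96,):
            raise SpectrumError(f"spectrum must have 96 channels, got {arr.shape}")
        if (arr < 0).any():
            raise SpectrumError("negative channel count")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n_snvs(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name=self.sample_id)


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map an SNV to its pyrimidine-centred channel label."""
    if ref in "AG":  # purine strand: flip onto the pyrimidine strand
        context = revcomp(context)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def _context_from_fasta(fasta, record: SnvRecord) -> str:
    try:
        seq = fasta[record.chromosome][record.position - 2 : record.position + 1]
    except KeyError as exc:
        raise SpectrumError(
            f"{record.sample_id} {record.chromosome}:{record.position}: "
            f"chromosome not in FASTA"
        ) from exc
    ctx = str(seq).upper()
    if len(ctx) != 3:
        raise SpectrumError(
            f"{record.sample_id} {record.chromosome}:{record.position}: "
            f"context unresolvable at sequence edge"
        )
    if ctx[1] != record.ref_base:
        raise SpectrumError(
            f"{record.sample_id} {record.chromosome}:{record.position}: FASTA base "
            f"{ctx[1]!r} != ref {record.ref_base!r}"
        )
    return ctx


def build_spectrum(
    snvs: Iterable[SnvRecord], fasta=None, sample_id: str | None = None
) -> SBS96Spectrum:
    """Accumulate SNVs of one sample into an SBS96 spectrum.

    Contexts come from the records themselves or, where absent, from an
    indexed FASTA (e.g. a ``pyfaidx.Fasta``). Counts are conserved: the
    spectrum total equals the number of SNVs consumed.
    """
    counts = np.zeros(96, dtype=np.int64)
    sid = sample_id
    for rec in snvs:
        if sid is None:
            sid = rec.sample_id
        elif rec.sample_id != sid:
            raise SpectrumError(
                f"mixed samples in one spectrum: {sid!r} vs {rec.sample_id!r}"
            )
        ctx = rec.context
        if ctx is None:
            if fasta is None:
                raise SpectrumError(
                    f"{rec.sample_id} {rec.chromosome}:{rec.position}: no context "
                    f"and no FASTA supplied"
                )
            ctx = _context_from_fasta(fasta, rec)
        counts[CHANNEL_INDEX[channel_of(rec.ref_base, rec.alt_base, ctx)]] += 1
    return SBS96Spectrum(sample_id=sid or "", counts=counts)


def read_snv_table(path) -> list[SnvRecord]:
    """Read a MAF-like SNV TSV (sample, chromosome, position, ref, alt,
    optional context). Non-SNV rows (multi-base or non-ACGT alleles) are
    skipped with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "chromosome", "position", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise SpectrumError(f"SNV table missing columns: {sorted(missing)}")
    records, skipped = [], 0
    has_context = "context" in df.columns
    for row in df.itertuples():
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            skipped += 1  # indel / MNV / symbolic allele
            continue
        ctx = getattr(row, "context", None) if has_context else None
        if isinstance(ctx, float):  # NaN from pandas
            ctx = None
        records.append(
            SnvRecord(
                sample_id=str(row.sample),
                chromosome=str(row.chromosome),
                position=int(row.position),
                ref_base=ref,
                alt_base=alt,
                context=str(ctx).upper() if ctx else None,
            )
        )
    if skipped:
        logger.info("skipped %d non-SNV rows", skipped)
    return records


def build_spectra(snvs: Iterable[SnvRecord], fasta=None) -> dict[str, SBS96Spectrum]:
    """Per-sample spectra for a multi-sample SNV collection."""
    by_sample: dict[str, list[SnvRecord]] = {}
    for rec in snvs:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    return {sid: build_spectrum(recs, fasta) for sid, recs in by_sample.items()}


class ReferenceSignatureSet:
    """Named 96-channel signature probability profiles."""

    def __init__(self, profiles: pd.DataFrame):
        if list(profiles.index) != list(CHANNELS):
            profiles = profiles.reindex(list(CHANNELS))
        if profiles.isna().any().any():
            raise SpectrumError("signature profiles missing channels")
        if (profiles.values < 0).any():
            raise SpectrumError("negative signature probability")
        sums = profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-6)].index.tolist()
            raise SpectrumError(f"signature profiles do not sum to 1: {bad}")
        self.profiles = profiles

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def profile(self, name: str) -> np.ndarray:
        if name not in self.profiles.columns:
            raise KeyError(f"unknown signature {name!r}; have {self.names}")
        return self.profiles[name].to_numpy()


def load_reference_signatures(path=None) -> ReferenceSignatureSet:
    """Load a reference signature TSV (Channel column + one column per
    signature). Defaults to the packaged synthetic stand-in catalog."""
    if path is None:
        path = packaged_data_path(SYNTHETIC_SIGNATURES_FILE).open("r")
    df = pd.read_csv(path, sep="\t", comment="#", index_col="Channel")
    return ReferenceSignatureSet(df)


def cosine_to_signature(
    spectrum: SBS96Spectrum,
    signatures: ReferenceSignatureSet,
    name: str = "Signature 3",
    channel_weights: Sequence[float] | None = None,
) -> float:
    """Cosine similarity between a spectrum and a named reference profile.

    Both vectors are non-negative, so the value lies in [0, 1]. An all-zero
    spectrum has no direction and raises; callers typically exclude such
    samples. ``channel_weights`` multiplies both vectors channel-wise before
    the cosine (e.g. for exome-coverage normalisation).
    """
    u = spectrum.counts.astype(float)
    if u.sum() == 0:
        raise SpectrumError(
            f"sample {spectrum.sample_id!r}: cosine undefined for an empty spectrum"
        )
    v = signatures.profile(name).astype(float)
    if channel_weights is not None:
        w = np.asarray(channel_weights, dtype=float)
        if w.shape != (96,) or (w < 0).any():
            raise SpectrumError("channel_weights must be 96 non-negative values")
        u, v = u * w, v * w
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def spectrum_report(
    spectra: Mapping[str, SBS96Spectrum],
    signatures: ReferenceSignatureSet | None = None,
    name: str = "Signature 3",
) -> pd.DataFrame:
    """Per-sample table (sample_id, n_snvs, signature3_cosine); samples with
    empty spectra get a missing cosine."""
    signatures = signatures or load_reference_signatures()
    rows = []
    for sid, spec in spectra.items():
        cos = (
            cosine_to_signature(spec, signatures, name) if spec.n_snvs > 0 else np.nan
        )
        rows.append({"sample_id": sid, "n_snvs": spec.n_snvs, "signature3_cosine": cos})
    return pd.DataFrame(rows, columns=["sample_id", "n_snvs", "signature3_cosine"])
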