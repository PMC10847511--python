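"""Chromosome arms and allele-specific copy-number segments.

Coordinates are **1-based and inclusive** throughout: a segment covering the
first megabase of a chromosome is ``start=1, end=1_000_000`` and has length
``end - start + 1``. Allele copy numbers are stored major-first (``a_cn >=
b_cn``); tables that list them the other way round are swapped on read with a
warning, so downstream loss-of-heterozygosity logic only ever inspects the
minor allele ``b_cn``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = [
    "SampleID",
    "Chromosome",
    "Start_position",
    "End_position",
    "total_cn",
    "A_cn",
    "B_cn",
]

ARM_COLUMNS = ["chrom", "length", "cen_start", "cen_end"]


class SegmentTableError(ValueError):
    """Malformed or inconsistent segment input."""


@dataclass(frozen=True)
class ChromosomeArmTable:
    """Chromosome lengths and centromere intervals.

    ``arms[chrom] = (length, cen_start, cen_end)`` with
    ``0 < cen_start < cen_end < length``.
    """

    arms: Mapping[str, tuple[int, int, int]]

    def __post_init__(self) -> None:
        for chrom, (length, cs, ce) in self.arms.items():
            if not (0 < cs < ce < length):
                raise SegmentTableError(
                    f"chromosome {chrom!r}: require 0 < cen_start < cen_end < length, "
                    f"got length={length}, cen_start={cs}, cen_end={ce}"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.arms)

    def length(self, chrom: str) -> int:
        return self.arms[chrom][0]

    def centromere(self, chrom: str) -> tuple[int, int]:
        _, cs, ce = self.arms[chrom]
        return cs, ce

    def arm_intervals(self, chrom: str) -> list[tuple[str, int, int]]:
        """The p and q arm intervals, 1-based inclusive, centromere excluded."""
        length, cs, ce = self.arms[chrom]
        return [("p", 1, cs), ("q", ce, length)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "length": l, "cen_start": cs, "cen_end": ce}
            for c, (l, cs, ce) in self.arms.items()
        ]
        return pd.DataFrame(rows, columns=ARM_COLUMNS)


@dataclass(frozen=True)
class AlleleSpecificSegment:
    """One contiguous interval with total/major/minor copy number."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    total_cn: int
    a_cn: int
    b_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SegmentTableError(
                f"{self.sample_id}/{self.chromosome}: start {self.start} > end {self.end}"
            )
        if min(self.total_cn, self.a_cn, self.b_cn) < 0:
            raise SegmentTableError(
                f"{self.sample_id}/{self.chromosome}:{self.start}: negative copy number"
            )
        if self.a_cn < self.b_cn:
            raise SegmentTableError(
                f"{self.sample_id}/{self.chromosome}:{self.start}: "
                f"A_cn {self.a_cn} < B_cn {self.b_cn} (major/minor order violated)"
            )
        if self.a_cn + self.b_cn != self.total_cn:
            raise SegmentTableError(
                f"{self.sample_id}/{self.chromosome}:{self.start}: "
                f"A_cn + B_cn = {self.a_cn + self.b_cn} != total_cn {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int]:
        """Copy-number state used for smoothing/fusion: (total_cn, b_cn)."""
        return (self.total_cn, self.b_cn)

    @property
    def imbalanced(self) -> bool:
        return self.a_cn != self.b_cn


@dataclass(frozen=True)
class SegmentProfile:
    """All segments of one sample, sorted by (chromosome order, start)."""

    sample_id: str
    segments: tuple[AlleleSpecificSegment, ...]
    ploidy: float

    def chromosome_segments(self, chrom: str) -> list[AlleleSpecificSegment]:
        return [s for s in self.segments if s.chromosome == chrom]


def toy_genome() -> ChromosomeArmTable:
    """Packaged deterministic test genome: 3 chromosomes of 100 Mb,
    centromere at 45-55 Mb."""
    return ChromosomeArmTable(
        {f"chr{i}": (100_000_000, 45_000_000, 55_000_000) for i in (1, 2, 3)}
    )


def load_arm_table(path) -> ChromosomeArmTable:
    """Read an arm table TSV with columns chrom, length, cen_start, cen_end."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ARM_COLUMNS) - set(df.columns)
    if missing:
        raise SegmentTableError(f"arm table missing columns: {sorted(missing)}")
    if df["chrom"].duplicated().any():
        dupes = df.loc[df["chrom"].duplicated(), "chrom"].tolist()
        raise SegmentTableError(f"duplicate chromosome labels in arm table: {dupes}")
    return ChromosomeArmTable(
        {
            str(r.chrom): (int(r.length), int(r.cen_start), int(r.cen_end))
            for r in df.itertuples()
        }
    )


def grch37_arms() -> ChromosomeArmTable:
    """The packaged GRCh37-style arm table (convenience only; any build works)."""
    from .config import packaged_data_path

    with packaged_data_path("grch37_arms.tsv").open("r") as fh:
        return load_arm_table(fh)


def _length_weighted_ploidy(segments: Iterable[AlleleSpecificSegment]) -> float:
    total = 0
    weighted = 0
    for seg in segments:
        total += seg.length
        weighted += seg.length * seg.total_cn
    return weighted / total if total else float("nan")


def build_profile(
    sample_id: str,
    segments: Iterable[AlleleSpecificSegment],
    arms: ChromosomeArmTable,
    ploidy: float | None = None,
) -> SegmentProfile:
    """Validate, sort and wrap segments into a profile.

    Checks chromosome membership in ``arms``, bounds, and per-chromosome
    non-overlap. Ploidy defaults to the length-weighted mean total copy number.
    """
    order = {c: i for i, c in enumerate(arms.chromosomes)}
    segs = sorted(segments, key=lambda s: (order.get(s.chromosome, -1), s.start))
    for seg in segs:
        if seg.chromosome not in order:
            raise SegmentTableError(
                f"sample {sample_id}: chromosome {seg.chromosome!r} absent from arm table"
            )
        if seg.end > arms.length(seg.chromosome):
            raise SegmentTableError(
                f"sample {sample_id}: segment {seg.chromosome}:{seg.start}-{seg.end} "
                f"exceeds chromosome length {arms.length(seg.chromosome)}"
            )
        if seg.sample_id != sample_id:
            raise SegmentTableError(
                f"segment sample {seg.sample_id!r} does not match profile {sample_id!r}"
            )
    for prev, cur in zip(segs, segs[1:]):
        if prev.chromosome == cur.chromosome and cur.start <= prev.end:
            raise SegmentTableError(
                f"sample {sample_id}: overlapping segments on {cur.chromosome}: "
                f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
            )
    if ploidy is None:
        ploidy = _length_weighted_ploidy(segs)
    return SegmentProfile(sample_id=sample_id, segments=tuple(segs), ploidy=ploidy)


def read_segment_table(path, arms: ChromosomeArmTable) -> list[SegmentProfile]:
    """Read a scarHRD-style allele-specific segment TSV into validated profiles.

    Expected columns: SampleID, Chromosome, Start_position, End_position,
    total_cn, A_cn, B_cn (header required). Rows with A_cn < B_cn are swapped
    into major/minor order with a warning. Returns one profile per sample, in
    first-appearance order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SampleID": str, "Chromosome": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SegmentTableError(f"segment table missing columns: {sorted(missing)}")
    if df.empty:
        return []
    for col in ("Start_position", "End_position", "total_cn", "A_cn", "B_cn"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.index[numeric.isna()][0]) + 2  # 1-based incl. header
            raise SegmentTableError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = numeric.astype(int)

    swapped = df["A_cn"] < df["B_cn"]
    if swapped.any():
        logger.warning(
            "swapping A_cn/B_cn into major/minor order for %d rows", int(swapped.sum())
        )
        a = df.loc[swapped, "B_cn"].copy()
        df.loc[swapped, "B_cn"] = df.loc[swapped, "A_cn"]
        df.loc[swapped, "A_cn"] = a

    profiles = []
    for sample_id, grp in df.groupby("SampleID", sort=False):
        segs = [
            AlleleSpecificSegment(
                sample_id=str(sample_id),
                chromosome=str(r.Chromosome),
                start=int(r.Start_position),
                end=int(r.End_position),
                total_cn=int(r.total_cn),
                a_cn=int(r.A_cn),
                b_cn=int(r.B_cn),
            )
            for r in grp.itertuples()
        ]
        profiles.append(build_profile(str(sample_id), segs, arms))
    return profiles


def write_segment_table(profiles: Iterable[SegmentProfile], path) -> None:
    """Write profiles back to the segment TSV dialect read by
    :func:`read_segment_table`."""
    rows = [
        (s.sample_id, s.chromosome, s.start, s.end, s.total_cn, s.a_cn, s.b_cn)
        for p in profiles
        for s in p.segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def merge_adjacent(profile: SegmentProfile, tolerance_bp: int = 0) -> SegmentProfile:
    """Fuse same-state neighbours separated by at most ``tolerance_bp``.

    Two consecutive segments on one chromosome are fused when their
    (total_cn, A_cn, B_cn) triples are identical and the gap between them
    (``next.start - prev.end - 1``) does not exceed ``tolerance_bp``.
    Idempotent; never increases the number of covered bases beyond closing
    sub-tolerance gaps.
    """
    merged: list[AlleleSpecificSegment] = []
    for seg in profile.segments:
        if (
            merged
            and merged[-1].chromosome == seg.chromosome
            and (merged[-1].total_cn, merged[-1].a_cn, merged[-1].b_cn)
            == (seg.total_cn, seg.a_cn, seg.b_cn)
            and seg.start - merged[-1].end - 1 <= tolerance_bp
        ):
            merged[-1] = AlleleSpecificSegment(
                sample_id=seg.sample_id,
                chromosome=seg.chromosome,
                start=merged[-1].start,
                end=max(merged[-1].end, seg.end),
                total_cn=seg.total_cn,
                a_cn=seg.a_cn,
                b_cn=seg.b_cn,
            )
        else:
            merged.append(seg)
    return SegmentProfile(
        sample_id=profile.sample_id, segments=tuple(merged), ploidy=profile.ploidy
    )
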