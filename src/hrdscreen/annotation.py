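"""HR-pathway alteration calls: deleterious mutations, locus LOH, BRCA1
promoter methylation, and the sample grouping used for drug comparisons.

Two mutation-table dialects are supported, mirroring the two big cell-line
resources:

* a *dataset-annotation* dialect where damaging variants carry a single
  label (``Variant_annotation == "damaging"``), and
* a *predictor* dialect where truncating variants are kept unconditionally
  and missense variants only when all 10 functional-impact predictors call
  them deleterious/damaging.

Locus-specific LOH at a mutation is read off the minor-allele copy number at
the mutated locus: 0 means the wild-type allele is lost (LOH present), 1 or
more means it is retained. When the copy number is unknown in one dataset the
other dataset's value is used; if still unknown, the sample is excluded from
the relevant comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .config import load_defaults

logger = logging.getLogger(__name__)

_DEFAULTS = load_defaults()

HR_GENE_PANEL: frozenset[str] = frozenset(_DEFAULTS["hr_gene_panel"])
PREDICTORS: tuple[str, ...] = tuple(_DEFAULTS["predictors"])
CCLE_DAMAGING_LABEL: str = _DEFAULTS["ccle_damaging_label"]

DELETERIOUS_CALLS = frozenset({"deleterious", "damaging"})

LohStatus = Literal["LOH_present", "LOH_absent", "unknown"]
Group = Literal["BRCA_altered", "HRR_LOH_pos", "HRR_LOH_neg", "WT", "excluded"]


def normalize_gene(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class MutationCall:
    sample_id: str
    gene: str
    variant_class: Literal["truncating", "missense", "other"] = "other"
    dataset_annotation: str = ""
    predictor_calls: Mapping[str, str] = field(default_factory=dict)
    minor_cn_at_locus: int | None = None  # None = unknown

    def __post_init__(self) -> None:
        extra = set(self.predictor_calls) - set(PREDICTORS)
        if extra:
            raise ValueError(f"unknown predictors: {sorted(extra)}")


@dataclass(frozen=True)
class MethylationEvidence:
    sample_id: str
    gene: str
    probe_betas: Mapping[str, float]
    expression_percentile: float

    def __post_init__(self) -> None:
        for probe, beta in self.probe_betas.items():
            if not (0.0 <= beta <= 1.0):
                raise ValueError(
                    f"{self.sample_id}/{self.gene}: beta {beta} for probe "
                    f"{probe!r} outside [0, 1]"
                )


@dataclass
class SampleAnnotation:
    sample_id: str
    group: Group
    brca1_methylated: bool = False
    hrd_score: int | None = None
    signature3: float | None = None


def filter_deleterious_ccle(
    mutations: Iterable[MutationCall], damaging_label: str = CCLE_DAMAGING_LABEL
) -> list[MutationCall]:
    """Keep rows whose dataset annotation equals the damaging label
    (case-sensitive by default)."""
    return [m for m in mutations if m.dataset_annotation == damaging_label]


def filter_deleterious_clp(mutations: Iterable[MutationCall]) -> list[MutationCall]:
    """Keep truncating variants unconditionally; keep missense variants only
    when all 10 predictors call them deleterious/damaging. A missense variant
    with any missing predictor call cannot satisfy the unanimity requirement
    and is dropped with a warning."""
    kept = []
    for m in mutations:
        if m.variant_class == "truncating":
            kept.append(m)
        elif m.variant_class == "missense":
            calls = [m.predictor_calls.get(p, "missing") for p in PREDICTORS]
            if all(c in DELETERIOUS_CALLS for c in calls):
                kept.append(m)
            elif any(c == "missing" for c in calls):
                logger.warning(
                    "%s %s: missense with missing predictor calls dropped "
                    "(unanimity unverifiable)",
                    m.sample_id,
                    m.gene,
                )
    return kept


def annotate_loh(
    mutation: MutationCall, fallback: MutationCall | None = None
) -> LohStatus:
    """Locus LOH from minor-allele copy number; falls back to the other
    dataset's call for the same mutation when unknown here."""
    for source in (mutation, fallback):
        if source is not None and source.minor_cn_at_locus is not None:
            return "LOH_present" if source.minor_cn_at_locus == 0 else "LOH_absent"
    return "unknown"


def call_brca1_methylation_ccle(
    evidence: MethylationEvidence,
    beta_threshold: float | None = None,
    expression_percentile: float | None = None,
) -> bool | None:
    """Promoter-region rule: both region betas above the threshold AND
    expression below the percentile cutoff. Returns None (unknown) when a
    region beta is missing."""
    cfg = _DEFAULTS["methylation"]["ccle"]
    beta_threshold = cfg["beta_threshold"] if beta_threshold is None else beta_threshold
    pct = (
        cfg["expression_percentile"]
        if expression_percentile is None
        else expression_percentile
    )
    betas = list(evidence.probe_betas.values())
    if len(betas) < cfg["n_regions"]:
        logger.warning(
            "%s: only %d promoter-region betas (need %d); methylation unknown",
            evidence.sample_id,
            len(betas),
            cfg["n_regions"],
        )
        return None
    return all(b > beta_threshold for b in betas) and evidence.expression_percentile < pct


def call_brca1_methylation_clp(
    evidence: MethylationEvidence,
    beta_threshold: float | None = None,
    expression_percentile: float | None = None,
    min_probes: int | None = None,
) -> bool | None:
    """Probe-array rule: the per-probe condition (beta above threshold with
    expression below the percentile cutoff) must hold for at least
    ``min_probes`` of the 17 probes. Returns None when fewer than
    ``min_probes`` probes are available at all."""
    cfg = _DEFAULTS["methylation"]["clp"]
    beta_threshold = cfg["beta_threshold"] if beta_threshold is None else beta_threshold
    pct = (
        cfg["expression_percentile"]
        if expression_percentile is None
        else expression_percentile
    )
    min_probes = cfg["min_probes"] if min_probes is None else min_probes
    betas = list(evidence.probe_betas.values())
    if len(betas) < min_probes:
        logger.warning(
            "%s: only %d probes available (need >= %d); methylation unknown",
            evidence.sample_id,
            len(betas),
            min_probes,
        )
        return None
    expression_low = evidence.expression_percentile < pct
    qualifying = sum(1 for b in betas if b > beta_threshold and expression_low)
    return qualifying >= min_probes


def expression_percentiles(expression: pd.Series) -> pd.Series:
    """Cohort percentile rank (0-100) of each sample's expression value."""
    return expression.rank(pct=True) * 100.0


@dataclass(frozen=True)
class AnnotatedMutation:
    """A deleterious panel-gene mutation together with its LOH status."""

    call: MutationCall
    loh: LohStatus


def assign_group(
    sample_id: str,
    mutations: Sequence[AnnotatedMutation],
    brca1_methylated: bool,
    panel: frozenset[str] = HR_GENE_PANEL,
    scheme: Literal["brca_vs_wt", "hrr_vs_wt"] = "brca_vs_wt",
    include_loh_negative: bool = False,
) -> SampleAnnotation:
    """Deterministic group label for one sample.

    ``mutations`` must already be filtered to deleterious calls; non-panel
    genes are ignored entirely. Fine-grained labels: BRCA_altered (BRCA1/2
    mutation with LOH, or BRCA1 methylation), HRR_LOH_pos (another panel gene
    mutated with LOH), HRR_LOH_neg (panel mutation without LOH), WT (no panel
    mutation and no methylation), excluded (a panel mutation whose LOH status
    is still unknown).

    Under ``scheme="brca_vs_wt"`` only BRCA_altered and WT enter the
    comparison; ``scheme="hrr_vs_wt"`` pools BRCA_altered with HRR_LOH_pos
    (plus HRR_LOH_neg when ``include_loh_negative``). The scheme does not
    change the fine-grained label, only which labels
    :func:`comparison_groups` treats as altered.
    """
    del scheme, include_loh_negative  # grouping label itself is scheme-free
    panel_muts = [m for m in mutations if normalize_gene(m.call.gene) in panel]
    if brca1_methylated:
        group: Group = "BRCA_altered"
    elif not panel_muts:
        group = "WT"
    elif any(m.loh == "unknown" for m in panel_muts):
        group = "excluded"
    elif any(
        m.loh == "LOH_present" and normalize_gene(m.call.gene) in {"BRCA1", "BRCA2"}
        for m in panel_muts
    ):
        group = "BRCA_altered"
    elif any(m.loh == "LOH_present" for m in panel_muts):
        group = "HRR_LOH_pos"
    else:
        group = "HRR_LOH_neg"
    return SampleAnnotation(
        sample_id=sample_id, group=group, brca1_methylated=brca1_methylated
    )


def comparison_groups(
    annotations: Iterable[SampleAnnotation],
    scheme: Literal["brca_vs_wt", "hrr_vs_wt"] = "brca_vs_wt",
    include_loh_negative: bool = False,
) -> tuple[set[str], set[str]]:
    """(altered, wild-type) sample-id sets for a two-group AUC comparison."""
    altered_labels: set[str] = {"BRCA_altered"}
    if scheme == "hrr_vs_wt":
        altered_labels.add("HRR_LOH_pos")
        if include_loh_negative:
            altered_labels.add("HRR_LOH_neg")
    elif scheme != "brca_vs_wt":
        raise ValueError(f"unknown scheme {scheme!r}")
    altered = {a.sample_id for a in annotations if a.group in altered_labels}
    wt = {a.sample_id for a in annotations if a.group == "WT"}
    return altered, wt


def annotate_cohort(
    mutation_table: pd.DataFrame,
    methylation_table: pd.DataFrame | None,
    expression: pd.Series | None,
    sample_ids: Sequence[str],
    dialect: Literal["ccle", "clp"] = "ccle",
) -> list[SampleAnnotation]:
    """End-to-end annotation from the TSV/CSV dialects the simulator writes.

    ``mutation_table`` columns: sample, gene, variant_class,
    dataset_annotation, one column per predictor, minor_cn (empty = unknown).
    ``methylation_table``: one row per sample with promoter-region beta
    columns. ``expression``: per-sample BRCA1 expression used for the
    cohort-percentile cutoff.
    """
    # itertuples cannot carry names like "M-CAP"; normalise to identifiers
    mutation_table = mutation_table.rename(columns=lambda c: c.replace("-", "_"))
    calls: dict[str, list[MutationCall]] = {s: [] for s in sample_ids}
    for row in mutation_table.itertuples():
        minor = getattr(row, "minor_cn", None)
        minor_cn = None if pd.isna(minor) else int(minor)
        predictor_calls = {
            p: str(getattr(row, p.replace("-", "_"), "missing"))
            for p in PREDICTORS
            if not pd.isna(getattr(row, p.replace("-", "_"), float("nan")))
        }
        call = MutationCall(
            sample_id=str(row.sample),
            gene=str(row.gene),
            variant_class=str(row.variant_class),
            dataset_annotation=str(row.dataset_annotation),
            predictor_calls=predictor_calls,
            minor_cn_at_locus=minor_cn,
        )
        calls.setdefault(call.sample_id, []).append(call)

    pct = (
        expression_percentiles(expression)
        if expression is not None
        else pd.Series(dtype=float)
    )
    methylated: dict[str, bool] = {}
    if methylation_table is not None:
        beta_cols = [c for c in methylation_table.columns if c != "sample"]
        for row in methylation_table.itertuples():
            sid = str(row.sample)
            evidence = MethylationEvidence(
                sample_id=sid,
                gene="BRCA1",
                probe_betas={c: float(getattr(row, c)) for c in beta_cols},
                expression_percentile=float(pct.get(sid, 100.0)),
            )
            flag = (
                call_brca1_methylation_ccle(evidence)
                if dialect == "ccle"
                else call_brca1_methylation_clp(evidence)
            )
            methylated[sid] = bool(flag)

    annotations = []
    for sid in sample_ids:
        deleterious = (
            filter_deleterious_ccle(calls.get(sid, []))
            if dialect == "ccle"
            else filter_deleterious_clp(calls.get(sid, []))
        )
        annotated = [AnnotatedMutation(call=m, loh=annotate_loh(m)) for m in deleterious]
        annotations.append(
            assign_group(sid, annotated, methylated.get(sid, False))
        )
    return annotations


def annotations_frame(annotations: Iterable[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "group": a.group,
                "brca1_methylated": a.brca1_methylated,
                "HRD_score": a.hrd_score,
                "signature3": a.signature3,
            }
            for a in annotations
        ]
    )
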