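"""Per-assay drug-sensitivity association tests with Holm correction.

Each screen assay contributes a vector of AUC values (area under the
dose-response curve; higher = more resistant) over cell lines. Two kinds of
association are computed, per assay:

* a two-group comparison (Mann-Whitney U, two-sided) between annotated
  altered and wild-type samples, with the effect reported as the difference
  of group medians (altered minus wild-type), and
* a rank correlation (Spearman) between AUC and a continuous score such as
  the HRD score or the signature-3 cosine.

P values are corrected within one invocation's family using the Holm
step-down method; an assay is called a *trend* at unadjusted p < alpha and
*significant* at Holm-adjusted p < alpha. Missing AUC values are dropped
pairwise per assay, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import load_defaults

logger = logging.getLogger(__name__)

_DEFAULTS = load_defaults()
DRUG_CATEGORIES: tuple[str, ...] = tuple(_DEFAULTS["drug_categories"])
DEFAULT_MIN_ALTERED: int = int(_DEFAULTS["association"]["min_altered"])
DEFAULT_ALPHA: float = float(_DEFAULTS["association"]["alpha"])

# Exact Mann-Whitney enumeration is used only for small tie-free groups;
# beyond this the normal approximation with tie/continuity correction applies.
EXACT_MWU_MAX_N = 8


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class DrugAssay:
    """One screen's AUC vector plus drug identity metadata."""

    assay_id: str
    drug_name: str
    compound_id: str
    source: str
    category: str
    auc: Mapping[str, float]  # sample_id -> AUC

    def __post_init__(self) -> None:
        values = np.asarray(list(self.auc.values()), dtype=float)
        if values.size and not np.isfinite(values).all():
            raise AssociationError(f"assay {self.assay_id}: non-finite AUC values")

    def auc_series(self) -> pd.Series:
        return pd.Series(dict(self.auc), name=self.assay_id, dtype=float)


@dataclass(frozen=True)
class AssociationResult:
    assay_id: str
    test: Literal["mann_whitney", "spearman"]
    effect: float  # median difference (A - B) or Spearman rho
    p_unadjusted: float
    p_adjusted: float = float("nan")
    n: int = 0

    @property
    def direction(self) -> Literal["positive", "negative", "zero"]:
        if self.effect > 0:
            return "positive"
        if self.effect < 0:
            return "negative"
        return "zero"

    @property
    def trend(self) -> bool:
        return self.p_unadjusted < DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_adjusted < DEFAULT_ALPHA


def normalize_category(category: str) -> str:
    """Map a category onto the configured vocabulary; unknowns become
    'Others' with a warning."""
    if category in DRUG_CATEGORIES:
        return category
    logger.warning("unknown drug category %r mapped to 'Others'", category)
    return "Others"


def filter_assays(
    assays: Iterable[DrugAssay],
    altered_samples: set[str],
    min_altered: int = DEFAULT_MIN_ALTERED,
) -> tuple[list[DrugAssay], pd.DataFrame]:
    """Keep assays with at least ``min_altered`` altered samples that have a
    measured AUC; also return an exclusion table for auditing."""
    kept, excluded = [], []
    for assay in assays:
        n_alt = sum(
            1
            for sid, val in assay.auc.items()
            if sid in altered_samples and np.isfinite(val)
        )
        if n_alt >= min_altered:
            kept.append(assay)
        else:
            excluded.append(
                {
                    "assay_id": assay.assay_id,
                    "reason": "insufficient_altered_samples",
                    "n_altered_measured": n_alt,
                    "min_required": min_altered,
                }
            )
    return kept, pd.DataFrame(
        excluded, columns=["assay_id", "reason", "n_altered_measured", "min_required"]
    )


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    if len(a) <= EXACT_MWU_MAX_N and len(b) <= EXACT_MWU_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def compare_groups(
    assay: DrugAssay, group_a: set[str], group_b: set[str]
) -> AssociationResult | None:
    """Two-sided Mann-Whitney on AUC between two sample groups.

    Effect is median(A) - median(B). Returns None (assay skipped, reason
    logged) when either group has fewer than 2 measured samples.
    """
    auc = assay.auc_series().dropna()
    a = auc[auc.index.isin(group_a)].to_numpy()
    b = auc[auc.index.isin(group_b)].to_numpy()
    if len(a) < 2 or len(b) < 2:
        logger.info(
            "assay %s skipped: group sizes %d vs %d too small",
            assay.assay_id,
            len(a),
            len(b),
        )
        return None
    return AssociationResult(
        assay_id=assay.assay_id,
        test="mann_whitney",
        effect=float(np.median(a) - np.median(b)),
        p_unadjusted=_mannwhitney_p(a, b),
        n=len(a) + len(b),
    )


def correlate_score(
    assay: DrugAssay, scores: Mapping[str, float]
) -> AssociationResult | None:
    """Spearman correlation between AUC and a per-sample score on their
    overlap (pairwise-complete). Returns None when fewer than 3 overlapping
    samples remain or either vector is constant."""
    auc = assay.auc_series().dropna()
    score = pd.Series(dict(scores), dtype=float).dropna()
    common = auc.index.intersection(score.index)
    if len(common) < 3:
        logger.info(
            "assay %s skipped: only %d samples with both AUC and score",
            assay.assay_id,
            len(common),
        )
        return None
    x, y = score[common].to_numpy(), auc[common].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("assay %s skipped: constant vector, correlation undefined",
                    assay.assay_id)
        return None
    rho, p = stats.spearmanr(x, y)
    return AssociationResult(
        assay_id=assay.assay_id,
        test="spearman",
        effect=float(rho),
        p_unadjusted=float(p),
        n=len(common),
    )


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise AssociationError("p values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def adjust_family(results: Sequence[AssociationResult]) -> list[AssociationResult]:
    """Holm-adjust one family of results (all assays of one invocation)."""
    adjusted = holm_adjust([r.p_unadjusted for r in results])
    return [replace(r, p_adjusted=adj) for r, adj in zip(results, adjusted)]


def results_frame(
    results: Iterable[AssociationResult],
    assay_meta: Mapping[str, DrugAssay] | None = None,
) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "assay_id": r.assay_id,
            "test": r.test,
            "effect": r.effect,
            "p_unadjusted": r.p_unadjusted,
            "p_adjusted": r.p_adjusted,
            "direction": r.direction,
            "trend": r.trend,
            "significant": r.significant,
            "n": r.n,
        }
        if assay_meta and r.assay_id in assay_meta:
            assay = assay_meta[r.assay_id]
            row.update(
                drug_name=assay.drug_name,
                category=assay.category,
                source=assay.source,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_panel(
    results: Sequence[AssociationResult],
    assay_meta: Mapping[str, DrugAssay],
    drug_class_filter: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Direction-split, p-ordered report plus per-class trend counts.

    ``positive`` lists assays with positive effect sorted by ascending
    unadjusted p (strongest first); ``negative`` those with negative effect
    sorted by descending p read the same way figures print them;
    ``class_counts`` tallies trend/significant assays per drug class.
    """
    frame = results_frame(results, assay_meta)
    if frame.empty:
        empty = frame
        return {"positive": empty, "negative": empty, "class_counts": pd.DataFrame()}
    if drug_class_filter is not None:
        frame = frame[frame["category"].isin(set(drug_class_filter))]
    positive = frame[frame["effect"] > 0].sort_values("p_unadjusted")
    negative = frame[frame["effect"] < 0].sort_values("p_unadjusted", ascending=False)
    counts = (
        frame.groupby("category")
        .agg(
            n_assays=("assay_id", "size"),
            n_trend=("trend", "sum"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    return {
        "positive": positive.reset_index(drop=True),
        "negative": negative.reset_index(drop=True),
        "class_counts": counts,
    }


def read_assays(metadata_path, auc_matrix_path) -> list[DrugAssay]:
    """Load assays from a metadata CSV (assay_id, drug_name, compound_id,
    source, category) and an AUC matrix CSV (rows = samples, columns =
    assay ids)."""
    meta = pd.read_csv(metadata_path, dtype=str)
    required = {"assay_id", "drug_name", "compound_id", "source", "category"}
    missing = required - set(meta.columns)
    if missing:
        raise AssociationError(f"assay metadata missing columns: {sorted(missing)}")
    if meta["assay_id"].duplicated().any():
        raise AssociationError("duplicate assay_id in metadata")
    auc = pd.read_csv(auc_matrix_path, index_col=0)
    assays = []
    for row in meta.itertuples():
        if row.assay_id not in auc.columns:
            raise AssociationError(f"assay {row.assay_id} missing from AUC matrix")
        series = auc[row.assay_id].dropna()
        assays.append(
            DrugAssay(
                assay_id=row.assay_id,
                drug_name=row.drug_name,
                compound_id=row.compound_id,
                source=row.source,
                category=normalize_category(row.category),
                auc={str(k): float(v) for k, v in series.items()},
            )
        )
    return assays
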