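"""Synthetic cell-line cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
latent per-sample HRD flag drives (i) the number of planted genomic scar
events, (ii) the signature-3 mixture weight of the SNV catalog, (iii) the
chance of BRCA1 promoter methylation or a deleterious HR-gene mutation with
locus LOH, and (iv) a configurable shift of screen AUC values per unit HRD
score (positive = resistance, negative = sensitivity).

Scar events are planted by an event grammar: every TAI, LST and LOH event is
built to satisfy its scoring rule exactly and is separated from its
neighbours by an inter-event gap wider than the LST smoothing window, so no
incidental events arise and the planted counts are recoverable by the scorer
as strict equalities. Each data type draws from its own child random stream,
so e.g. adding assays never perturbs the segment layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import association
from .annotation import HR_GENE_PANEL, PREDICTORS
from .association import DRUG_CATEGORIES, DrugAssay, adjust_family, correlate_score
from .genome import (
    AlleleSpecificSegment,
    ChromosomeArmTable,
    SegmentProfile,
    build_profile,
    write_segment_table,
)
from .scars import ScarConfig, compute_hrd_score
from .spectrum import CHANNELS, ReferenceSignatureSet, load_reference_signatures

MB = 1_000_000

BASELINE_STATE = (2, 1, 1)  # balanced diploid (total, A, B)
TAI_STATE = (3, 2, 1)  # imbalanced, heterozygous: TAI without LOH
LOH_STATE = (1, 1, 0)  # copy-loss LOH
LST_STATES = ((2, 1, 1), (3, 2, 1))  # adjacent large segments of differing state

_NON_PANEL_GENES = ("TTN", "TP53", "MUC16", "KRAS", "PIK3CA")


class PackingError(RuntimeError):
    """Scar events do not fit on the genome."""


def simulation_genome(
    n_chromosomes: int = 12,
    chrom_length: int = 160 * MB,
    cen_start: int = 75 * MB,
    cen_end: int = 85 * MB,
) -> ChromosomeArmTable:
    """Default synthetic genome for cohort simulation; large enough to hold
    realistic per-sample scar event counts."""
    return ChromosomeArmTable(
        {
            f"chr{i + 1}": (chrom_length, cen_start, cen_end)
            for i in range(n_chromosomes)
        }
    )


@dataclass(frozen=True)
class ScarEventRates:
    """Poisson means for (TAI, LST, LOH) event counts per sample."""

    hrd: tuple[float, float, float] = (3.0, 4.0, 5.0)
    non_hrd: tuple[float, float, float] = (0.5, 0.5, 1.0)

    def for_group(self, hrd: bool) -> tuple[float, float, float]:
        return self.hrd if hrd else self.non_hrd


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines a synthetic cohort, bit for bit."""

    n_samples: int = 200
    hrd_prevalence: float = 0.15
    scar_event_rates: ScarEventRates = field(default_factory=ScarEventRates)
    n_snvs_mean: float = 120.0
    n_snvs_dispersion: float = 5.0
    sig3_weight_hrd: float = 0.6
    sig3_weight_non_hrd: float = 0.1
    methylation_rate: float = 0.2
    n_assays_per_class: int = 2
    assay_categories: tuple[str, ...] = DRUG_CATEGORIES
    affected_categories: tuple[str, ...] = ("Platinum", "PARP inhibitor")
    auc_effect: float = 0.5  # AUC SDs per HRD-score SD; sign = direction
    auc_noise_sd: float = 0.1
    auc_baseline: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("hrd_prevalence", self.hrd_prevalence),
            ("methylation_rate", self.methylation_rate),
            ("sig3_weight_hrd", self.sig3_weight_hrd),
            ("sig3_weight_non_hrd", self.sig3_weight_non_hrd),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for rates in (self.scar_event_rates.hrd, self.scar_event_rates.non_hrd):
            if any(r < 0 for r in rates):
                raise ValueError("scar event rates must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


@dataclass
class SimulatedCohort:
    config: CohortConfig
    arms: ChromosomeArmTable
    profiles: list[SegmentProfile]
    snv_table: pd.DataFrame
    mutation_table: pd.DataFrame
    methylation_table: pd.DataFrame
    expression: pd.Series
    assays: list[DrugAssay]
    auc_matrix: pd.DataFrame
    ledger: pd.DataFrame
    assay_truth: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ledger["sample_id"])


# ---------------------------------------------------------------------------
# scar-event grammar


def _draw_lengths(rng: np.random.Generator, cfg: ScarConfig, kind: str) -> list[int]:
    """Block lengths for one event, telomere-first order (bp)."""
    if kind == "tai":
        return [int(rng.integers(cfg.tai_min_len, cfg.tai_min_len + 5 * MB))]
    if kind == "loh":
        # strictly longer than the LOH cutoff
        return [int(rng.integers(cfg.loh_min_len + MB, cfg.loh_min_len + 5 * MB))]
    if kind == "lst":
        return [
            int(rng.integers(cfg.lst_min_seg, cfg.lst_min_seg + 3 * MB)),
            int(rng.integers(cfg.lst_min_seg, cfg.lst_min_seg + 3 * MB)),
        ]
    raise ValueError(kind)


def _event_states(kind: str) -> list[tuple[int, int, int]]:
    return {"tai": [TAI_STATE], "loh": [LOH_STATE], "lst": list(LST_STATES)}[kind]


def plant_scar_events(
    sample_id: str,
    counts: tuple[int, int, int],
    arms: ChromosomeArmTable,
    rng: np.random.Generator,
    scar_config: ScarConfig | None = None,
) -> SegmentProfile:
    """Build a segment profile containing exactly ``counts`` = (TAI, LST,
    LOH) qualifying events on a balanced-diploid background.

    Every event is flanked by inter-event gaps wider than the LST smoothing
    window, TAI events occupy telomeric slots, and interstitial events are
    preceded by a balanced spacer so they never touch a telomere. Raises
    :class:`PackingError` when the events cannot fit.
    """
    cfg = scar_config or ScarConfig()
    tai_n, lst_n, loh_n = counts

    def gap() -> int:  # always wider than the smoothing/max-gap window
        return int(rng.integers(cfg.lst_smooth_len + MB // 2, cfg.lst_smooth_len + 2 * MB))

    # arm slots: (chrom, telomere side, arm_start, arm_end)
    arm_slots = []
    for chrom in arms.chromosomes:
        cen_start, cen_end = arms.centromere(chrom)
        arm_slots.append((chrom, "p", 1, cen_start - 1))
        arm_slots.append((chrom, "q", cen_end + 1, arms.length(chrom)))
    if tai_n > len(arm_slots):
        raise PackingError(
            f"{sample_id}: {tai_n} TAI events but only {len(arm_slots)} telomeric "
            f"arm slots; use a larger genome or lower rates"
        )

    tai_arm_idx = set(
        rng.choice(len(arm_slots), size=tai_n, replace=False).tolist()
    ) if tai_n else set()

    # Each arm gets an ordered block plan, telomere-first:
    # [(state|None, length)], None = inter-event gap.
    plans: list[list[tuple[tuple[int, int, int] | None, int]]] = []
    remaining: list[int] = []
    for idx, (_, _, arm_start, arm_end) in enumerate(arm_slots):
        arm_len = arm_end - arm_start + 1
        plan: list[tuple[tuple[int, int, int] | None, int]] = []
        if idx in tai_arm_idx:
            (tai_len,) = _draw_lengths(rng, cfg, "tai")
            plan.append((TAI_STATE, tai_len))
        else:
            plan.append((BASELINE_STATE, int(rng.integers(4 * MB, 6 * MB))))
        plan.append((None, gap()))
        plans.append(plan)
        remaining.append(arm_len - sum(l for _, l in plan))

    events = ["lst"] * lst_n + ["loh"] * loh_n
    rng.shuffle(events)
    for kind in events:
        lengths = _draw_lengths(rng, cfg, kind)
        states = _event_states(kind)
        need = sum(lengths) + cfg.lst_smooth_len + 2 * MB  # event + trailing gap
        target = int(np.argmax(remaining))
        if remaining[target] < need:
            raise PackingError(
                f"{sample_id}: cannot place a {kind.upper()} event "
                f"({need} bp needed, {remaining[target]} bp free); "
                f"use a larger genome or lower scar rates"
            )
        for state, length in zip(states, lengths):
            plans[target].append((state, length))
        plans[target].append((None, gap()))
        remaining[target] = (
            arm_slots[target][3] - arm_slots[target][2] + 1
            - sum(l for _, l in plans[target])
        )

    segments: list[AlleleSpecificSegment] = []
    for (chrom, side, arm_start, arm_end), plan, rem in zip(
        arm_slots, plans, remaining
    ):
        if rem > 0:  # balanced fill on the centromere side
            plan = plan + [(BASELINE_STATE, rem)]
        if side == "q":  # telomere-first means laying blocks from the arm end
            plan = plan[::-1]
        pos = arm_start
        for state, length in plan:
            if state is not None:
                total, a, b = state
                segments.append(
                    AlleleSpecificSegment(
                        sample_id=sample_id,
                        chromosome=chrom,
                        start=pos,
                        end=pos + length - 1,
                        total_cn=total,
                        a_cn=a,
                        b_cn=b,
                    )
                )
            pos += length
    return build_profile(sample_id, segments, arms)


def random_segment_profile(
    sample_id: str,
    arms: ChromosomeArmTable,
    rng: np.random.Generator,
    states: Sequence[tuple[int, int, int]] = (
        (2, 1, 1),
        (2, 2, 0),
        (1, 1, 0),
        (3, 2, 1),
        (4, 2, 2),
        (3, 3, 0),
        (2, 1, 1),  # over-weight the balanced state
    ),
) -> SegmentProfile:
    """Unstructured random tiling (for oracle cross-checks, not cohorts):
    random segment lengths, gaps and states, occasionally spanning a whole
    chromosome or crossing the centromere."""
    segments = []
    for chrom in arms.chromosomes:
        length = arms.length(chrom)
        if rng.random() < 0.08:  # whole-chromosome segment
            total, a, b = states[rng.integers(len(states))]
            segments.append(
                AlleleSpecificSegment(sample_id, chrom, 1, length, total, a, b)
            )
            continue
        pos = 1 if rng.random() < 0.7 else int(rng.integers(1, 10 * MB))
        while pos < length:
            seg_len = int(rng.integers(1 * MB, 30 * MB))
            end = min(pos + seg_len - 1, length if rng.random() < 0.6 else length - 1)
            if end < pos:
                break
            total, a, b = states[rng.integers(len(states))]
            segments.append(
                AlleleSpecificSegment(sample_id, chrom, pos, end, total, a, b)
            )
            pos = end + 1 + int(rng.integers(0, 7 * MB))
    return build_profile(sample_id, segments, arms)


# ---------------------------------------------------------------------------
# cohort assembly


def _child_rngs(seed_seq: np.random.SeedSequence) -> dict[str, np.random.Generator]:
    names = ("latent", "segments", "snvs", "mutations", "methylation", "auc")
    children = seed_seq.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _channel_parts(channel: str) -> tuple[str, str, str]:
    """context, ref, alt of a channel label like 'A[C>T]G'."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def _simulate_snvs(
    sample_id: str,
    hrd: bool,
    config: CohortConfig,
    signatures: ReferenceSignatureSet,
    arms: ChromosomeArmTable,
    rng: np.random.Generator,
) -> tuple[list[dict], float]:
    w = config.sig3_weight_hrd if hrd else config.sig3_weight_non_hrd
    mixture = w * signatures.profile("Signature 3") + (1 - w) * signatures.profile(
        "Signature 1"
    )
    mean, disp = config.n_snvs_mean, config.n_snvs_dispersion
    n = int(rng.negative_binomial(disp, disp / (disp + mean))) if mean > 0 else 0
    chroms = arms.chromosomes
    rows = []
    for ch_idx in rng.choice(96, size=n, p=mixture):
        context, ref, alt = _channel_parts(CHANNELS[ch_idx])
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(2, arms.length(chrom) - 1))
        rows.append(
            {
                "sample": sample_id,
                "chromosome": chrom,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "context": context,
            }
        )
    return rows, w


def _simulate_mutations(
    sample_id: str,
    hrd: bool,
    methylated: bool,
    rng: np.random.Generator,
) -> tuple[list[dict], str | None]:
    """Mutation-table rows for one sample; returns (rows, driver gene)."""
    panel = sorted(HR_GENE_PANEL)
    rows: list[dict] = []
    driver: str | None = None

    def row(gene, variant_class, annotation, minor_cn, predictors="damaging"):
        base = {
            "sample": sample_id,
            "gene": gene,
            "variant_class": variant_class,
            "dataset_annotation": annotation,
            "minor_cn": minor_cn,
        }
        for p in PREDICTORS:
            base[p] = predictors
        return base

    if hrd and not methylated:
        u = rng.random()
        if u < 0.3:
            driver = "BRCA1"
        elif u < 0.6:
            driver = "BRCA2"
        else:
            driver = panel[rng.integers(len(panel))]
        variant_class = "truncating" if rng.random() < 0.7 else "missense"
        rows.append(row(driver, variant_class, "damaging", 0))
    elif not hrd:
        if rng.random() < 0.10:  # deleterious panel mutation, wild-type allele kept
            gene = panel[rng.integers(len(panel))]
            rows.append(row(gene, "truncating", "damaging", int(rng.integers(1, 3))))
        elif rng.random() < 0.05:  # benign panel variant, filtered out downstream
            gene = panel[rng.integers(len(panel))]
            rows.append(row(gene, "other", "silent", 1, predictors="tolerated"))
    if rng.random() < 0.3:  # passenger outside the panel; never affects grouping
        gene = _NON_PANEL_GENES[rng.integers(len(_NON_PANEL_GENES))]
        rows.append(row(gene, "missense", "damaging", 1))
    return rows, driver


def _make_assays(config: CohortConfig) -> pd.DataFrame:
    sources = ("GDSC1", "GDSC2", "CTRP2", "PRISM", "gCSI")
    rows = []
    idx = 0
    for category in config.assay_categories:
        slug = category.lower().replace(" ", "_").replace("/", "_")
        for i in range(config.n_assays_per_class):
            rows.append(
                {
                    "assay_id": f"{slug}_{i + 1}",
                    "drug_name": f"{category} compound {i + 1}",
                    "compound_id": f"CID{100000 + idx}",
                    "source": sources[idx % len(sources)],
                    "category": category,
                    "beta": config.auc_effect
                    if category in config.affected_categories
                    else 0.0,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def _simulate_auc(
    assay_meta: pd.DataFrame,
    hrd_scores: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """AUC matrix (samples x assays): baseline + beta * standardized HRD
    score * noise SD + Gaussian noise."""
    sd = float(hrd_scores.std(ddof=0))
    z = (hrd_scores - hrd_scores.mean()) / sd if sd > 0 else hrd_scores * 0.0
    data = {}
    for row in assay_meta.itertuples():
        noise = rng.normal(0.0, config.auc_noise_sd, size=len(hrd_scores))
        data[row.assay_id] = (
            config.auc_baseline + row.beta * z.to_numpy() * config.auc_noise_sd + noise
        )
    return pd.DataFrame(data, index=hrd_scores.index)


def simulate_cohort(
    config: CohortConfig,
    arms: ChromosomeArmTable | None = None,
    scar_config: ScarConfig | None = None,
) -> SimulatedCohort:
    """Generate a full synthetic cohort with its ground-truth ledger.

    The same config (including seed) always produces the identical cohort.
    """
    arms = arms or simulation_genome()
    scar_cfg = scar_config or ScarConfig()
    rngs = _child_rngs(np.random.SeedSequence(config.seed))
    signatures = load_reference_signatures()

    sample_ids = [f"CL{i + 1:04d}" for i in range(config.n_samples)]
    hrd_flags = rngs["latent"].random(config.n_samples) < config.hrd_prevalence

    profiles, ledger_rows = [], []
    snv_rows: list[dict] = []
    mutation_rows: list[dict] = []
    methyl_rows: list[dict] = []
    expression = {}
    for sid, hrd in zip(sample_ids, hrd_flags):
        rates = config.scar_event_rates.for_group(bool(hrd))
        counts = tuple(int(rngs["segments"].poisson(r)) for r in rates)
        profiles.append(
            plant_scar_events(sid, counts, arms, rngs["segments"], scar_cfg)
        )
        rows, w = _simulate_snvs(sid, bool(hrd), config, signatures, arms, rngs["snvs"])
        snv_rows.extend(rows)

        methylated = bool(hrd) and rngs["methylation"].random() < config.methylation_rate
        if methylated:
            betas = rngs["methylation"].uniform(0.5, 0.9, size=2)
            expression[sid] = float(rngs["methylation"].normal(1.0, 0.3))
        else:
            betas = rngs["methylation"].uniform(0.0, 0.25, size=2)
            expression[sid] = float(rngs["methylation"].normal(10.0, 2.0))
        methyl_rows.append(
            {"sample": sid, "region1": float(betas[0]), "region2": float(betas[1])}
        )

        mut_rows, driver = _simulate_mutations(
            sid, bool(hrd), methylated, rngs["mutations"]
        )
        mutation_rows.extend(mut_rows)

        ledger_rows.append(
            {
                "sample_id": sid,
                "hrd": bool(hrd),
                "tai": counts[0],
                "lst": counts[1],
                "loh": counts[2],
                "hrd_score": sum(counts),
                "sig3_weight": w,
                "brca1_methylated": methylated,
                "driver_gene": driver if driver else "",
            }
        )

    ledger = pd.DataFrame(ledger_rows)
    assay_meta = _make_assays(config)
    hrd_scores = ledger.set_index("sample_id")["hrd_score"].astype(float)
    auc_matrix = _simulate_auc(assay_meta, hrd_scores, config, rngs["auc"])

    assays = [
        DrugAssay(
            assay_id=row.assay_id,
            drug_name=row.drug_name,
            compound_id=row.compound_id,
            source=row.source,
            category=row.category,
            auc=auc_matrix[row.assay_id].to_dict(),
        )
        for row in assay_meta.itertuples()
    ]

    mutation_cols = [
        "sample", "gene", "variant_class", "dataset_annotation", *PREDICTORS,
        "minor_cn",
    ]
    return SimulatedCohort(
        config=config,
        arms=arms,
        profiles=profiles,
        snv_table=pd.DataFrame(
            snv_rows,
            columns=["sample", "chromosome", "position", "ref", "alt", "context"],
        ),
        mutation_table=pd.DataFrame(mutation_rows, columns=mutation_cols),
        methylation_table=pd.DataFrame(
            methyl_rows, columns=["sample", "region1", "region2"]
        ),
        expression=pd.Series(expression, name="BRCA1"),
        assays=assays,
        auc_matrix=auc_matrix,
        ledger=ledger,
        assay_truth=assay_meta,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write all cohort tables in the dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": outdir / "segments.tsv",
        "arms": outdir / "arms.tsv",
        "snvs": outdir / "snvs.tsv",
        "mutations": outdir / "mutations.tsv",
        "methylation": outdir / "methylation.csv",
        "expression": outdir / "expression.csv",
        "assays": outdir / "assays.csv",
        "auc": outdir / "auc.csv",
        "ledger": outdir / "ledger.tsv",
        "assay_truth": outdir / "assay_truth.tsv",
    }
    write_segment_table(cohort.profiles, paths["segments"])
    cohort.arms.to_frame().to_csv(paths["arms"], sep="\t", index=False)
    cohort.snv_table.to_csv(paths["snvs"], sep="\t", index=False)
    cohort.mutation_table.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.methylation_table.to_csv(paths["methylation"], index=False)
    cohort.expression.rename_axis("sample").reset_index().to_csv(
        paths["expression"], index=False
    )
    cohort.assay_truth.drop(columns=["beta"]).to_csv(paths["assays"], index=False)
    cohort.auc_matrix.rename_axis("sample").to_csv(paths["auc"])
    cohort.ledger.to_csv(paths["ledger"], sep="\t", index=False)
    cohort.assay_truth.to_csv(paths["assay_truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# validation harnesses


@dataclass(frozen=True)
class NullFamilyResult:
    n_replicates: int
    n_assays: int
    type_i_error: float  # fraction of (replicate, assay) tests with p < alpha
    fwer: float  # fraction of replicates with any Holm-significant assay
    rejections: int
    total_tests: int


def _association_replicate(
    config: CohortConfig,
    arms: ChromosomeArmTable,
    assay_meta: pd.DataFrame,
    scar_cfg: ScarConfig,
    seed_key: tuple[int, int],
):
    """One replicate of the score->AUC association pipeline: simulate
    segments, rescore them with the real scorer, simulate AUC, run the
    per-assay Spearman association, Holm-adjust the family."""
    rngs = _child_rngs(np.random.SeedSequence(seed_key))
    hrd_flags = rngs["latent"].random(config.n_samples) < config.hrd_prevalence
    scores = {}
    for i, hrd in enumerate(hrd_flags):
        sid = f"CL{i + 1:04d}"
        rates = config.scar_event_rates.for_group(bool(hrd))
        counts = tuple(int(rngs["segments"].poisson(r)) for r in rates)
        profile = plant_scar_events(sid, counts, arms, rngs["segments"], scar_cfg)
        scores[sid] = float(compute_hrd_score(profile, arms, scar_cfg).hrd_score)
    auc = _simulate_auc(assay_meta, pd.Series(scores), config, rngs["auc"])
    results = []
    for row in assay_meta.itertuples():
        assay = DrugAssay(
            assay_id=row.assay_id,
            drug_name=row.drug_name,
            compound_id=row.compound_id,
            source=row.source,
            category=row.category,
            auc=auc[row.assay_id].to_dict(),
        )
        res = correlate_score(assay, scores)
        if res is not None:
            results.append(res)
    return adjust_family(results)


def simulate_null_family(
    config: CohortConfig,
    n_replicates: int,
    alpha: float = 0.05,
    arms: ChromosomeArmTable | None = None,
) -> NullFamilyResult:
    """Monte-Carlo calibration of the per-assay score association under the
    no-effect null.

    Requires ``config.auc_effect == 0``. Each replicate simulates segment
    profiles and AUC matrices, recomputes HRD scores with the real scorer,
    runs the per-assay Spearman association against those scores, and applies
    Holm within the replicate's assay family. SNV, mutation and methylation
    stages are off the causal path of this statistic and are skipped.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if config.auc_effect != 0:
        raise ValueError("null family requires auc_effect == 0")
    arms = arms or simulation_genome()
    assay_meta = _make_assays(config)
    scar_cfg = ScarConfig()

    rejections = total = families_hit = 0
    for rep in range(n_replicates):
        results = _association_replicate(
            config, arms, assay_meta, scar_cfg, (config.seed, rep)
        )
        rejections += sum(1 for r in results if r.p_unadjusted < alpha)
        total += len(results)
        families_hit += any(r.p_adjusted < alpha for r in results)
    return NullFamilyResult(
        n_replicates=n_replicates,
        n_assays=len(assay_meta),
        type_i_error=rejections / total if total else float("nan"),
        fwer=families_hit / n_replicates,
        rejections=rejections,
        total_tests=total,
    )


@dataclass(frozen=True)
class RecoveryResult:
    n_replicates: int
    n_affected_assays: int
    recovery_rate: float  # fraction of affected-assay tests with the planted
    # direction and an unadjusted trend
    mean_rho: float


def direction_recovery_rate(
    config: CohortConfig,
    n_replicates: int,
    alpha: float = 0.05,
    arms: ChromosomeArmTable | None = None,
) -> RecoveryResult:
    """Power/direction check: fraction of affected-assay tests (over
    replicate pipelines) whose Spearman association has the planted effect's
    sign and unadjusted p < alpha."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if config.auc_effect == 0:
        raise ValueError("direction recovery requires a non-zero auc_effect")
    arms = arms or simulation_genome()
    assay_meta = _make_assays(config)
    affected = set(assay_meta.loc[assay_meta["beta"] != 0, "assay_id"])
    if not affected:
        raise ValueError("no affected assays under this config")
    want = "positive" if config.auc_effect > 0 else "negative"
    scar_cfg = ScarConfig()

    hits = total = 0
    rhos = []
    for rep in range(n_replicates):
        results = _association_replicate(
            config, arms, assay_meta, scar_cfg, (config.seed, 7_000_000 + rep)
        )
        for r in results:
            if r.assay_id in affected:
                total += 1
                rhos.append(r.effect)
                if r.direction == want and r.p_unadjusted < alpha:
                    hits += 1
    return RecoveryResult(
        n_replicates=n_replicates,
        n_affected_assays=len(affected),
        recovery_rate=hits / total,
        mean_rho=float(np.mean(rhos)),
    )
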