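"""End-to-end orchestration: simulate/ingest -> score -> spectrum ->
annotate -> associate -> report, with a deterministic run manifest.

Stages are pure functions of (inputs, config, seed); the manifest records the
fully-resolved configuration and a SHA-256 checksum of every output file, so
a re-run from the same manifest reproduces outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotation as ann
from . import association as assoc
from .genome import load_arm_table, read_segment_table
from .scars import ScarConfig, score_cohort
from .simulate import CohortConfig, ScarEventRates, simulate_cohort, write_cohort
from .spectrum import build_spectra, load_reference_signatures, read_snv_table, spectrum_report

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    outdir: str
    seed: int = 0
    simulate: dict[str, Any] | None = None  # CohortConfig field overrides
    inputs: dict[str, str] = field(default_factory=dict)  # paths when not simulating
    scar: dict[str, int] = field(default_factory=dict)
    min_altered: int = assoc.DEFAULT_MIN_ALTERED
    alpha: float = assoc.DEFAULT_ALPHA
    mutation_dialect: str = "ccle"
    schemes: tuple[str, ...] = ("brca_vs_wt", "hrr_vs_wt")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "schemes" in raw:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["schemes"] = list(self.schemes)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _cohort_config(run: RunConfig) -> CohortConfig:
    overrides = dict(run.simulate or {})
    if "scar_event_rates" in overrides:
        rates = overrides["scar_event_rates"]
        overrides["scar_event_rates"] = ScarEventRates(
            hrd=tuple(rates.get("hrd", ScarEventRates.hrd)),
            non_hrd=tuple(rates.get("non_hrd", ScarEventRates.non_hrd)),
        )
    for key in ("assay_categories", "affected_categories"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    overrides.setdefault("seed", run.seed)
    return CohortConfig(**overrides)


def run_pipeline(run: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- ingest or simulate -------------------------------------------------
    if run.simulate is not None:
        cohort = simulate_cohort(_cohort_config(run))
        input_paths = write_cohort(cohort, outdir / "inputs")
        inputs = {k: str(v) for k, v in input_paths.items()}
    else:
        inputs = dict(run.inputs)
    for key in ("segments", "arms"):
        if key not in inputs or not Path(inputs[key]).exists():
            raise PipelineStageError(
                "genome_model", f"required input {key!r} missing"
            )

    # --- genome_model -------------------------------------------------------
    try:
        arms = load_arm_table(inputs["arms"])
        profiles = read_segment_table(inputs["segments"], arms)
    except Exception as exc:
        raise PipelineStageError("genome_model", str(exc)) from exc

    # --- scar_scores --------------------------------------------------------
    try:
        scar_cfg = ScarConfig.from_mapping(run.scar)
        scores = score_cohort(profiles, arms, scar_cfg)
    except Exception as exc:
        raise PipelineStageError("scar_scores", str(exc)) from exc
    outputs["scores"] = outdir / "scar_scores.tsv"
    scores.to_csv(outputs["scores"], sep="\t", index=False)

    # --- mutational_spectrum ------------------------------------------------
    sig3 = pd.Series(dtype=float)
    if "snvs" in inputs and Path(inputs["snvs"]).exists():
        try:
            records = read_snv_table(inputs["snvs"])
            spectra = build_spectra(records)
            sig_report = spectrum_report(spectra, load_reference_signatures())
            sig3 = sig_report.set_index("sample_id")["signature3_cosine"]
        except Exception as exc:
            raise PipelineStageError("mutational_spectrum", str(exc)) from exc
        outputs["spectrum"] = outdir / "signature3.tsv"
        sig_report.to_csv(outputs["spectrum"], sep="\t", index=False)

    # --- alteration_annotation ----------------------------------------------
    sample_ids = scores["sample_id"].tolist()
    try:
        mutation_table = (
            pd.read_csv(inputs["mutations"], sep="\t")
            if "mutations" in inputs and Path(inputs["mutations"]).exists()
            else pd.DataFrame(
                columns=["sample", "gene", "variant_class", "dataset_annotation",
                         "minor_cn"]
            )
        )
        methylation_table = (
            pd.read_csv(inputs["methylation"])
            if "methylation" in inputs and Path(inputs["methylation"]).exists()
            else None
        )
        expression = None
        if "expression" in inputs and Path(inputs["expression"]).exists():
            expr_df = pd.read_csv(inputs["expression"])
            expression = expr_df.set_index("sample").iloc[:, 0]
        annotations = ann.annotate_cohort(
            mutation_table,
            methylation_table,
            expression,
            sample_ids,
            dialect=run.mutation_dialect,
        )
    except Exception as exc:
        raise PipelineStageError("alteration_annotation", str(exc)) from exc
    score_by_sample = scores.set_index("sample_id")["HRD_score"]
    for a in annotations:
        a.hrd_score = int(score_by_sample.get(a.sample_id, 0))
        a.signature3 = float(sig3.get(a.sample_id, float("nan")))
    annotations_df = ann.annotations_frame(annotations)
    outputs["annotations"] = outdir / "annotations.tsv"
    annotations_df.to_csv(outputs["annotations"], sep="\t", index=False)

    # --- association_analysis -----------------------------------------------
    analyses: dict[str, pd.DataFrame] = {}
    exclusions = []
    if "assays" in inputs and "auc" in inputs:
        try:
            assays = assoc.read_assays(inputs["assays"], inputs["auc"])
            meta = {a.assay_id: a for a in assays}

            for scheme in run.schemes:
                altered, wt = ann.comparison_groups(annotations, scheme=scheme)
                kept, excluded = assoc.filter_assays(
                    assays, altered, min_altered=run.min_altered
                )
                if not excluded.empty:
                    excluded.insert(0, "analysis", scheme)
                    exclusions.append(excluded)
                results = [
                    r
                    for a in kept
                    if (r := assoc.compare_groups(a, altered, wt)) is not None
                ]
                analyses[scheme] = assoc.results_frame(
                    assoc.adjust_family(results), meta
                )

            for label, series in (
                ("hrd_score", score_by_sample.astype(float)),
                ("signature3", sig3),
            ):
                if series.dropna().empty:
                    continue
                results = [
                    r
                    for a in assays
                    if (r := assoc.correlate_score(a, series.dropna().to_dict()))
                    is not None
                ]
                analyses[label] = assoc.results_frame(
                    assoc.adjust_family(results), meta
                )
        except Exception as exc:
            raise PipelineStageError("association_analysis", str(exc)) from exc

        for label, frame in analyses.items():
            outputs[f"associations_{label}"] = outdir / f"associations_{label}.tsv"
            frame.to_csv(outputs[f"associations_{label}"], sep="\t", index=False)
        if exclusions:
            outputs["exclusions"] = outdir / "excluded_assays.tsv"
            pd.concat(exclusions).to_csv(outputs["exclusions"], sep="\t", index=False)

        # --- report ---------------------------------------------------------
        summary: dict[str, Any] = {}
        for label, frame in analyses.items():
            if frame.empty:
                summary[label] = {"n_assays": 0}
                continue
            per_class = (
                frame.groupby("category")
                .agg(n_trend=("trend", "sum"), n_significant=("significant", "sum"))
                .astype(int)
                .to_dict("index")
                if "category" in frame
                else {}
            )
            summary[label] = {
                "n_assays": int(len(frame)),
                "n_trend": int(frame["trend"].sum()),
                "n_significant": int(frame["significant"].sum()),
                "n_positive": int((frame["effect"] > 0).sum()),
                "n_negative": int((frame["effect"] < 0).sum()),
                "per_class": per_class,
            }
        outputs["summary"] = outdir / "summary.json"
        outputs["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": run.to_dict(),
        "inputs": inputs,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "checksums": {k: _sha256(v) for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_report(analysis_tsv, outdir, drug_class_filter=None) -> dict[str, Path]:
    """Direction-split, p-ordered report files from a saved association table."""
    frame = pd.read_csv(analysis_tsv, sep="\t")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if drug_class_filter and "category" in frame:
        frame = frame[frame["category"].isin(set(drug_class_filter))]
    positive = frame[frame["effect"] > 0].sort_values("p_unadjusted")
    negative = frame[frame["effect"] < 0].sort_values("p_unadjusted", ascending=False)
    paths = {
        "positive": outdir / "report_positive.tsv",
        "negative": outdir / "report_negative.tsv",
    }
    positive.to_csv(paths["positive"], sep="\t", index=False)
    negative.to_csv(paths["negative"], sep="\t", index=False)
    return paths
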