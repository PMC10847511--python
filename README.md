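# hrdscreen

Genomic-scar HRD scoring and drug-sensitivity association for cell-line
cohorts.

Homologous recombination deficiency (HRD) — classically caused by BRCA1/2
inactivation — leaves measurable footprints in a tumor genome. `hrdscreen`
implements the full chain of analysis that links those footprints to *in
vitro* drug response in cell-line screen databases:

* **Scar scores** from allele-specific copy-number segments: TAI (telomeric
  allelic imbalance), LST (large-scale state transitions) and genomic LOH,
  with `HRD score = TAI + LST + LOH`.
* **Mutational signature 3**: SBS96 spectra from SNV catalogs and their
  cosine similarity to a 96-channel reference signature.
* **HR-gene alteration annotation**: deleterious mutations in the 29-gene HR
  panel, locus-specific LOH from the minor-allele copy number at the mutated
  locus (0 = wild-type allele lost), and BRCA1 promoter methylation
  silencing calls.
* **Association testing**: per-assay AUC comparisons (Mann-Whitney between
  altered and wild-type lines; Spearman against continuous scores), with
  Holm multiple-testing correction, assay filtering (≥ 10 altered samples),
  and direction-split ranked reports. Higher AUC = more resistant.
* **A synthetic cohort generator** that plants known numbers of scar events,
  signature mixtures, methylation silencing and AUC effects, so every stage
  — and the pipeline end to end — is validated against exact ground truth.

## Worked example

```python
import numpy as np
from hrdscreen import (
    CohortConfig, simulate_cohort, score_cohort, correlate_score, adjust_family,
)

cohort = simulate_cohort(CohortConfig(n_samples=60, seed=3))
scores = score_cohort(cohort.profiles, cohort.arms)
print(scores.head(3).to_string(index=False))

hrd = scores.set_index("sample_id")["HRD_score"].astype(float).to_dict()
results = adjust_family(
    [r for a in cohort.assays if (r := correlate_score(a, hrd)) is not None]
)
hits = [r for r in results if r.trend]
print(f"{len(hits)} of {len(results)} assays show an unadjusted trend")
```

prints

```
sample_id  TAI  LST  LOH  HRD_score
   CL0001    0    1    2          3
   CL0002    0    0    1          1
   CL0003    0    0    0          0
```

(the planted per-sample TAI/LST/LOH event counts, recovered exactly — the
generator ledger `cohort.ledger` carries the ground truth) and

```
6 of 48 assays show an unadjusted trend
```

Among those six, one Platinum and one PARP-inhibitor assay — the classes
where the generator plants its AUC shift — plus four chance trends in
unaffected classes, as expected at n = 60 where power is modest and 44 null
assays are tested at alpha 0.05. At n = 200 the affected assays are
recovered essentially always (see `scripts/acceptance.py`).

The same stages are available from the shell:

```bash
hrdscreen simulate --seed 3 --n-samples 60 --out cohort/
hrdscreen score-hrd --segments cohort/segments.tsv --arms cohort/arms.tsv --out scores.tsv
hrdscreen run-all --config run.yaml
```

Coordinates are 1-based inclusive throughout; segment tables use the
scarHRD-style columns `SampleID, Chromosome, Start_position, End_position,
total_cn, A_cn, B_cn`.

The packaged reference signature file is a **synthetic stand-in** catalog
(flat "Signature 3", CpG-concentrated "Signature 1", …); point
`load_reference_signatures` at a real catalog TSV to use published profiles.

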