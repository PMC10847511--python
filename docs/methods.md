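# Methods

## Scope and model

`hrdscreen` operationalizes a cell-line HRD analysis as five composable
stages: (1) validated allele-specific copy-number segment profiles on an
explicit chromosome-arm model; (2) genomic scar scoring (TAI, LST, LOH, and
their sum); (3) SBS96 spectrum construction and cosine similarity to a
reference signature; (4) rule-based HR-pathway alteration annotation; and
(5) per-assay drug-response association with family-wise error control.
A synthetic cohort generator with an exact ground-truth ledger closes the
loop: every stage is tested against either a literal brute-force re-derivation
of its rule or the generator's planted truth.

## Coordinates and segment model

Segments are 1-based, inclusive on both ends; length is `end − start + 1`.
Copy numbers are stored major-first (`A_cn ≥ B_cn`), so loss of
heterozygosity is always `B_cn == 0`. Within one sample and chromosome,
segments must not overlap; gaps (unsegmented sequence) are allowed and are
meaningful to the LST rule. The arm model is a table of chromosome length
and centromere interval; a packaged toy genome (3 × 100 Mb, centromere at
45–55 Mb) serves the test suite, and a GRCh37-style arm table ships as an
optional convenience. Ploidy, kept as profile metadata only, defaults to the
length-weighted mean total copy number.

## Scar scores

All constants are exposed in configuration; the defaults are the
conventional ones for SNP-array scar scoring:

| constant | default | role |
|---|---|---|
| `loh_min_len` | 15 Mb | LOH segments must be strictly longer |
| `tai_min_len` | 11 Mb | minimum TAI segment length (inclusive) |
| `lst_min_seg` | 10 Mb | minimum flanking-segment length at an LST breakpoint |
| `lst_smooth_len` | 3 Mb | short-segment removal, same-state fusion, max gap |
| `telomere_tolerance` | 0 bp | slack for "reaches the chromosome end" |

Definitions as implemented (and re-derived independently by the test
oracles):

* **LOH** — count of segments with `B_cn = 0`, `total_cn ≥ 1`, length >
  `loh_min_len`, excluding segments spanning an entire chromosome (both ends
  within the telomere tolerance).
* **TAI** — count of segments with `A_cn ≠ B_cn`, length ≥ `tai_min_len`,
  whose start is at position 1 or whose end is at the chromosome end (within
  tolerance), and which do not extend into the open centromere interval.
* **LST** — per arm: clip segments to the arm, drop pieces shorter than
  `lst_smooth_len`, fuse same-state neighbours separated by at most
  `lst_smooth_len` (state = the `(total_cn, B_cn)` pair), then count
  adjacent pairs with different state, both ≥ `lst_min_seg`, separated by at
  most `lst_smooth_len`. Segments crossing the centromere contribute their
  clipped parts to each arm separately.

The HRD score is the raw sum; no dichotomisation at a clinical cutoff is
applied, because the downstream statistics use the continuous score.
Sex chromosomes are processed whenever present in both the profile and the
arm table. Degenerate inputs: an empty profile scores (0, 0, 0); segment
tables listing minor before major copy number are swapped on read with a
warning rather than rejected.

## Mutational spectrum and signature similarity

SNVs are classified into the standard 96 pyrimidine-centred channels
(substitution class major — C>A, C>G, C>T, T>A, T>C, T>G — then 5′ flank,
then 3′ flank, each A/C/G/T). Purine-reference records are
reverse-complemented; trinucleotide contexts come inline or from an indexed
FASTA; indels and multi-nucleotide rows are skipped with a logged count.
The similarity statistic is the plain cosine between the raw count vector
and the reference profile — a deliberately transparent quantity (the
likelihood-based machinery some callers wrap around it is out of scope
here). A per-channel weighting hook exists for coverage normalisation; the
default is unweighted raw counts. The cosine of an all-zero spectrum is
undefined and raises; callers exclude such samples.

The packaged reference catalog is **synthetic**: deterministically
constructed 96-channel profiles reproducing the qualitative shapes relevant
to this analysis (a broad, near-flat "Signature 3"; a CpG-C>T-concentrated
"Signature 1"; TpC-focused companions). Every property the package relies
on — unit self-similarity, strict monotone recovery of the signature-3
mixture weight — is invariant to the exact profile values, and any
real catalog TSV in the same layout can be supplied instead.

## Alteration annotation

Deleteriousness is called per dataset dialect: a single damaging label
(matched case-sensitively), or truncating-always plus missense-only-if all
10 predictors (SIFT, Polyphen2, LRT, MutationTaster, MutationAssessor,
FATHMM, PROVEAN, MetaSVM, MetaLR, M-CAP) agree. A missense variant with a
missing predictor call cannot demonstrate unanimity and is dropped with a
warning. Locus LOH: minor-allele copy number 0 = present, ≥ 1 = absent,
unknown resolved from the paired dataset when available, otherwise the
sample is excluded from the relevant comparison.

BRCA1 methylation silencing uses two rules: both promoter-region betas >
0.3 with expression below the 10th cohort percentile (two-region dialect),
or beta > 0.2 with expression below the 30th percentile for ≥ 15 of 17
probes (probe-array dialect). "Expression below X%" is interpreted as a
cohort percentile rank — the only scale-free reading that works across
expression units. Methylation-silencing thresholds for HR genes other than
BRCA1 are not shipped (no established criteria); the generic per-probe rule
is configurable for users who wish to define their own.

Grouping is a pure function of the calls: `BRCA_altered` (BRCA1/2 mutation
with LOH, or BRCA1 methylation), `HRR_LOH_pos` (another panel gene mutated
with LOH), `HRR_LOH_neg` (panel mutation without LOH — including BRCA1/2
mutations whose wild-type allele is retained, since the comparison pools
all LOH-negative mutants on the unaltered side), `WT` (no deleterious panel
mutation, no methylation), `excluded` (unknown LOH). The two comparison
schemes nest: the BRCA-vs-WT altered set is a subset of the HRR-vs-WT
altered set, and WT is identical in both. Whether LOH-negative mutants
count as altered in the broader scheme is genuinely ambiguous in practice,
so it is a config switch (`include_loh_negative`, default off).

## Association analysis

AUC (higher = more resistant) is the response; missing values are dropped
pairwise per assay and never imputed. Two-group comparisons use the
two-sided Mann-Whitney U: exact enumeration when both groups have ≤ 8
samples and the pooled values are tie-free, otherwise the normal
approximation with tie and continuity correction. Score associations use
Spearman's rank correlation with average ranks and the t-approximation for
p. The effect is the median difference (altered − wild-type) or rho;
direction is its sign. Holm correction is applied within one invocation's
family (all assays analysed together, mirroring per-figure families);
`trend` = unadjusted p < 0.05, `significant` = Holm-adjusted p < 0.05, with
alpha configurable. Assays with fewer than 10 altered samples having a
measured AUC are excluded before testing, and an exclusion table is emitted
so the count is auditable. The 24-class drug-category vocabulary ships in
the package configuration; unknown categories map to "Others" with a
warning.

## Synthetic cohorts

A latent Bernoulli HRD flag (default prevalence 0.15) drives everything:

* **Scar events** — per-component Poisson counts with means (TAI, LST, LOH)
  = (3, 4, 5) for HRD-positive and (0.5, 0.5, 1) for HRD-negative samples,
  giving mean HRD scores near 12 vs 2, the kind of separation seen between
  HR-deficient and HR-proficient lines. Events are planted by an event
  grammar: TAI events occupy telomeric slots ((3,2,1) segments of 11–16 Mb
  at a chromosome end), LOH events are interstitial (1,1,0) segments of
  16–20 Mb, LST events are abutting (2,1,1)/(3,2,1) pairs of 10–13 Mb each,
  and every event is separated from its neighbours by a 3.5–5 Mb gap —
  wider than the smoothing window, so no incidental events arise and the
  ledger equals the scorer's output *exactly*, which is the central oracle
  binding simulator and scorer. Infeasible packings raise an error rather
  than silently truncating. The default simulation genome is 12 chromosomes
  of 160 Mb (centromere 75–85 Mb), sized so default Poisson draws
  essentially never exhaust capacity; the 3 × 100 Mb toy genome remains the
  deterministic test fixture.
* **SNVs** — negative-binomial catalog sizes (mean 120, dispersion 5,
  exome-scale), channels drawn from the mixture `w·sig3 + (1−w)·sig1` with
  w = 0.6 (HRD+) vs 0.1 (HRD−); contexts are emitted inline.
* **Alterations** — HRD-positive samples carry either BRCA1 methylation
  (rate 0.2; high betas, bottom-tail expression) or a deleterious panel
  mutation with minor-allele copy number 0; HRD-negative samples
  occasionally carry LOH-negative or benign panel variants; non-panel
  passengers are sprinkled everywhere.
* **AUC** — `baseline + β · z(HRD score) · σ + N(0, σ)` with σ = 0.1 and
  β in units of AUC SD per HRD-score SD, applied to the Platinum and
  PARP-inhibitor classes by default. β's sign is configurable on purpose:
  the generator can emulate either a resistance association (β > 0) or the
  clinically expected sensitivity (β < 0).

Each data type draws from its own child stream of a single seed sequence,
so the same seed reproduces the cohort bit for bit and adding assays never
perturbs the segment layout.

What the generator does *not* emulate: real marginal distributions of CCLE
copy-number profiles, linkage between scar components, subclonality,
segmentation noise, batch structure across screens, or dose-response curve
shapes. Passing tests therefore demonstrate the correctness of the rules
and statistics, not the field performance of scar scoring on real arrays.

## Validation harnesses and problem sizes

* Scar oracle suite: 100 random unstructured profiles vs literal
  brute-force enumerators, exact equality.
* Ground truth: 200-sample cohorts at several seeds, ledger equality for
  every sample.
* Signature recovery: 5,000-SNV catalogs, 20 replicates per mixture weight
  in {0, .25, .5, .75, 1}, strictly increasing mean cosine.
* Null calibration: 20 assays × 200 samples × 500 replicate pipelines;
  per-assay type-I error inside the exact binomial 99% band around 5%, Holm
  FWER within three Monte-Carlo SEs of 5%.
* Direction recovery: β = +0.5, 100 replicate pipelines, ≥ 95% of
  affected-assay tests positive with a trend.

These sizes keep the whole suite in the low minutes on a single CPU while
leaving Monte-Carlo margins well clear of their thresholds. The null and
power harnesses run the stages on the causal path of the statistic
(segments → scar scores → AUC → association); SNV, mutation-table and
methylation generation do not influence those statistics and are skipped
inside the replicate loop.

## Known limitations

* The TAI definition has published sub-variants (e.g. with copy-number
  filters); this package's semantics are fixed by its brute-force oracle,
  and all five constants are overridable.
* The LST smoothing here is "drop all short pieces once, then fuse to a
  fixed point"; implementations that iterate removal and fusion can differ
  on pathological stacks of sub-3 Mb segments.
* Exact Mann-Whitney enumeration is limited to tie-free groups of ≤ 8; at
  screen-typical sizes the corrected normal approximation is standard.
* Holm families are per invocation; a global family across several analyses
  must be assembled by the caller.
* No dose-response fitting, no cross-screen AUC harmonisation, no de novo
  signature extraction, and no variant-effect prediction — those live
  upstream of this package's inputs.
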