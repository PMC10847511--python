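# Default configuration constants for the hrdscreen pipeline.
# Every value here can be overridden by a user-supplied run config.

# The 29-gene homologous-recombination-related panel used for alteration calls.
hr_gene_panel:
  - ATM
  - ATR
  - BARD1
  - BLM
  - BRCA1
  - BRCA2
  - BRIP1
  - CDK12
  - CHEK1
  - CHEK2
  - FANCA
  - FANCC
  - FANCD2
  - FANCE
  - FANCF
  - FANCI
  - FANCL
  - FANCM
  - MRE11
  - NBN
  - PALB2
  - RAD50
  - RAD51
  - RAD51B
  - RAD51C
  - RAD51D
  - RAD52
  - RAD54L
  - RPA1

# The 10 functional-impact predictors a missense variant must unanimously fail
# to be kept by the CLP-style deleteriousness filter.
predictors:
  - SIFT
  - Polyphen2
  - LRT
  - MutationTaster
  - MutationAssessor
  - FATHMM
  - PROVEAN
  - MetaSVM
  - MetaLR
  - M-CAP

# Label a CCLE-style mutation table uses to mark damaging variants
# (matched case-sensitively by default).
ccle_damaging_label: damaging

# The 24 drug categories used to organise screen assays.
drug_categories:
  - Platinum
  - PARP inhibitor
  - Topoisomerase inhibitor
  - DNA alkylator
  - DNA inhibitor
  - Antimetabolite
  - PI3K/MTOR signaling
  - RTK signaling
  - Chromatin-related
  - ERK MAPK signaling
  - Cell cycle-related
  - Anti-microtubular
  - Protein stability and degradation
  - Apoptosis regulation
  - EGFR signaling
  - WNT signaling
  - Genome integrity
  - Metabolism
  - Hormone-related
  - IGF1R signaling
  - p53 pathway
  - Cytoskeleton
  - JNK and p38 signaling
  - Others

# BRCA1 promoter methylation-silencing call thresholds.
methylation:
  ccle:
    beta_threshold: 0.3        # beta must exceed this in BOTH promoter regions
    expression_percentile: 10.0  # expression must fall below this cohort percentile
    n_regions: 2
  clp:
    beta_threshold: 0.2
    expression_percentile: 30.0
    min_probes: 15             # per-probe condition must hold for >= 15 probes
    n_probes: 17

# Genomic scar score constants (base pairs).
scar:
  loh_min_len: 15000000        # LOH segments must be longer than this
  tai_min_len: 11000000        # imbalanced telomeric segments at least this long
  lst_min_seg: 10000000        # both segments flanking an LST breakpoint
  lst_smooth_len: 3000000      # short-segment removal / fusion / max gap
  telomere_tolerance: 0        # slack for "reaches the chromosome end"

# Association-analysis settings.
association:
  min_altered: 10              # assays with fewer altered samples are excluded
  alpha: 0.05
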