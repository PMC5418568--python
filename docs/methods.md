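# Methods

## The screening cascade

Universal tumour screening stains the four MMR proteins (MLH1, MSH2, MSH6,
PMS2) on resections; biopsy-only cases start with a two-stain MSH6 + PMS2
panel that covers both heterodimers, reflexing to MLH1 after PMS2 loss and
to MSH2 after MSH6 loss. Stains score present only with convincing nuclear
staining and a positive internal control; a stain without its control is
treated as not done. Weak-but-present stains (> 1% of cells) are recorded
with a weak flag but count as present for pattern purposes — this is what
makes low-penetrance MSH6 carriers invisible to the screen and is modelled
explicitly.

Loss patterns collapse to `MLH1/PMS2`, `MSH2/MSH6`, `MSH6`, `PMS2`,
`normal` or `incomplete`. Heterodimer pairs take precedence and additional
missing stains ride along with the pattern implied by the absent ones
(e.g. MSH6+PMS2 absent reads as a PMS2 pattern, since PMS2 loss already
implies the MLH1/PMS2 axis while isolated MSH6 loss does not explain PMS2
absence). A two-stain biopsy panel with both stains present is a complete
negative screen and reads normal, not incomplete.

### Methylation and the BRAF fallback

*MLH1* promoter methylation is the arithmetic mean of the assayed CpG
sites, called positive at a mean ≥ 15% (inclusive; the threshold is
configuration, `screening.methylation_threshold`). The ≥ 15% rule is
applied to the mean, not per site, matching the assay's single averaged
read-out; an empty measurement is a failed assay. BRAF V600E positivity
stands in for direct methylation evidence in two situations: a failed assay
on a biopsy-only case, and a negative assay whose mean lies within
`screening.braf_rescue_margin` (default 2) percentage points below the
threshold — the second rule is required by an evidence row in which a 14%
assay plus BRAF V600E resolves to hypermethylation, and the margin is kept
as an explicit, configurable constant rather than folded into the
threshold.

### Tumour-sequencing resolution

The MSI call is a threshold rule on the fraction-of-unstable-loci score:
MSI-high at score ≥ `somatic.msi_threshold`. The published record prints
scores and calls but no cut-off; 0.2 — the convention for the score — falls
cleanly between the largest printed stable score (0.1587) and the smallest
unstable one (0.2188) and is adopted, inclusive at the boundary. All thirty
printed scores reproduce their printed calls under it.

LOH is banded from allelic imbalance: with tumour purity *p*, a
heterozygous variant whose wild-type allele is lost is expected at
VAF 1/(2 − *p*); the observed/expected ratio maps to definite (≥ 0.90),
likely (≥ 0.75), maybe (≥ 0.60), else none (`somatic.loh_bands`). The
bands are chosen to reproduce the likely/maybe annotations of the evidence
rows. A boundary case worth noting: VAF 0.60 at purity 0.6 gives ratio
0.84 and lands in the likely band under these constants.

Solved rules. A variant is pathogenic/likely pathogenic when class 4/5 or
predicted truncating (splice-disrupting changes count as truncating).
Without a qualifying germline mutation: two such hits in one gene, or one
hit with LOH at likely-or-better, is solved double somatic; one hit with
possible LOH is possibly solved; anything less is unresolved. With a
qualifying germline mutation, any somatic hit in the same gene or
likely-or-better LOH is the second hit (Lynch syndrome); none detected
means a sporadic tumour in a carrier. Class-3 germline variants qualify
only when the tumour shows a second hit — the second hit is the evidence
that argues the variant is pathogenic, mirroring how such variants get
reclassified.

### Decision order of the classifier

1. Normal/incomplete IHC: tumour sequencing (when available) decides
   second-hit LS vs sporadic-tumour-in-carrier; a qualifying germline
   mutation without tumour data still reads as LS (sporadic tumour);
   otherwise MMR-proficient.
2. MLH1/PMS2 loss: positive or BRAF-inferred methylation → sporadic
   hypermethylation; else germline; else tumour sequencing; else
   unexplained.
3. Other loss patterns: qualifying germline mutation in a concordant gene
   (MLH1/PMS2 ← MLH1 or PMS2; MSH2/MSH6 ← MSH2 or MSH6; MSH6 ← MSH6;
   PMS2 ← PMS2 or MLH1 — protein-partner biology), else tumour sequencing,
   else unexplained. Cases whose tumour testing failed are unexplained.

Screen-positive for the performance metrics means abnormal IHC *not*
explained by hypermethylation: hypermethylated tumours are resolved as
sporadic before any germline work-up, so they belong to the screen-negative
stratum. This is also the only definition under which the four published
percentages are simultaneously consistent (21/27, 905/926, 21/42, 905/911).
Sporadic tumours in carriers count as LS for prevalence and metrics but are
reported separately. Percentages are carried at full precision and rounded
half-away-from-zero to one decimal only in reports.

## The fixture cohort and the generator

`fixture_cohort()` reconstructs a deterministic 1,182-case cohort whose
marginals match the published tables cell by cell. The under-determined
joint assignment of mutations to IHC patterns is resolved as: PMS2
frameshift — 9 PMS2-pattern + 3 normal-IHC (two sporadic tumours, one
untested); MSH6 p.Leu585Pro — 6 MSH6-pattern + 3 normal-with-weak-stain;
the three private MSH6 mutations — 1 MSH6-pattern + 2 MSH2/MSH6;
translocation — MLH1/PMS2; the two de-novo PMS2 variants — PMS2 pattern.
This is the only assignment consistent with the row totals and the
tumour-sequencing evidence rows. The gene of the untested sixth normal-IHC
LS case is not recorded publicly; the fixture assigns the PMS2 frameshift
(the most frequent founder allele) and flags this as an assumption. The 90
hypermethylated MLH1/PMS2 cases comprise 86 directly positive assays, 3
failed biopsy assays rescued by BRAF IHC and 1 borderline-negative (14%)
BRAF-positive case. Demographics (age, sex, stage, location) are sampled
from the published per-etiology distributions — ages triangular between the
printed quartiles around the median — purely for realism; the classifier
never reads them.

`generate_cohort()` draws configurable cohorts: multinomial etiology counts
(largest-remainder apportionment in exact mode), one seeded generator per
run, founder-mutation assignment proportional to carrier frequencies, weak
stains in a configurable fraction of MSH6 LS cases (default 3/9, the
fixture rate), and a configurable number of sporadic-tumour carriers
(default 2). Round-tripping an exact cohort through the classifier
reproduces the configured mixture exactly. The double-somatic gene mixture
(MLH1 0.50, MSH2 0.31, PMS2 0.13, MSH6 0.06) follows the observed 16-case
distribution.

What the generator does **not** emulate: inter-site assay drift, tissue
quality, pedigree structure, and any correlation between demographics and
molecular evidence. Passing tests therefore show the cascade's rules and
arithmetic are right, not that the assays behave this cleanly on real
tissue.

## Association and penetrance

Association is maximum-likelihood logistic regression of case status on
carrier dosage (statsmodels GLM, binomial family). Binary 0/1 dosages are
aggregated to a frequency-weighted 2×2 design before fitting — the ML
solution is unchanged and the estimate equals the cross-product odds ratio,
which the tests verify against an independent closed-form oracle. Intervals
are Wald (the GWAS convention), p-values from the Wald χ² with 1 df.
Degenerate tables (empty cells, complete separation) return flagged
estimates with infinite/zero bounds rather than raising; cohorts with no
carriers at all are an error.

Inflation correction divides the χ² statistic by a per-trait factor — the
LD-score-regression intercepts are shipped as a 17-trait configuration
table, not estimated (LD-score regression itself is out of scope).
Bonferroni: α/m, reported at three significant figures (0.05/16 →
3.13e-03).

Simulation honours the published fixed case/control totals by sampling
retrospectively: controls carry at the population frequency *f*, cases at
OR·o₀/(1 + OR·o₀) with o₀ = f/(1 − f). Parameter-recovery checks run 600
replicates per row; with expected carrier-case counts as low as ~1–5 for
the weakest rows the OR distribution is strongly discrete, and a few
hundred replicates are needed before the sample median is a stable estimate
of the distribution median.

Risk conversion never had a published formula or registry baselines; both
scales are provided with the odds scale as default (consistent with
logistic ORs), baselines are user-supplied configuration, and the published
lifetime-risk columns are treated as reproducible only conditional on those
baselines. The conversions are checked by exact round-trip inversion and
monotonicity instead. Combined carrier prevalence assumes independent
mutations (union formula); the published national prevalence additionally
includes family-level frequencies that are not printed, so the package
reports the union of the three imputable frequencies (0.406%) and makes no
claim about the rest.

## Translocation scan

Coordinates are 0-based half-open internally, 1-based at SAM/report
boundaries. Insert statistics come from proper same-chromosome FR pairs
(up to 100,000), with symmetric 1% trimming against contamination; the
trimmed SD is rescaled by the Gaussian truncation factor so the 3-SD
discordance rule keeps its nominal meaning. Discordance reasons are
evaluated in a fixed order: inter-chromosomal/unaligned mate, then
orientation (FR expected), then insert size beyond 3 SD.

Clustering is single-linkage over pairs whose two sides each lie within
`cluster_max_gap` (default 500 bp), sorted internally so input order is
irrelevant. Clusters are discarded when they overlap a user-supplied
repeat mask (BED), fall below `min_support` (default 3 pairs — the
published scan reviewed clusters manually; automation needs a floor), or
occur in more than `max_control_fraction` (default 1%) of a control
catalogue. Because the scanner targets translocations, same-chromosome
discordant clusters (deletions, inversions, insert-size outliers) are not
called.

Breakpoints: the junction on each side is the modal soft-clip boundary,
ties broken toward the smaller coordinate. On each side, a trailing-clip
boundary above the leading-clip boundary measures duplicated bases
(present on both derivatives); the reverse measures deleted bases. The
inserted motif is the prefix of the position-wise consensus of the clipped
tails that does not align to the partner reference at its junction
(smallest such prefix; under sequencing errors, the mismatch-minimising
prefix with ties toward fewer inserted bases). The motif is flagged
reverse-complement when its reverse complement, but not the motif itself,
occurs within 60 bp of either junction. Micro-homology at a junction can
make the insert length ambiguous by construction; the deterministic
tie-break resolves it reproducibly. Without spanning soft-clips the call
degrades to the discordant-cluster intervals with anatomy unset.

The read simulator emits what an ideal local aligner would report (longest
reference-contiguous run aligned, remainder soft-clipped, mates and TLEN
consistent), from both derivative chromosomes and both intact haplotypes of
a heterozygous carrier. It is the truth-generating counterpart of the
scanner, not a sequencing-error model: base errors are uniform
substitutions, quality strings are flat, and mapping ambiguity in repeats
is not simulated (repeats are handled by the mask instead).

## Problem sizes and numerical choices

Default verification runs use 4–20 kb references at 20–30× haploid depth,
100 translocation-free seeds for the false-positive check, and 200–600
association replicates — sizes chosen so the full suite re-runs in a few
minutes on one core while leaving every statistical check comfortably
powered. Thresholds (15% methylation, 0.2 MSI, LOH bands, 3 SD, margins)
live in `AnalysisConfig` and serialize to JSON; every randomised component
takes an explicit seed and fixed seeds give byte-identical outputs
(serialized cohorts, SAM files).

## Known limitations

- The cascade consumes abstracted stain calls and assay values, not images
  or raw sequencing; inter-observer scoring variability is out of scope.
- Class-3 handling implements the second-hit reclassification logic for
  the specific evidence patterns observed; it is not a general variant
  classifier.
- The association module fits single-variant models without covariates;
  relatedness/stratification are handled only through the inflation
  factor, as in the modelled analysis.
- One published evidence row (a possibly-double-somatic tumour with a
  germline splice-region variant elsewhere shown benign) is reproduced as
  printed; the tension between that row's outcome and the variant's later
  reclassification is inherited, not resolved.
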