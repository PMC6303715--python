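# Methods

## Problem setting

`snpharmony` implements a data-synthesis workflow for diploid, biallelic SNP
genotypes collected by independent projects: intersect the panels, detect and
correct strand-designation inconsistencies at ambiguous loci, apply tiered
locus QC, and compute the population-genetic statistics used to characterize
range-wide structure (heterozygosity, pairwise Weir–Cockerham F_ST,
isolation by distance, regional Welch comparisons). Everything operates on a
dosage matrix counting copies of each locus' *designated* allele (the first
allele of its recorded pair; VCF REF, or the lower allele code in Genepop),
with a dedicated missing-data sentinel. Swapping the designation maps dosage
g → 2 − g; because the designation is always carried explicitly, the swap is
an involution and never happens silently.

## Strand-ambiguity calibration and correction

A/T and C/G polymorphisms equal their own reverse complement, so allele
identities cannot reveal which strand a dataset genotyped. The workflow
instead exploits *geographic replicates*: the same population sampled by two
datasets, whose allele frequencies must agree up to binomial sampling noise.

Calibration asks how often frequency comparison would mislabel a strand as a
function of minor allele frequency, measured on loci where the truth is
known — unambiguous loci, which are never strand-confounded after allele
reconciliation. Per locale, loci are folded to MAF orientation in the
reference dataset and binned cumulatively at MAF ≤ x for
x ∈ {0.05, …, 0.45}; the error rate at x is the fraction of binned loci
whose alternate-dataset frequency of the same allele exceeds 0.5.
Confidences (1 − error) are averaged across locales. The selected threshold
is the largest x with mean confidence ≥ the requirement (default 0.95) and
per-locale confidence strictly above it. Numerical choices: an empty
cumulative bin contributes error 0 (vacuous), and calibration errors out
only if every locale is empty at every grid value; bin membership uses
MAF ≤ x + 1e-12 to absorb float rounding. Loci with zero calls in either
replicate sample are skipped.

Resolution then classifies each ambiguous locus per locale: with threshold
t, frequencies below t or above 1 − t are "clear"; MATCHED means both
replicate frequencies clear on the same side, FLIPPED on opposite sides,
INCONCLUSIVE when either lies inside [t, 1 − t] or is undefined. The
interpretation of the threshold rule as symmetric around 0.5 is the only
reading under which it is well defined for frequencies of either allele.
Verdicts are combined per *alternate dataset* over that dataset's locales
(with a single alternate dataset this is exactly a per-locus consensus):
under the default strict rule a dataset is flipped only when every verdict
is FLIPPED and trusted only when every verdict is MATCHED; anything else
discards the locus. A `majority` option relaxes this to a majority of
conclusive verdicts (ties discard). Datasets with no replicate coverage are
trusted as-is with a warning — appropriate when they share a genotyping
protocol with the reference, which is the situation the workflow targets.
Corrections recode g → 2 − g for the flipped dataset's individuals; the
merged panel keeps the reference designation.

## Tiered locus QC and stage order

* **Missingness** (per locus, within sampling locations): rule A discards a
  locus whose call rate is ≤ 0.60 in at least one location; rule B discards
  one missing ≥ 15% of calls in more than five locations. The "call rate
  within location" reading of rule A is an interpretation choice,
  configurable thresholds throughout.
* **Hardy–Weinberg**: the exact conditional test per (locus, location) —
  full enumeration of heterozygote counts given allele counts, in log-gamma
  arithmetic with a (1 + 1e-12) tie tolerance — is used at every sample
  size; it is O(n) per test and deterministic, so no Monte-Carlo variant is
  needed. p-values are FDR-adjusted jointly across *all* tests
  (Benjamini–Hochberg, π₀ = 1, conservative); a locus is discarded when
  q ≤ 0.05 in more than three locations. Locations with fewer than two
  called individuals are skipped and recorded.
* **Replicate F_ST screen**: per replicate pair, per-locus Weir–Cockerham
  theta between the two samples; loci at or above the empirical 95th
  percentile (linear-interpolation quantile, ≥-inclusive so ties are kept)
  form that pair's outlier set, and loci in more than one set are discarded.
  Undefined thetas are excluded from the quantile population; fewer than 20
  defined loci triggers an instability warning. Because the screen is
  relative, it removes a background of upper-tail coincidences (≈ n · C(k,2)
  · 0.05² loci for k pairs) even on perfectly clean data; that is inherent
  to the published rule, not a defect.

Stage order: intersect → missingness → HWE → strand calibration →
strand resolution → replicate-F_ST screen → merge. The screen runs *after*
strand correction by default because an uncorrected flip produces an extreme
replicate F_ST, so screening first would discard precisely the loci the
correction rescues; HWE and missingness are invariant under g → 2 − g, so
their position is immaterial. A `fst_screen_before_strand` switch restores
the narrative order for comparison. Every candidate locus receives exactly
one final status (RETAINED/DISCARDED) in the QC ledger, with the first
failing rule recorded as the cause; loci private to one panel or with
irreconcilable allele pairs are ledgered as NOT_SHARED.

## Statistics

* Heterozygosity: Ho = n_het/n_called, He = 2p(1−p), unbiased
  uHe = He · 2n/(2n−1); location means are unweighted over loci with at
  least one call.
* Weir–Cockerham (1984) variance components with the observed-heterozygosity
  term, general r, unequal sample sizes; theta is UNDEFINED only when
  a + b + c = 0 (samples monomorphic for the same allele), negative values
  are reported unclamped, and multi-locus estimates are ratios of sums.
* Mantel test on F_ST/(1 − F_ST) (Rousset linearization; requires all
  F_ST < 1) versus supplied distances: Pearson r of upper-triangle vectors,
  permutation p with the +1 correction, one-tailed "greater" by default
  since isolation by distance predicts positive correlation. When the
  requested permutations cover the full group (n ≤ 8), the test enumerates
  all n! permutations, which the +1-corrected sampled p equals when sampling
  the n! − 1 non-identity permutations exactly once.
* Welch's t (scipy, Satterthwaite df); degenerate zero-variance/equal-mean
  input raises. The CLI's regional comparison contrasts within-region versus
  between-region multi-locus pairwise F_ST values.

## Synthetic data generator

The generator emulates a multi-consortium synthesis with known truth:

* **Divergence**: Balding–Nichols — population frequencies Beta-distributed
  with mean p and variance F·p(1−p) — chained along a line of demes (one BN
  step per deme, frequencies clipped to [0.001, 0.999] to avoid fixation
  degeneracies), giving parametric F_ST that grows with separation and a
  distance matrix |i − j| · step_km. An optional two-refugia mode splits the
  line in half, each half expanding outward from its own refugium.
* **Datasets**: demes are divided into contiguous west-to-east blocks, one
  per dataset, reference westernmost. Every replicate locale is a deme of
  the reference block re-sampled independently by the reference and by
  *each* alternate dataset, so each dataset's strand convention is checked
  at all locales — the way the empirical design calibrates one dataset pair
  at three locales.
* **Genotypes**: binomial(2, p) per individual (HWE within locations); an
  `inbreeding_f` switch reduces heterozygote probability by (1 − f) to
  exercise the HWE filter.
* **Strand flips**: per non-reference dataset, a fraction of ambiguous loci
  get dosages recoded g → 2 − g and alleles complemented, recorded in the
  truth ledger. Ambiguous loci are drawn from the low-MAF stratum (ancestral
  MAF ≤ `ambiguous_maf_max` = 0.35) and their frequencies at replicate demes
  are fold-clipped to that MAF, because flips near 0.5 are *inherently*
  unresolvable by frequency comparison — the generator models the resolvable
  regime the correction procedure is designed for, and the threshold rule
  itself discards the rest.
* **Ascertainment**: loci with MAF below a floor in the discovery deme are
  dropped before genotyping, reproducing the diversity gradient that panel
  discovery in one corner of the range imposes: mean observed
  heterozygosity declines with distance from the discovery population.
* **Missingness**: independent per dataset at its configured rate.

All draws come from one `numpy` generator seeded by the config, in a fixed
documented order, so identical configs give byte-identical panels. The
parametric pairwise F_ST recorded in the truth ledger is the
infinite-sample limit of the two-population Weir–Cockerham estimator at the
realized frequencies, Σd²/2 over Σ(p̄(1−p̄) + d²/4).

**Defaults as study conditions**: 1,000 shared loci, 3 datasets, 12 demes,
40 individuals per location, 20% ambiguous loci with 50% of them flipped
per alternate dataset, 3 replicate locales, per-step F = 0.02 (low marine
divergence: replicate-pair F_ST ≈ 0.01, range-wide end-to-end ≈ 0.1–0.2),
2% missing data per dataset, step 100 km.

What the generator does *not* emulate: linkage/LD and chromosomal
inversions, selection, coalescent genealogies, overlapping individuals
between datasets, genotyping-batch artifacts beyond strand flips and
missingness. Passing tests therefore demonstrate correctness of the
harmonization logic and estimators under idealized panmictic sampling, not
robustness to every failure mode of real array data.

## Validation scales and known limitations

The test suite validates: strand-flip recovery (default scenario, 20 seeds:
every injected flip is corrected or discarded, ≥ 95% corrected) and
false-flip control (50 clean seeds, ≤ 1%); the F_ST estimator against an
independently coded brute-force implementation (1,000 random configurations,
1e-12) and against parametric truth (±0.02 at 500 loci, n = 50); the HWE
test against full rational-arithmetic enumeration for every configuration
with n ≤ 50 and for null calibration (10,000 loci); the Mantel test against
exhaustive enumeration on 5 labels, for type-I error (1,000 null
replicates) and for power on stepping-stone gradients (100 seeds); filter
boundary fixtures; and 100-panel I/O round trips. These sizes were chosen
to make the checks statistically decisive while keeping the suite fast.

Known limitations: locus matching is by identifier only (no positional
liftover); multi-allelic sites, phased data and PLINK formats are out of
scope; imputation and sample-level QC (duplicates, relatedness) are not
attempted; distances are always supplied, never computed from coordinates.
On real data the false-flip rate depends on how well replicate locales
approximate single panmictic populations — residual structure between the
paired samples inflates apparent mismatch and lowers the calibrated
threshold, which is the conservative failure direction.
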