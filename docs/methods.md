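# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical corner cases. All thresholds named here are
function parameters; nothing is hard-coded.

## Enrichment against the no-antibody control

For each replicate pair, the fold change is pulldown intensity over control
intensity; a protein is enriched when the fold change strictly exceeds
`min_fold` (default 2) in **every** pair. Two deliberate conventions:

* A zero control intensity with positive signal yields fold `+inf` and
  passes — absence from the no-antibody background is the strongest possible
  evidence of antibody-dependent recovery.
* A protein undetected in any pulldown replicate is never enriched, but it
  still participates in abundance ranking if detected anywhere. The source
  material is silent on this case; the choice is an interpretation and is
  pinned by tests.

Abundance is the **sum** of intensities across pulldown replicates (summed
MS peak area). Sum and mean rank identically with equal replicate counts,
and the sum degrades gracefully when one replicate misses a protein. Rank
ties are broken by lexicographic protein id so every ranking is
deterministic. The bait QC pass flag (bait and ≥ 1 histone within the top
`top_k` = 10 ranks) is advisory; an undetected bait is a reported status,
never an exception.

`precision_against_reference` reports `100 · |enriched ∩ reference| /
detected` to one decimal. Two printed-arithmetic quirks are documented
rather than forced: 232/6,500 computes to 3.6% where 3.5% is conventionally
quoted, and 156/1,232 computes to 12.7% where 12.5% is quoted; 365/407 gives
89.7%, quoted as 90%. The implementation reports the computed value.

## Specificity scoring

Annotated proteins are resolved to one effective class by precedence
(bait > known_interactor > histone > chromatin_dna_binder > ribosomal >
ribonucleoprotein > affinity_reagent > cytoplasmic_other, then any custom
classes in sorted order); unannotated proteins form the `unclassified`
class, so the effective assignment is always a partition. The dedicated
`bait` class has top precedence and is excluded from both the PTP and PFP
sums (the bait's own huge intensity would otherwise dominate the interactor
fraction) while still counting toward the normalizing total; callers can
override `ptp_classes`/`pfp_classes` to fold it in.

Class fractions are intensities summed per class divided by the total
intensity of the same samples — unclassified proteins therefore dilute both
PTP and PFP fractions, as a whole-sample normalization should. The
specificity ratio `ΣPTP / ΣPFP` is `+inf` when no PFP signal exists and an
error when both sums are zero; it is invariant under any uniform intensity
rescaling (tested).

Cumulative rank–class curves are emitted both as prefix counts and as
within-class fractions, because the axis convention of such plots varies; a
declared class with no detected member yields a zero curve with undefined
(NaN) fractions.

## SILAC differential binding

Replicate ratios are `log2(heavy/light)` with heavy = 2iL and light =
serum; a pair with either channel undetected yields no ratio. Ratios are
median-centered per replicate by default (standard SILAC practice to remove
mixing-ratio offsets). The test is a two-sided one-sample t against 0 with
BH adjustment across tested proteins and significance at adjusted p ≤ 0.1
(non-strict, matching the quoted threshold). Proteins with fewer than
`min_replicates` = 2 ratios are left untested and excluded from BH. Zero
variance with nonzero mean is reported as the smallest representable
p-value with a `zero_variance` flag instead of a crash or a silent 0.

**Variance moderation.** With 2–3 replicates the plain t-statistic is
dominated by its 1–2-df variance estimate: at a planted |log2 effect| of 2,
σ = 0.3 and n = 3, its BH-level sensitivity is ~0.6–0.7 no matter how clean
the data, because the chi-squared noise of s² outweighs the signal. The
`moderate_variance` flag therefore shrinks per-protein variances toward the
across-protein median with a fixed prior weight (`prior_df` = 4), crediting
`prior_df + n − 1` degrees of freedom — the standard empirical-Bayes remedy
for few-replicate designs. Plain t remains the default so the stated test
is what runs unless asked otherwise; the recovery analyses and the
end-to-end pipeline enable moderation, which is the recommended setting.

Ratio-matrix clustering is agglomerative average linkage on correlation
distance over both axes (both distance and linkage selectable). Missing
cells are imputed with 0 (no change) for the distance computation only,
with the mask recorded — imputation never feeds the significance tests. A
constant row/column under correlation distance (undefined correlation)
triggers a flagged fallback to Euclidean distance for that axis. Leaf
orders are deterministic given the input order.

## Genomic occupancy

All intervals are 0-based half-open; touching intervals do not overlap. The
overlap counter uses a per-chromosome sorted sweep (prefix-maximum of ends
for the ≥ 1 bp case, exact windowed computation for larger `min_bp`) and is
property-tested against an all-pairs oracle. Chromosomes present in only
one set are warned about and treated as non-overlapping. Because it is
unstated whether a quoted peak-set overlap is peak-count or base-pair
based, both are reported: per-set overlapping-interval counts and a merged
base-pair Jaccard index.

Superenhancer colocalization reports whole-number percentages (88 of 142
→ 62%); an empty superenhancer set yields "not applicable" rather than a
division error. Top-N concordance ranks by one method's enrichment (ties
broken by chrom, start), and counts peaks whose other-method enrichment is
strictly below the fold threshold.

Differential occupancy tests log2 normalized counts with Welch's t and BH;
a region is preferential for a condition at adjusted p < FDR (strict) and
linear fold > `min_fold` (strict) in that direction, making the two
preference flags mutually exclusive. Normalization uses **median-of-ratios
size factors** rather than raw totals: when a subset of regions shifts
strongly in one condition, total-count scaling transfers that shift to
every null region (composition bias) and produces spurious calls in the
opposite direction; the median ratio against a geometric-mean reference is
robust to it.

Gene proximity uses the distance from a TSS to the nearest covered base,
`d = max(0, start − tss, tss − (end − 1))`, zero inside the peak, with the
strict `d < 10 kb` rule. Strand is used only to locate the TSS.

## Knockdown differential expression and genetic interaction

DE testing: log2(CPM + 1), Welch t per gene against the control group, BH
across genes, DE at adjusted p < 0.01 and |linear fold| > 1.5 (both
strict). Genes with zero counts in both groups are untested. The same
moderated-variance option applies, here with a **trended prior**: the prior
variance is the median s² within quantile bins of mean log abundance, since
count data have a mean–variance relation and a single global prior would
shrink low-count genes toward a too-small variance (inflating their t). The
degrees of freedom are capped at `prior_df + n_a + n_b − 2`; the prior is
shared information, not fresh per-group observations, and crediting it
twice makes the test anticonservative (verified against null simulations).

The genetic-interaction classifier takes the single-knockdown DE genes as
targets and computes `r = Δ_double / Δ_single` on **log2** changes (the
scale makes the ratio symmetric for up- and down-regulated targets; the
classifier is invariant to flipping all signs, tested). The independence
band is `[0.5, 1.5]` inclusive — no published thresholds exist, so the
default sits midway between the generator's planted antagonistic ([0, 0.4])
and synergistic ([1.6, 2.5]) ranges, keeping generator truth and classifier
tuning separated; the band is a parameter. Sign-flipped double-knockdown
effects (r < 0) are antagonistic: rescue beyond baseline is the extreme of
attenuation.

## Synthetic data model

* **Quant tables**: log10 intensity ~ Normal(μ_base + log10 factor(class),
  σ_rep), censored to 0 below a detection limit. Defaults: μ_base = 6 (MS
  intensity scale 10⁶), σ_rep = 0.15 (≈ 1.4× typical replicate scatter),
  detection limit 10⁵. The clean profile enriches histones 30×, interactors
  and chromatin binders 8×, bait 100×, reagents 0.5×; the contaminated
  profile raises ribosomal/RNP to 8× and the affinity reagent to 50× while
  halving chromatin enrichment — the qualitative contrast between a washed
  DNA-capture protocol and a bead digest. Control samples reset the
  antibody-driven classes (bait, interactors, chromatin binders, histones)
  to background. Peptide counts are a deterministic monotone function of
  intensity (0 iff censored), sufficient for contamination accounting.
* **SILAC ratios**: Normal(planted effect or 0, σ_rep = 0.3) with effects
  drawn uniformly from |log2| ∈ [2, 4] with random sign; 50 of 500 proteins
  differential by default.
* **Peaks**: non-overlapping locus grid; exactly round(fraction · n_A)
  A-peaks receive an overlapping B-peak and round(fraction · n_SE)
  superenhancers contain an A-peak, so overlap truths are exact by
  construction. Superenhancer anchors avoid B-anchored loci when possible,
  keeping the superenhancer and enhancer sets disjoint.
* **Counts**: gamma-Poisson (negative-binomial) with a single dispersion
  (default 0.05, a typical RNA-seq biological CV² for cell lines) over
  baselines log2-uniform in [5, 12]. Knockdown targets respond with
  ±effect_log2 (default 3 — a strong direct-target response comfortably
  above the fold-1.5 filter); the double knockdown scales that by the
  planted ratio. The planted label split follows the observed 73.4/18.1/8.4%
  independent/antagonistic/synergistic proportions (renormalized to sum
  to 1).

What the generators do **not** emulate: peptide-level quantification and
protein inference, intensity-dependent missingness (censoring is a hard
threshold), correlated contaminant structure across classes, p53-specific
targets in the kd_P arm, chromosomal covariates of peaks (GC, mappability),
and any real genome coordinates. Passing tests therefore demonstrate the
statistical machinery under the stated noise models, not performance on
real instrument data.

## Problem sizes and determinism

The end-to-end pipeline runs at 500 proteins, 500 SILAC proteins, 500+500
peaks with 142 superenhancers, 1,000 regions, and 2,000 genes with 200
targets — sizes at which every planted quantity is recoverable and the
whole run completes in seconds. A single master seed is expanded into
independent child streams (numpy `SeedSequence`) for each generator;
identical seeds give byte-identical outputs, and all stochastic acceptance
checks are run at pinned seeds.

## Known limitations

* The moderated Welch df cap is an approximation; its calibration was
  verified empirically against null simulations (p < 0.05/0.01 rates within
  ~6% of nominal) rather than derived exactly.
* At FDR 0.05 with ~50 true discoveries, the *expected* number of false
  discoveries is ~2.5; single-seed false-call counts therefore fluctuate by
  a few either way even for a perfectly calibrated test.
* The BED dialect preserves extra columns positionally (`extra_1`, ...),
  not by name, as BED files carry no header.
* `filter_enriched` pairs pulldown and control samples by replicate index;
  designs with unequal replicate structure must pass an explicit pairing.
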