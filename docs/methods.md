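# Methods

This note records the statistical model behind each stage, the defaults
and why they are what they are, what the synthetic-study generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## The stability index

The average variation degree (AVD) treats the replicate samples of a
study as repeated draws of the same assemblage and asks how far each
sample scatters around the per-taxon means. For taxon *i* and sample
*k*, with relative abundances `x_ki`,

    a_ki = |x_ki − μ_i| / σ_i,          AVD_k = (1/m) Σ_i a_ki,

where μ_i and σ_i (n−1 denominator) are taken **across all samples of
the analysed table**, m is the number of retained taxa, and a taxon that
never varies (σ_i = 0) contributes 0. A group's AVD is the mean over its
member samples, and the stability index is −AVD: any strictly decreasing
transform preserves every between-group comparison, and the affine
choice keeps the units interpretable (one unit = one mean absolute
z-score).

The standardisation scope matters and was a genuinely open design
choice. Standardising *within* each group looks natural but makes the
statistic scale-free: for Gaussian noise the expected mean |z| is
√(2/π) ≈ 0.80 whatever the noise level, and for heavier-tailed noise it
*falls* (the MAD/SD ratio shrinks with kurtosis), so a noisier group
would score as more stable. Standardising across the table anchors each
taxon to one mean and one scale, so groups whose samples scatter more
widely get a larger AVD — which is the quantity a stability comparison
needs. To compare seasons within a single recovery group, pass that
group's samples as the table; the two flavours then coincide.

Taxa enter the AVD after a mean relative-abundance filter
(> 0.001% = 1e-5, strict inequality, mean over all samples): rare taxa
carry mostly counting noise. `variation_degree` itself takes an explicit
sample set, so callers can reproduce any scope they need.

## Indicator species and core taxa

IndVal is computed in its group-size-corrected form ("IndVal.g"): for
OTU *i* and a combination C of groups,

    A = Σ_{g∈C} m̄_ig / Σ_g m̄_ig      (specificity, group means)
    B = #{samples in C with count > 0} / |C|    (fidelity)
    IndVal = √(A·B)

maximised over all non-empty proper subsets of groups (an indicator may
mark one *or several* recovery periods). Group means rather than pooled
sums keep A honest under the unbalanced design (5 transects in the 20-y
group versus 3 elsewhere). Significance is by permutation of the
sample-to-group labels, p = (b+1)/(nperm+1) on the maximised statistic,
nperm = 999 by default with a mandatory seed; selection is at raw
p < 0.05 with no multiplicity correction (a BH flag exists as an
extension). The analysis runs on relative abundances, so per-sample
sequencing depth cancels by construction.

Differential abundance is a negative-binomial GLM likelihood-ratio test
on raw counts: log link, per-sample offsets log(library × TMM factor),
one common dispersion φ, full model one mean per group versus a pooled
null, statistic 2(ℓ_full − ℓ_null) against χ²(G−1). Means are fitted by
Fisher scoring (score Σ(y−μ)/(1+φμ), 50 iterations, step tolerance
1e-10, clipped steps, closed-form fallback with a warning); φ is the
median of per-OTU method-of-moments estimates
Σ((y−μ̂)²−μ̂)/μ̂² / (n−G) from a Poisson pre-fit, floored at 1e-8. An
explicitly supplied φ = 0 runs the exact Poisson deviance limit. The
full tagwise/trended shrinkage machinery of count-RNA-seq packages is
intentionally out of scope; a common dispersion captures the defined
computation at this scale. The log-likelihood keeps only μ-dependent
terms (the Γ terms cancel in the ratio) and uses log1p so the small-φ
limit is numerically exact.

TMM factors follow the canonical weighted, doubly trimmed recipe:
reference = sample whose upper-quartile/library ratio is closest to the
mean ratio; M- and A-values on shared-positive taxa; trim 30% of M each
tail and 5% of A; precision-weighted mean M; factors rescaled to
geometric mean 1. The implementation reproduces `calcNormFactors` to
machine precision (a cross-check against edgeR via Rscript is part of
the suite). Note the precision weights are not scale-free: multiplying a
column by c rescales only the observation half of each delta-method
weight, so the normalised profile of a scaled duplicate matches the
original only to ~1e-3 relative — a property of the statistic, not a
bug.

Core taxa are the OTUs significant in both analyses; bipartite edges
connect each significant indicator to every group in its best
combination.

## Co-occurrence networks

Spearman correlations (average ranks for ties) between TMM-CPM profiles
across all samples; two-sided p from t = ρ√((n−2)/(1−ρ²)) with n−2 df —
at n = 168 an exact permutation p adds nothing at the 0.001 threshold.
Edges require ρ > 0.7 and p < 0.001, both strict, positive correlations
only; nodes are the OTUs incident to at least one edge. Seasons are
pooled by default (restrict the input table to analyse one season).

Modules come from Clauset–Newman–Moore greedy modularity maximisation on
the unweighted thresholded graph (edges are near-binary after ρ > 0.7; a
weighted Q is available via the stored ρ weights). Module ids are
assigned by decreasing size with lexicographic tie-break, so labels are
stable run to run. The reported Q is recomputed from the returned
partition. Keystone taxa are the top `max(1, floor(0.01·n))` nodes by
degree — flooring matches the convention that 1% of a 2394-node network
is 22-23 nodes — with boundary ties broken by higher total relative
abundance, then id. Module "core abundance" series sum the relative
abundances of each module's core-taxon members per sample; the top four
modules by that measure are flagged.

## Diversity and the association layer

Faith's PD is the branch-length sum of the minimal subtree spanning the
present tips and the root (stem and any root-edge length included; a
crown-only flag subtracts the stem), checked against scikit-bio's
implementation. ANOSIM runs on Bray–Curtis dissimilarities of relative
abundances: R = (r̄_between − r̄_within)/(M/2) on ranked distances, label
permutations with an explicit seed (the in-house implementation exists
precisely so the permutation stream is seedable; scikit-bio's R
statistic is the cross-check). One-way ANOVA is the classical F test.

Association fits (stability vs PD, vs accumulated indicator / core /
keystone abundances, vs module core series) are least-squares linear and
quadratic polynomials computed on centred x and reported on the raw
scale, with R² = 1 − SSE/SST and an overall F test. Fits run on
group × season mean cells (12 units under the default design) so each
point summarises one study cell rather than pseudo-replicating samples.

## The synthetic-study generator

The generator emulates the *statistical structure* the analysis assumes,
with ground truth for scoring:

- Design: ages {10, 20, 30, 40} y with {3, 5, 3, 3} transects, 3 seasons
  (level/wet/dry), 4 samples per transect ⇒ 168 samples; 600 bacterial
  plus 250 fungal OTUs with QIIME-style lineages weighted toward the
  phyla that dominate wetland rhizosphere surveys; a pure-birth random
  tree over all OTUs (dendropy).
- Baseline log-abundances are Normal(0, 1.5) — a moderately uneven
  community; the exact unevenness is a free choice and only the planted
  contrasts are load-bearing.
- Indicators: 30 OTUs per age (disjoint sets, drawn outside the
  modules), multiplied by fold-change 8 in their target group.
- Modules: 4 kingdom-pure blocks of 25 OTUs (3 bacterial, 1 fungal, so
  cross-kingdom module membership never confounds the kingdom splits);
  members share an additive per-sample latent Normal(0, 1) log-factor,
  which induces positive rank correlation, and get a +2 natural-log
  baseline boost because core taxa are the abundant ones — low-abundance
  members would drown the latent signal in counting noise.
- Noise: expected proportions are perturbed per sample by independent
  gamma multipliers with mean 1 and variance φ(age)
  (0.8/0.4/0.25/0.2 for 10/20/30/40 y, strictly decreasing), then a
  multinomial draw at a Normal(5·10⁴, 10⁴) library size (floored at
  1000). Overdispersion rather than mean shifts encodes the stability
  gradient because AVD measures scatter around per-taxon means; column
  sums equal the drawn library sizes exactly.

What the generator does **not** emulate: phylogenetic signal in
abundances (the tree is independent of the count model), seasonal mean
shifts, spatial/transect autocorrelation, chimeras or sequencing error.
Passing tests therefore demonstrate that the statistics recover planted
compositional structure under realistic overdispersion — not that they
are robust to every artefact of real amplicon data.

One master seed drives everything; per-stage child seeds are derived by
fixed offsets (simulate +0, IndVal +11, ANOSIM +13, annotation +17,
modulo 2³¹) so a stage rerun reproduces the full-pipeline stream, and
reruns with the same configuration are byte-identical (fixed float
formatting, sorted node/edge emission, no timestamps).

## Problem sizes and known limitations

- The calibration check of the NB-LRT uses 4 × 12 samples, 500 OTUs with
  lognormal(4, 1) mean counts: moderately expressed taxa, where the
  χ²(G−1) reference is adequate. At very low means (μ < a few counts)
  the test is mildly liberal, as for any asymptotic LRT, and the common
  dispersion's median-of-moments estimate sits a few percent below the
  truth because the per-OTU estimator is right-skewed.
- Planted-structure recovery is scored over 20 seeds with nperm = 199
  for the indicator permutation test (p resolution 0.005, ample at
  α = 0.05); the full default nperm = 999 is used in the pipeline.
- Keystone sets at desk scale contain a single node (1% of a ~100-node
  network), so the keystone-abundance-vs-age trend is reported (by
  `scripts/acceptance.py`) but too noisy at this problem size to assert
  as an invariant; across seeds its sign is positive more often than
  not.
- "Network width" appears in the surrounding literature without a
  definition; the package reports mean degree and the degree histogram
  and claims neither as that metric.
- Empty taxon sets give PD 0 with a warning; constant OTUs are excluded
  from correlation networks with a single warning; an edgeless network
  is a hard error for module detection (no modular structure is defined).
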