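# Methods

`hzmove` infers whether a hybrid zone between two parapatric taxa has moved,
and whether adaptive introgression contributed to the movement, from three
mutually reinforcing analyses: geographic cline fitting (genetic vs
morphological), genomic cline outlier classification crossed with geographic
coincidence in a contingency test, and variance partitioning of two-locus
linkage disequilibrium along the transect. A phased individual-based
simulator provides no-selection reference dynamics under contrasting
divergence histories. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Geographic clines

A cline describes the change of an allele frequency or trait mean along a
one-dimensional transect (great-circle distance from the southernmost
population, haversine on a 6,371-km sphere). The core shape is

    p(x) = pmin + (pmax - pmin) · (1 + tanh(2(x - c)/w)) / 2

with centre `c` (km) and width `w` (km, inverse of the maximal slope).
Exponential tails may replace the sigmoid beyond `c - δ_L` and `c + δ_R`,
joining it continuously with decay rate `4τ/w`, `τ ∈ [0, 1]` (the
HZAR-compatible convention). Five tail modes (none, left, right, mirror,
independent) crossed with three scaling modes for frequency responses
(`pmin`,`pmax` fixed at 0/1, fixed at the observed deme extremes, or
estimated) give the 15-model frequency family; trait clines use the five
tail modes with estimated asymptotes. The hybrid-index cline is fitted with
the same 15-model family under the Gaussian population-mean likelihood.

Likelihoods: binomial per-population allele counts (cline value clipped to
`[1e-9, 1 - 1e-9]`) or Gaussian population means with standard error
`sd/√n`. Decreasing trait clines are negated before fitting (centre and
width are invariant to the flip).

Fitting is random-walk Metropolis–Hastings with per-parameter bounds:
`c ∈ [x₀ - 0.25L, x₀ + 1.25L]` (L = transect length; centres beyond L are
possible and flagged downstream), `w ∈ [L/(n-1), 3L]`, `δ ∈ [0, L]`,
`τ ∈ [0, 1]`. The lower width bound is an identifiability constraint:
clines narrower than the inter-population spacing cannot be resolved by the
sampling design. Proposal scales adapt during burn-in toward ~30%
acceptance. Replicate chains run with distinct seeds; the MLE is the best
visited state polished by bounded L-BFGS-B. Convergence is flagged (never
fatal) when per-chain best centres spread more than 5% of the pooled centre
interval (floored at 1% of the transect, since flat-topped profiles make
tiny interval widths meaningless as a yardstick).

Approximate 95% confidence intervals are ±2 log-likelihood units (2 LLU)
around the MLE. Rather than reading the interval off the chain's visited
states — a noisy lower envelope of the true profile that systematically
under-covers — nuisance parameters are re-optimised on a grid spanning the
chains' explored range and the resulting profile is interpolated linearly at
the 2-unit threshold. Sides that never drop 2 units are reported at the
explored bound and flagged unbounded.

Model selection uses AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with n = number of
populations (observations are population-level records). Every family is
compared against a no-cline null (constant frequency, k = 1; constant trait
mean, k = 2 by the trait-family convention); the minimum-AICc model wins and
ties go to the fewer-parameter model. Per-SNP scans run the same sampler
vectorised across loci sharing the transect positions, refining only each
locus's winning model.

A calibration caveat, measured rather than assumed: for genuinely flat
(i.i.d. binomial) loci on 30 populations of 40 alleles, best-of-15-vs-null
selection picks the null for roughly 90% of loci, not ~100%. The observed-
and estimated-scaling members can absorb changepoint-like chance trends at a
cost of only ~2.3 AICc units over the null. This is a property of the model
family itself, and the exclusion of null-best loci downstream is exactly why
the workflow tolerates it.

## Hybrid index and genomic clines

The hybrid index h (proportion of northern-parental ancestry, the Q-score
analogue) is supervised maximum likelihood against parental reference
frequencies: allele dose at locus l ~ Binomial(2, h·pB_l + (1−h)·pA_l),
maximised over h ∈ [0, 1] by grid-plus-bounded refinement, with a 2-LLU
support interval from the grid profile. All loci with distinct parental
frequencies contribute, mirroring the use of the full SNP panel (not only
the nearly diagnostic subset) for global admixture estimation.

The genomic cline of a locus is φ(h) = h + 2h(1−h)(α + β(2h−1)), clamped to
[0, 1]; α > 0 marks excess northern-parental ancestry. Per-locus (α, β) are
sampled by Metropolis–Hastings over hybrid-zone individuals with independent
Normal(0, 0.5²) priors — a deliberate simplification of the full
hierarchical Bayesian genomic-cline model, whose hierarchical variances are
not recoverable here. Outliers are loci whose 95% equal-tailed credible
interval for α excludes zero. Because the prior shrinks toward zero, power
against moderate |α| is limited at ~100–200 hybrid individuals; the planted
end-to-end scenario uses effect sizes large enough to be detectable under
exactly this estimator.

## Diagnostic SNPs and the contingency test

Nearly diagnostic SNPs are those at or above the 0.90 type-7 empirical
quantile of |Δp| between the pure parental groups (ties kept, so slightly
more than 10% can be retained). Each retained SNP is classified on two axes:
geographic (excluded if the null model won or the centre exceeds the
transect length; otherwise overlap with the hybrid-index centre interval,
with the union of the trait centre intervals, or neither — double overlaps
resolve to the nearer interval midpoint with a warning) and genomic (α
outlier class). The 3×3 table is tested by Pearson chi-square without
continuity correction at α = 0.01, reporting each cell's percentage
contribution 100(O−E)²/E/X² and the sign of O−E.

## Ohta's D variance partitioning

For a locus pair in a set of subpopulations with gamete frequencies g_ij(k),
marginal allele frequencies x_i(k), y_j(k), and unweighted means over
subpopulations (bars):

    D²_IS  = E_k[Σ_ij (g_ij(k) − x_i(k) y_j(k))²]
    D²_ST  = E_k[Σ_ij (x_i(k) y_j(k) − x̄_i ȳ_j)²]
    D²'_IS = E_k[Σ_ij (g_ij(k) − ḡ_ij)²]
    D²'_ST = Σ_ij (ḡ_ij − x̄_i ȳ_j)²
    D²_IT  = E_k[Σ_ij (g_ij(k) − x̄_i ȳ_j)²]

with the identity D²_IT = D²'_IS + D²'_ST holding exactly under equal
weights. Populations are tiled into overlapping windows (default four per
window, overlap one; 34 populations give exactly 11 windows; non-divisible
counts append a truncated, flagged window). Within a window, locus pairs are
uniformly subsampled (seeded, without replacement, default cap 50,000) and
the profile reports mean D²_IS, mean D²_ST and their ratio of means (the
stabler convention; mean-of-ratios is available by flag), with the ratio
undefined below a 1e-12 denominator. The statistics are gametic: true phase
is used when present; for unphased genotypes two-locus gamete frequencies
are estimated per subpopulation by EM under random mating. Bootstrap panels
of non-diagnostic loci (default 20 resamples) provide the neutral reference
profile. Mean D² values at these sample sizes include a finite-sample floor
of order (p(1−p))²/2n per pair; profiles should be read as contrasts along
the transect, not absolute LD levels.

## Individual-based simulator

A one-dimensional column of patches holds southern parental, hybrid-zone and
northern parental bands. Monoecious diploids carry unlinked biallelic loci
(100 diagnostic by default, initialised as fixed differences between the
parental groups — divergence is matched at initialisation rather than
evolved, guaranteeing informative loci at analysis time); there is no
selection and no age structure. Each non-overlapping generation applies
reproduction (random mating with selfing, Mendelian transmission,
Poisson offspring with Beverton–Holt expectation n·r/(1+(r−1)n/K), r = 2),
dispersal, and random truncation to the carrying capacity K.

Dispersal has a within-band nearest-neighbour component (0.10/generation,
split between neighbours) and an among-group component set by the phase:
Phase I (divergence) has zero exchange under the secondary-contact model A
and 0.002/generation parental exchange under the gene-flow model B (low
enough that the diagnostic differential survives the phase); Phase II opens
the middle band to colonisation from the southern parental only; Phase III
begins its scenario regime once every middle patch reaches 50% of K —
(i) bidirectional dispersal with both parents, (ii) with the northern parent
only, (iii, model B only) both parents at half rate; Phase IV restricts all
scenarios to hybrid↔northern exchange. Among-group migrants settle with
exponential distance decay (e-folding 100 km): uniform settlement would
erase spatial structure inside the hybrid band and make the mean hybrid
index a step function that no cline model can track. Patch counts, K values
(hybrid patches half the parental K) and rates are package assumptions at
desk scale — 10 patches per group, K = 50/25/50, phases 150/20/200/130
generations by default — chosen so the scenario contrasts are resolvable;
they are not calibrated to any empirical system.

Differentiation uses three-level unbalanced nested ANOVA on allele
indicators, components summed across loci: F_CT = σ²_groups / σ²_total and
F_ST = σ²_pops-within-groups / (σ²_pops-within-groups + σ²_within), the
among-population-within-group convention. Monomorphic data yield NaN.
Cline-centre tracking computes per-individual hybrid indices against the
current parental-group frequencies (loci eroded below |Δp| = 0.2 are
dropped), fits per-patch means with the fixed-0/1 mirror-tail model, and
records the centre (missing when convergence is flagged).

## Synthetic data generator

The generator emulates the sampling design the analyses assume: 5 + 16 + 13
populations of 3–10 individuals in south/centre/north latitude bands of a
2,000-km transect, thousands of biallelic SNPs with a Balding–Nichols
background (dispersion `fst_noise`) and a planted fraction of near-fixed
parental differences, two Gaussian traits on a sigmoid cline, and
two-ancestry mosaic hybrids. Each hybrid individual draws an admixture
proportion q ~ Beta around the sigmoid expectation at its position
(concentration interpolating south→north, so within-population ancestry
variance can rise toward an expanding front), then every haplotype of every
locus draws ancestry Bernoulli(q) — admixture LD without a linkage map.
Individual-level spread is suppressed where the expected ancestry is outside
(0.05, 0.95): the Beta tail would otherwise plant spurious F1-like outliers
in effectively pure edge populations. An optional fraction of northern-edge
individuals are recent lower-ancestry immigrants (the expanding-front
signal).

Planting hooks, all off by default, embed a known truth for end-to-end
validation: position-shifted locus classes south/north of the genome-wide
centre, and an "adaptively introgressed" class carrying excess
northern-parental ancestry either through the genomic-cline map φ(q, α) or
through a uniform penetrance (1 − (1−π)(1−q), optionally ramped along the
transect). The planted end-to-end scenario uses a broad admixture gradient
(cline width 500 km across an 1,100-km hybrid band) with the penetrance
mechanism (π = 0.25): the linear ancestry lift leaves the sigmoid inflection
— which is what both the per-SNP scan and the hybrid-index fit estimate —
in place, so introgressed loci remain geographically coincident with the
hybrid-index centre while their dose exceeds the genome-wide expectation at
every hybrid index, the positive-α signature. Two structural facts motivated
this design: under a single-hybrid-index generative model, a locus planted
by *shifting its position* to sit on the Q centre is, by that very
alignment, neutral to the α estimator; and a steep cline concentrates all
frequency transitions into one window, spiking D²_ST there and masking the
northward D²_IS rise.

What passing tests on this generator do and do not show: they demonstrate
that the full pipeline detects a three-part movement signature —
non-coincident genetic and trait centres, enrichment of Q-coincident
positive-α loci, and within-population LD rising toward the northern zone
edge — when that signature is truly present at realistic sampling depth.
They do not show performance under missing data, genotyping error, linked
loci, or locus-specific evolutionary histories richer than the mosaic model;
in particular, real data can decouple a locus's geographic centre from its
genomic-cline α in ways the mosaic model cannot (a genuinely south-shifted
steep locus is always an excess-northern-ancestry locus here, so the
combination "morphologically coincident and negative-α" cannot be planted).

## Problem sizes

Default test and validation sizes: cline recovery at 30 populations × 40
alleles with 10,000-step chains after 2,000 burn-in (3 replicate chains);
null-model calibration on 100 loci against the full 15-model family;
genomic-cline calibration at 200 individuals × 100 loci; contingency
calibration on 10⁴ tables of 2,000 draws; simulator contrasts at 10
patches/group, K = 50, 500 generations, 6 replicates; the end-to-end
scenario at 34 populations × 1,200 loci. These sizes make every stochastic
check reproducible in minutes while keeping each estimator in the regime
where its asymptotics hold.
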