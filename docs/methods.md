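# Methods

This note documents the statistical models, numerical choices, and open
design decisions behind the package, and what the synthetic-data tests do
and do not demonstrate about real data.

## Setting

Three species on a rooted ultrametric tree ((SH, SP), SL): branch *a* is
the SL terminal, *b* the internal stem shared by SH and SP ("early"),
*c* and *d* the SH and SP terminals ("late"). Hybrid sterility QTL mapped
in the SH×SL and SP×SL introgression-line crosses each tag one side of a
Dobzhansky–Muller incompatibility (the donor allele); the pipeline infers
on which branch the underlying mutation arose and how such mutations
accumulate with divergence.

## Allelism tests

**Model.** For each locus, `value ~ genotype + genotype:maternal_family`
is fit by OLS (fixed effects; maternal family nested within genotype),
with type-I ANOVA F-tests for both terms. Maternal effects are modelled as
fixed because the design is balanced and the reported quantity is an
F-test p-value; in the packaged scenarios the maternal variance is small,
mirroring experiments where no maternal effect is detected.

**Contrasts.** All pairwise genotype contrasts use the Tukey–Kramer
studentized-range test at family-wise α = 0.05, with the *nested* model's
residual mean square and degrees of freedom (this is why the readily
available one-way Tukey implementation is not used). Significance is
rendered as a compact letter display via the insert–absorb algorithm;
letters are ordered by descending mean so the most fertile class is 'A'.

**Classification.** The rule table operates purely on the letter display
(plus mean ordering), which is what makes the test valid for incompletely
recessive loci: only statistically supported differences count. One
deliberate refinement: "rescued" means *not significantly below SL* rather
than "shares a letter with SL". A trans-heterozygote can significantly
overshoot the SL mean under replication and is still fully rescued;
requiring letter identity with SL would misclassify such replicates.

**Effect sizes.** Δ% = 100·(m_IL − m_SL)/m_SL. For a composite locus the
shared allele's effect pools the two classes homozygous for it (IL_HH and
IL_HP); the additional lineage-specific effect is the multiplicative
residual, 100·(m_PP/pool − 1), so that applying the shared then the
additional reduction to SL reconstructs the IL_PP mean exactly. An
additive-residual variant (difference of Δ% values on the SL scale) is
available behind a flag.

## Placement

Each QTL is conservatively assumed to be underpinned by one mutation.
Unique QTL go to their cross's terminal branch; homologous pairs
contribute one mutation on *b*; composite calls contribute one on *b* and
one on the specific lineage's terminal; a lineage-specific call at a
co-localized position keeps the genuine instance and drops an instance
flagged as statistically confounded with pollen sterility. A parsimony
check (`derived_ancestral_check`) downgrades a *b* placement to
"possibly ancestral" when additional SL-sister crosses show a QTL at the
shared location.

The packaged inventory encodes 8 + 7 pollen QTL (one homologous pair) and
a seed inventory with one composite and one lineage-specific co-localized
pair plus five unique QTL. The per-cross split of the unique seed QTL is
not published; the package uses 3 (SH) + 2 (SP), giving seed counts
(1, 3, 4). Only totals and the early/late split feed the headline
results, but the split does interact with the *extrapolated-loci* variant:
terminal counts are inflated per branch by (1 + f), f = 1/3 by default,
and rounded to the nearest whole mutation (ties away from zero), so
(1, 3, 4) → late 9 while (1, 2, 5) would give 10. The chosen split is the
one consistent with the published extrapolated totals. Per-locus Δ% values
for the unique QTL are deterministic synthetic stand-ins (the per-locus
supplementary table is not machine-readable) and carry no weight in any
count-based result.

## Branch tests

* χ² goodness of fit of (n_early, n_late) against (N·p_early, N·p_late),
  df = 1, with a logged warning when an expected count falls below 5
  (which it does at N = 14 — the test is approximate at this scale, one
  reason the resampling test exists).
* Binomial resampling: the fraction of seeded Binomial(N, p_late) draws
  with at least the observed number of late mutations, iters = 1000 by
  default; the closed-form tail P(X ≥ k) is computed alongside as the
  oracle the simulation must converge to.
* Effect-size comparison: percentile 95% bootstrap CI (2.5/97.5) of the
  late |Δ%| values, resampled with replacement at the observed sample
  size, statistic = resample mean (a raw-values variant is available; the
  choice of statistic is not dictated by anything upstream). Comparisons
  use magnitudes — a 47% fertility reduction is *smaller* than a 60% one —
  and the CI boundary is closed (a value exactly on it is inside).
  Branch-length uncertainty variants (equal branch lengths, SD-perturbed
  lengths) enter as alternative `BranchProportions` inputs, not separate
  code paths.

## Accumulation models

**Generative assumptions.** Substitutions arrive as a unit-rate (after
composite rescaling) Poisson process on branches of the clock-enforced
tree. A substitution participates in an observable incompatibility against
SL with probability proportional to its number of potential interaction
partners — the small-probability regime, in which per-branch counts of
participating mutations are independent Poisson and only rate×probability
composites are identifiable. That fixes the parameter counts: 1 (linear),
1 (DM), 2 (2+3), 2 (p_a≠p_d). SL-side substitutions enter through the
known t_a as the derived–derived partner budget; branch *a* itself carries
no observed counts because the introgression design only detects donor
alleles.

**Means.** With depth T, branch *b* spanning depth [0, t_b] and terminals
[t_b, T]:

* linear: μ_x = ρ·t_x;
* DM: μ_x = c·(T·t_x + (u₁² − u₀²)/2) — the integral over the branch of
  the per-substitution pairwise budget (T derived–derived partners on the
  SL lineage plus u derived–ancestral partners from its own lineage's
  earlier substitutions);
* p_a≠p_d: the same two integrals weighted separately by c_d and c_a;
* 2+3: the DM term with weight c₂ plus c₃·M3_x.

M3_x is the Monte-Carlo expectation (20 000 replicates by default, seeded
from the run configuration, cached per tree) of the number of three-locus
interactions *completed* by substitutions on branch x: each replicate
draws a unit-rate substitution history along the full root-to-tip path
through the branch plus an independent SL count K ~ Poisson(t_a), and the
i-th substitution contributes (i−1)·K derived–derived–derived trios plus
(i−1)(i−2)/2 derived–derived–ancestral trios. Attributing each trio to its
latest same-lineage member counts every trio exactly once and — unlike
counting every trio once per member — yields a triple column that is not
nearly collinear with the pairwise column, so (c₂, c₃) are identifiable
from three branch counts. Both counting conventions live in
`combinatorics`; the participation-per-member census backs the
enumeration tests.

**Likelihood and fitting.** ℓ = Σ_x [n_x ln μ_x − μ_x − ln n_x!] over
x ∈ {b, c, d}; μ_x = 0 with n_x > 0 returns −∞ with a warning. Because
every μ is linear in the parameters the log likelihood is concave;
L-BFGS-B with nonnegativity bounds, a moment-matched start and four
additional seeded random starts (ftol 1e−12) is ample. AIC = 2k − 2ℓ per
tree; over a tree set the mean and SD of AIC are reported and parameter
estimates come from the median-AIC tree. Ties in model selection break
toward fewer parameters, then the fixed order linear, DM, 2+3, p_a≠p_d.
The per-branch Poisson likelihood is verified in tests against the
equivalent total-Poisson × multinomial factorization (the per-pair-totals
form with the shared internal branch made explicit).

Exact reproduction of any published AIC table is out of scope: those
values depend on a multi-locus posterior tree sample and on an external
likelihood's algebra that is not reproduced here. What the package
asserts instead are the structural properties: nested-model dominance,
snowball superlinearity (doubling T more than doubles the DM total), the
lower early fraction of snowball models relative to linear, and rejection
of the linear model on the observed pollen counts.

## Model-selection validation

For each ground-truth model, counts are simulated on trees drawn uniformly
with replacement from a tree set, with the truth's overall rate calibrated
in closed form so the expected total matches the data scale (14
pollen-like, 8 seed-like); the AIC comparison is rerun and the winner
tallied into a truth × selected confusion matrix, from which precision and
recall are computed per model. Shape ratios of two-parameter truths
default to 1. The experiment is bit-for-bit reproducible given (seed,
trees, configuration). Published precision/recall values are likewise
posterior-dependent and out of scope; the package's own checks are
large-sample consistency (linear-vs-DM accuracy ≥ 95% at totals ≥ 500)
and the confusion-matrix identities.

**Problem sizes.** The shipped tests run parameter recovery at 200
replicates per model with the *smallest* branch calibrated to 500 expected
counts (so every branch is well populated — with fewer counts on the short
internal branch the two-parameter models lose precision rapidly), and the
selection-accuracy check at 100 simulations per truth with total 600.

## Synthetic data

`gen_fertility` draws value = class mean + family effect N(0, σ_m) +
residual N(0, σ), clipped to the trait's domain, balanced families.
`gen_tree_set` multiplies each branch by an independent mean-one lognormal
with chosen CV and re-enforces the clock. `gen_inventory` inverts the
placement logic (shared mutations become co-localized pairs, terminal
mutations unique records) and returns ground truth, so
`collapse_inventory ∘ gen_inventory` must reproduce the generating counts
exactly — the module's primary contract.

Two families of fertility scenarios ship:

* *observed-means emulations* use the published class means with residual
  SD inside the window the published letter displays imply (seed 18
  seeds/fruit, pollen 0.085) — the published means sit near the
  classifier's decision boundary, so these scenarios yield the published
  call as the modal determinate outcome rather than near-certainly;
* *ground-truth recovery scenarios* give statistically equal classes
  identical population means at the published effect structure (shared
  seed allele −47%, additional −68%, shared pollen allele −13%), SD 8 /
  0.05, where the classifier recovers the generating call in ≥ 95% of
  replicates.

What passing these tests shows: the estimators and decision rules behave
correctly under Gaussian, balanced, truncation-respecting noise with the
study's effect structure and sample sizes. What they do not show:
robustness to the features real fertility data add — overdispersion and
zero inflation in seed counts, unbalanced families, segregation within
introgression lines, genotyping error in co-localization calls, or QTL
underpinned by multiple mutations beyond the one composite case modelled.

## Numerical conventions

* Clock enforcement averages the two donor terminals (t_c' = t_d' =
  (t_c+t_d)/2, t_a' = t_b + t_c'); exact and idempotent on a three-taxon
  tree, deliberately simpler than penalized-likelihood rate smoothing,
  which has nothing extra to do with a single free constraint.
* Ultrametricity tolerance: relative 1e−6 of tree scale.
* Rounding of extrapolated counts: nearest integer, ties away from zero.
* All randomized operations take one integer seed and use an isolated
  `numpy.random.Generator`; Monte-Carlo triple means are cached per
  (tree, reps, seed) so repeated fits are deterministic and cheap.
* Enumeration guard: brute-force interaction censuses refuse histories
  beyond 10⁷ combinations and point to the closed forms.

## Known limitations

* The three-count data vector carries little information; with ~14
  mutations the two-parameter models are barely distinguishable from DM
  (that is precisely what the selection validation quantifies).
* The likelihood treats per-branch counts as independent Poisson; the
  alternative covariance formulation over per-pair totals is implemented
  only as the factorization identity, not as a separate estimator.
* Composite loci beyond one shared + one specific mutation, and arity-4+
  interactions, are out of scope.
* The tree is an input; no attempt is made to estimate it from sequence
  data beyond pruning and clock enforcement.
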