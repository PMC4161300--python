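# dmisnowball

Tools for inferring the evolutionary timing and pattern of accumulation of
the mutations behind hybrid sterility — Dobzhansky–Muller incompatibilities
(DMIs) — from comparative QTL data on a three-taxon phylogeny.

The package is aimed at speciation geneticists who have mapped reproductive
isolation QTL in two crosses sharing a common (recipient) parent — here the
*Solanum* system with *S. lycopersicum* (SL) crossed to each of
*S. habrochaites* (SH) and *S. pennellii* (SP) — and who want to know *when*
the underlying mutations arose and whether they accumulated faster than
linearly with divergence time (the "snowball" prediction).

## What it does

1. **Tests of allelism** (`dmisnowball.allelism`). Co-localized sterility
   QTL from the two crosses are combined in a trans-heterozygote on the SL
   background. A nested fixed-effects ANOVA (genotype + maternal family
   nested within genotype) with all-pairs Tukey HSD contrasts, rendered as
   a compact letter display, feeds a rule table: restored fertility in the
   trans-heterozygote means the two lineages' mutations complement (not
   homologous); persistent sterility means a shared mutation; partial
   rescue means a shared mutation plus a lineage-specific one. Effect
   sizes are reported as Δ% = 100·(m_IL − m_SL)/m_SL.

2. **Phylogenetic placement** (`dmisnowball.placement`). On the rooted tree
   ((SH, SP), SL) with internal branch *b* and terminal branches *c* (SH)
   and *d* (SP): QTL unique to one cross place their mutation on that
   cross's terminal branch; homologous pairs place one mutation on *b*;
   composite loci contribute one mutation on *b* plus one on the terminal
   branch. The result is the per-branch count vector (n_b, n_c, n_d).

3. **Early/late branch tests** (`dmisnowball.branch_tests`). Under the null
   that mutations land in proportion to branch length, p_early =
   t_b/(t_b+t_c+t_d). Pearson χ² goodness of fit, seeded binomial
   resampling with the exact tail as internal oracle, and a bootstrap
   comparison of the early mutation's |Δ%| against the resampled late
   effect-size distribution.

4. **Accumulation models** (`dmisnowball.models`). Four models of how
   DMI-participating mutations accrue on an ultrametric tree, as
   independent Poisson counts per branch with means

   * linear: μ_x = ρ·t_x
   * DM (pairwise snowball): μ_x = c·∫_x (T + u) du
   * p_a≠p_d: μ_x = c_d·T·t_x + c_a·∫_x u du
   * 2+3: the DM term (c₂) plus c₃·M3_x, a Monte-Carlo mean of three-locus
     interaction counts completed on branch x

   fitted by maximum likelihood and compared by AIC = 2k − 2ℓ, averaged
   over a tree set to propagate phylogenetic uncertainty.

5. **Selection validation** (`dmisnowball.selection`). Simulates counts
   under a known model calibrated to the data's scale, reruns the AIC
   comparison, and reports precision/recall per model.

6. **Interaction combinatorics** (`dmisnowball.combinatorics`). Closed-form
   counts of potential derived–derived and derived–ancestral interactions
   per focal substitution (the i-th substitution has i−1 potential
   derived–ancestral partners but an order-independent derived–derived
   budget), checked against a brute-force enumeration oracle.

7. **Synthetic data** (`dmisnowball.synth`, `dmisnowball.presets`).
   Generators for fertility tables, jittered tree sets, and QTL inventories
   with ground truth, plus the packaged *Solanum* study fixtures.

## Worked example

```python
from dmisnowball import presets
from dmisnowball.allelism import estimate_additional_effect, estimate_shared_effect
from dmisnowball.branch_tests import binomial_tail_sim, branch_proportions
from dmisnowball.models import compare_models
from dmisnowball.placement import branch_counts, collapse_inventory

# dissect the composite seed locus from its published class means
means = presets.TABLE2_MEANS["sss1.2"]
shared, seeds = estimate_shared_effect(means["SL"], means["IL_HH"], means["IL_HP"])
extra = estimate_additional_effect(means["IL_PP"], (means["IL_HH"] + means["IL_HP"]) / 2)
print(f"shared allele: {shared:.1f}% ({seeds:.1f} seeds/fruit); additional: {extra:.1f}%")
# shared allele: -46.7% (28.4 seeds/fruit); additional: -67.9%

# collapse the two crosses' QTL inventories onto the tree
records, outcomes = presets.solanum_inventory()
counts = branch_counts(collapse_inventory(records, outcomes))
print({t: c.as_tuple() for t, c in counts.items()})
# {'pollen': (1, 7, 6), 'seed': (1, 3, 4)}

# is 13/14 late mutations surprising given branch lengths?
props = branch_proportions(presets.SOLANUM_TREE)          # p_late = 0.749
tail = binomial_tail_sim(14, props.p_late, 13, iters=1000, seed=1)
print(f"{100*tail.simulated_fraction:.1f}% of draws >= 13 late (exact {100*tail.exact_tail:.2f}%)")
# 9.2% of draws >= 13 late (exact 9.95%)

# which accumulation model fits the pollen counts?
result = compare_models(counts["pollen"], presets.SOLANUM_TREE)
print(result.selected, {m: round(f.aic, 2) for m, f in result.fits.items()})
# DM {'linear': 14.62, 'DM': 13.17, 'p2p3': 15.17, 'paPd': 13.59}
```

The shared mutation at the composite seed locus reduces fertility by ~47%
(~28 seeds/fruit) and the additional SP-specific mutation by a further
~68%; 13 of the 14 distinct pollen mutations sit on terminal ("late")
branches, an excess over the linear-with-branch-length null that ~9% of
binomial resamples match; and the AIC comparison rejects the linear model
in favour of snowball-type accumulation.

A command-line interface mirrors these steps:

```bash
dmi allelism --fertility fert.csv --trait seed --locus sss2.1 --out results/
dmi place --inventory inventory.csv --calls calls.csv --out results/
dmi branch-test --tree tree.nwk --n-early 1 --n-late 13 --out results/
dmi fit-models --trees trees.nwk --n-b 1 --n-c 7 --n-d 6 --out results/
dmi validate-selection --n-sims 200 --target-total 14 --out results/
```

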