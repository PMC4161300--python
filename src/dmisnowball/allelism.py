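"""Cross-species complementation (allelism) tests for co-localized QTL.

A test of allelism crosses two introgression lines — one carrying the SH
allele, one the SP allele, of a co-localized sterility QTL on the common
SL background — and asks whether the trans-heterozygote (IL_HP / IL_PH)
recovers fertility.  Rescued fertility means the two lineages carry
different (non-homologous) mutations that complement; persistently low
fertility is consistent with one shared, homologous mutation.

The statistical machinery mirrors the standard analysis of such designs:
a nested fixed-effects ANOVA (genotype + maternal family nested within
genotype), least-squares means per genotype class, all-pairs Tukey HSD
contrasts rendered as a compact letter display, and a rule table that
converts the letter display into an allelism call.  Using letter overlap
rather than raw fertility thresholds is what makes the test valid for
incompletely recessive loci: only statistically supported differences
drive the call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .tables import GENOTYPES, FertilityMeasurement, fertility_frame


class AllelismError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeStats:
    """Per-genotype summary from the nested ANOVA + Tukey analysis."""

    genotype: str
    ls_mean: float
    group_labels: frozenset[str]
    n: int

    def shares_letter(self, other: "GenotypeStats") -> bool:
        """True when the two classes are statistically indistinguishable."""
        return bool(self.group_labels & other.group_labels)


@dataclass(frozen=True)
class GroupFit:
    """Full result of :func:`fit_group_stats`."""

    stats: tuple[GenotypeStats, ...]
    anova_p_genotype: float
    maternal_p: float
    mse: float
    df_resid: float

    def by_genotype(self) -> dict[str, GenotypeStats]:
        return {s.genotype: s for s in self.stats}


@dataclass(frozen=True)
class AllelismOutcome:
    locus: str
    call: str
    evidence: str = ""
    anova_p_genotype: float = float("nan")
    maternal_p: float = float("nan")


CALLS = (
    "homologous",
    "lineage_specific_SP",
    "lineage_specific_SH",
    "composite_shared_plus_SP",
    "composite_shared_plus_SH",
    "no_sterility",
    "indeterminate",
)


# ---------------------------------------------------------------------------
# nested ANOVA + Tukey HSD + compact letter display
# ---------------------------------------------------------------------------

def _tukey_pairwise(
    means: dict[str, float], ns: dict[str, int], mse: float, df_resid: float, alpha: float
) -> dict[tuple[str, str], bool]:
    """Tukey–Kramer all-pairs tests; returns {pair: significantly different}."""
    groups = sorted(means)
    k = len(groups)
    out: dict[tuple[str, str], bool] = {}
    for g1, g2 in itertools.combinations(groups, 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        q = abs(means[g1] - means[g2]) / se if se > 0 else np.inf
        p = stats.studentized_range.sf(q, k, df_resid)
        out[(g1, g2)] = bool(p < alpha)
    return out


def compact_letter_display(
    groups: Sequence[str], significant: dict[tuple[str, str], bool], means: dict[str, float]
) -> dict[str, frozenset[str]]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff they are not significantly different.
    Letters are assigned in order of descending mean, so the most fertile
    class carries 'A'.
    """
    sets: list[set[str]] = [set(groups)]
    for (g1, g2), sig in significant.items():
        if not sig:
            continue
        for s in list(sets):
            if g1 in s and g2 in s:
                sets.remove(s)
                a, b = s - {g2}, s - {g1}
                for new in (a, b):
                    if not any(new <= other for other in sets):
                        sets.append(new)
    # absorb (defensive; the insertion step already avoids subsets)
    sets = [s for s in sets if not any(s < other for other in sets)]
    # order letter groups by the best (highest) mean they contain
    sets.sort(key=lambda s: -max(means[g] for g in s))
    letters = {g: set() for g in groups}
    for i, s in enumerate(sets):
        label = chr(ord("A") + i)
        for g in s:
            letters[g].add(label)
    return {g: frozenset(v) for g, v in letters.items()}


def fit_group_stats(
    measurements: Iterable[FertilityMeasurement] | pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
) -> GroupFit:
    """Nested ANOVA and Tukey letter display for one fertility trait.

    Fits ``value ~ genotype + genotype:maternal_family`` (maternal family
    nested within genotype, fixed effects), reports F-test p-values for
    both terms, least-squares means per genotype, and all-pairs
    Tukey-adjusted contrasts collapsed into a compact letter display.
    """
    df = measurements if isinstance(measurements, pd.DataFrame) else fertility_frame(measurements)
    df = df[df["trait"] == trait].copy()
    if df.empty:
        raise AllelismError(f"no measurements for trait {trait!r}")
    df["value"] = df["value"].astype(float)
    counts = df.groupby("genotype")["value"].count()
    if len(counts) < 2:
        raise AllelismError("need at least 2 genotype classes")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise AllelismError(f"genotype classes with fewer than 2 plants: {bad}")

    n_families = df.groupby("genotype")["maternal_family"].nunique()
    nested = (n_families > 1).any()
    formula = "value ~ C(genotype)"
    if nested:
        formula += " + C(genotype):C(maternal_family)"
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    p_geno = float(anova.loc["C(genotype)", "PR(>F)"])
    p_mat = (
        float(anova.loc["C(genotype):C(maternal_family)", "PR(>F)"])
        if nested
        else float("nan")
    )
    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)

    means = df.groupby("genotype")["value"].mean().to_dict()
    ns = counts.to_dict()
    sig = _tukey_pairwise(means, ns, mse, df_resid, alpha)
    letters = compact_letter_display(sorted(means), sig, means)

    order = [g for g in GENOTYPES if g in means]
    stats_out = tuple(
        GenotypeStats(genotype=g, ls_mean=float(means[g]), group_labels=letters[g], n=int(ns[g]))
        for g in order
    )
    return GroupFit(
        stats=stats_out,
        anova_p_genotype=p_geno,
        maternal_p=p_mat,
        mse=mse,
        df_resid=df_resid,
    )


# ---------------------------------------------------------------------------
# rule-based classification
# ---------------------------------------------------------------------------

def classify_allelism(
    stats: Sequence[GenotypeStats],
    locus: str = "",
    anova_p_genotype: float = float("nan"),
    maternal_p: float = float("nan"),
) -> AllelismOutcome:
    """Convert a Tukey letter display into an allelism call.

    Rule table (SL = fertile parent; letters shared = indistinguishable):

    * all classes indistinguishable → ``no_sterility``;
    * every IL below SL and all ILs mutually indistinguishable →
      ``homologous`` (no complementation — one shared mutation);
    * IL_HP (and IL_PH when present) and IL_HH rescued — i.e. not
      significantly below SL — and only IL_PP low → ``lineage_specific_SP``
      (full complementation; mirror case for SH);
    * IL_HP indistinguishable from IL_HH, both below SL, and IL_PP
      significantly below IL_HP → ``composite_shared_plus_SP`` (partial
      complementation: a shared mutation plus an SP-specific one; mirror
      case for SH);
    * anything else → ``indeterminate`` with the letter display as
      evidence.
    """
    by_g = {s.genotype: s for s in stats}
    for required in ("SL", "IL_HH", "IL_PP", "IL_HP"):
        if required not in by_g:
            raise AllelismError(f"classification requires genotype {required}")
    sl, hh, pp, hp = by_g["SL"], by_g["IL_HH"], by_g["IL_PP"], by_g["IL_HP"]
    ph = by_g.get("IL_PH")
    ils = [s for s in (hh, pp, hp, ph) if s is not None]

    def same(a: GenotypeStats, b: GenotypeStats) -> bool:
        return a.shares_letter(b)

    def below(a: GenotypeStats, b: GenotypeStats) -> bool:
        return (not a.shares_letter(b)) and a.ls_mean < b.ls_mean

    def rescued(a: GenotypeStats) -> bool:
        # fertility restored: not significantly below SL (a trans
        # heterozygote may even overshoot the SL mean)
        return not below(a, sl)

    evidence = "; ".join(
        f"{s.genotype}={s.ls_mean:.3g}[{''.join(sorted(s.group_labels))}]" for s in stats
    )

    def outcome(call: str) -> AllelismOutcome:
        return AllelismOutcome(
            locus=locus,
            call=call,
            evidence=evidence,
            anova_p_genotype=anova_p_genotype,
            maternal_p=maternal_p,
        )

    # (iv) nothing distinguishable at all
    if all(same(a, b) for a, b in itertools.combinations(stats, 2)):
        return outcome("no_sterility")

    # (i) no complementation: every IL low, ILs mutually indistinguishable
    if all(below(s, sl) for s in ils) and all(
        same(a, b) for a, b in itertools.combinations(ils, 2)
    ):
        return outcome("homologous")

    # (ii) full complementation: only one homozygote is low
    hetero_rescued = rescued(hp) and (ph is None or rescued(ph))
    if hetero_rescued and rescued(hh) and below(pp, sl) and below(pp, hp):
        return outcome("lineage_specific_SP")
    if hetero_rescued and rescued(pp) and below(hh, sl) and below(hh, hp):
        return outcome("lineage_specific_SH")

    # (iii) partial complementation: shared mutation plus one extra
    if same(hp, hh) and below(hp, sl) and below(hh, sl) and below(pp, hp):
        return outcome("composite_shared_plus_SP")
    if same(hp, pp) and below(hp, sl) and below(pp, sl) and below(hh, hp):
        return outcome("composite_shared_plus_SH")

    return outcome("indeterminate")


def run_allelism_test(
    measurements: Iterable[FertilityMeasurement] | pd.DataFrame,
    trait: str,
    locus: str = "",
    alpha: float = 0.05,
) -> tuple[GroupFit, AllelismOutcome]:
    """Convenience wrapper: fit the nested ANOVA and classify in one step."""
    fit = fit_group_stats(measurements, trait, alpha=alpha)
    out = classify_allelism(
        fit.stats,
        locus=locus,
        anova_p_genotype=fit.anova_p_genotype,
        maternal_p=fit.maternal_p,
    )
    return fit, out


# ---------------------------------------------------------------------------
# effect-size estimators (Δ% convention: percent change vs SL, <= 0)
# ---------------------------------------------------------------------------

def effect_size_delta(sl_mean: float, il_mean: float) -> float:
    """Δ% of an introgression-line mean relative to the fertile SL parent."""
    if sl_mean <= 0:
        raise AllelismError(f"SL mean must be > 0, got {sl_mean}")
    return 100.0 * (il_mean - sl_mean) / sl_mean


def estimate_shared_effect(
    sl_mean: float, il_hh_mean: float, il_hp_mean: float
) -> tuple[float, float]:
    """Effect of the shared (homologous) allele at a composite locus.

    Pools the two classes homozygous for the shared mutation only
    (IL_HH and IL_HP) and compares the pooled mean to SL.  Returns
    ``(delta_pct, absolute_difference)`` — the latter in the trait's own
    units (seeds/fruit for seed fertility).
    """
    pool = (il_hh_mean + il_hp_mean) / 2.0
    return effect_size_delta(sl_mean, pool), sl_mean - pool


def estimate_additional_effect(
    il_pp_mean: float,
    shared_pool_mean: float,
    sl_mean: Optional[float] = None,
    sequential: bool = True,
) -> float:
    """Residual effect of the lineage-specific mutation at a composite locus.

    Under the sequential (multiplicative) composition the two mutations'
    proportional effects multiply, so the additional reduction is measured
    relative to the shared-allele fertility level:
    ``100 * (il_pp / shared_pool - 1)``.  ``sequential=False`` gives the
    additive-residual variant, the difference of the two Δ% values on the
    SL scale (requires ``sl_mean``).
    """
    if shared_pool_mean <= 0:
        raise AllelismError(f"shared pool mean must be > 0, got {shared_pool_mean}")
    if sequential:
        return 100.0 * (il_pp_mean / shared_pool_mean - 1.0)
    if sl_mean is None:
        raise AllelismError("additive-residual variant requires sl_mean")
    return effect_size_delta(sl_mean, il_pp_mean) - effect_size_delta(sl_mean, shared_pool_mean)
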