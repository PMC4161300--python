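"""Synthetic-data generators for every pipeline input.

Each generator is a pure function of (scenario, seed) and emulates the
statistical structure its consumer assumes:

* :func:`gen_fertility` — per-plant fertility measurements with genotype
  class means, a nested maternal-family effect, and Gaussian residual
  noise truncated to the trait's domain (pollen in [0, 1], seed >= 0).
  Maternal effects default to small, matching experiments in which no
  significant maternal effect is detected.
* :func:`gen_tree_set` — a jittered stand-in for a posterior sample of
  trees: each branch of a base tree is multiplied by an independent
  mean-one lognormal with a chosen coefficient of variation, then the
  clock is re-enforced.
* :func:`gen_inventory` — the inverse of the placement logic: simulate
  per-branch mutation counts under an accumulation model, then emit the
  per-cross QTL tables (shared b-mutations become co-localized pairs, one
  record per cross; terminal mutations become unique records) together
  with the ground-truth allelism outcomes and placements, so that
  ``collapse_inventory(gen_inventory(...))`` must reproduce the generating
  counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .allelism import AllelismOutcome
from .placement import BranchCounts, MutationPlacement
from .selection import simulate_counts
from .tables import FertilityMeasurement, QTLRecord, RunConfig
from .trees import ThreeTaxonTree, TreeSet, enforce_clock
from .models import ModelSpec


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fertility tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FertilityScenario:
    genotype_means: dict[str, float]
    sd: float
    trait: str
    maternal_sd: float = 0.0
    n_per_class: int = 25
    families_per_class: int = 5

    def __post_init__(self) -> None:
        if self.sd < 0 or self.maternal_sd < 0:
            raise SynthError("standard deviations must be >= 0")
        if not self.n_per_class >= self.families_per_class >= 1:
            raise SynthError("need n_per_class >= families_per_class >= 1")
        for g, m in self.genotype_means.items():
            if self.trait == "pollen" and not 0.0 <= m <= 1.0:
                raise SynthError(f"pollen mean for {g} outside [0, 1]: {m}")
            if self.trait == "seed" and m < 0:
                raise SynthError(f"seed mean for {g} negative: {m}")


def gen_fertility(scenario: FertilityScenario, seed: int = 0) -> list[FertilityMeasurement]:
    """Simulate a balanced allelism-test fertility table."""
    rng = np.random.default_rng(seed)
    records: list[FertilityMeasurement] = []
    hi = 1.0 if scenario.trait == "pollen" else np.inf
    for genotype, mean in scenario.genotype_means.items():
        fam_effects = rng.normal(0.0, scenario.maternal_sd, size=scenario.families_per_class)
        for plant in range(scenario.n_per_class):
            fam = plant % scenario.families_per_class
            value = mean + fam_effects[fam] + rng.normal(0.0, scenario.sd)
            value = float(np.clip(value, 0.0, hi))
            records.append(
                FertilityMeasurement(
                    plant_id=f"{genotype}_{plant + 1}",
                    genotype=genotype,
                    maternal_family=f"{genotype}_fam{fam + 1}",
                    trait=scenario.trait,
                    value=value,
                )
            )
    return records


# ---------------------------------------------------------------------------
# tree sets
# ---------------------------------------------------------------------------

def gen_tree_set(
    base: ThreeTaxonTree, cv: float, n: int, seed: int = 0, source_label: str = "synthetic"
) -> TreeSet:
    """Jitter every branch by an independent mean-one lognormal (CV = cv),
    then re-enforce the clock."""
    if cv < 0:
        raise SynthError("cv must be >= 0")
    if n < 1:
        raise SynthError("need at least one tree")
    if cv == 0:
        return TreeSet(trees=tuple(enforce_clock(base) for _ in range(n)), source_label=source_label)
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    mu = -sigma2 / 2.0  # lognormal mean exactly 1
    trees = []
    for _ in range(n):
        f = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=4)
        trees.append(
            enforce_clock(
                ThreeTaxonTree(
                    t_a=base.t_a * f[0],
                    t_b=base.t_b * f[1],
                    t_c=base.t_c * f[2],
                    t_d=base.t_d * f[3],
                )
            )
        )
    return TreeSet(trees=tuple(trees), source_label=source_label)


# ---------------------------------------------------------------------------
# QTL inventories with ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InventoryScenario:
    model: Optional[ModelSpec]
    tree: Optional[ThreeTaxonTree]
    trait: str = "pollen"
    effect_mean: float = -40.0
    effect_sd: float = 20.0
    seed: int = 0
    n_composite: int = 0
    forced_counts: Optional[tuple[int, int, int]] = None


@dataclass(frozen=True)
class GeneratedInventory:
    records: tuple[QTLRecord, ...]
    outcomes: tuple[AllelismOutcome, ...]
    truth_placements: tuple[MutationPlacement, ...]
    truth_counts: BranchCounts


def _draw_delta(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to the sterility convention (delta <= 0)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v <= 0:
            return float(v)
    return 0.0


def gen_inventory(scenario: InventoryScenario) -> GeneratedInventory:
    """Simulate an inventory pair plus its ground truth.

    Branch counts come from the accumulation model (or
    ``scenario.forced_counts``).  Each b-mutation yields a co-localized
    record pair with a ``homologous`` ground-truth outcome; the first
    ``n_composite`` b-mutations are instead paired with an extra SP-specific
    mutation at the same location (``composite_shared_plus_SP``), which
    consumes one mutation from branch d's budget if available, otherwise
    adds one.
    """
    rng = np.random.default_rng(scenario.seed)
    if scenario.forced_counts is not None:
        n_b, n_c, n_d = scenario.forced_counts
        counts = BranchCounts(trait=scenario.trait, n_b=n_b, n_c=n_c, n_d=n_d)
    else:
        if scenario.model is None or scenario.tree is None:
            raise SynthError("need either forced_counts or (model, tree)")
        counts = simulate_counts(
            scenario.model,
            scenario.tree,
            seed=scenario.seed,
            trait=scenario.trait,
        )
    tag = "pf" if scenario.trait == "pollen" else "sss"
    records: list[QTLRecord] = []
    outcomes: list[AllelismOutcome] = []
    placements: list[MutationPlacement] = []
    chrom = lambda: int(rng.integers(1, 13))

    n_composite = min(scenario.n_composite, counts.n_b)
    d_budget = counts.n_d

    for i in range(counts.n_b):
        base = f"{tag}_b{i + 1}"
        delta_sh = _draw_delta(rng, scenario.effect_mean, scenario.effect_sd)
        delta_sp = _draw_delta(rng, scenario.effect_mean, scenario.effect_sd)
        composite = i < n_composite
        records.append(
            QTLRecord(
                qtl_id=f"{base}_sh", cross="SHxSL", trait=scenario.trait,
                chromosome=chrom(), delta_pct=delta_sh, colocal_partner=f"{base}_sp",
            )
        )
        records.append(
            QTLRecord(
                qtl_id=f"{base}_sp", cross="SPxSL", trait=scenario.trait,
                chromosome=chrom(), delta_pct=delta_sp, colocal_partner=f"{base}_sh",
            )
        )
        if composite:
            outcomes.append(
                AllelismOutcome(locus=f"{base}_sh", call="composite_shared_plus_SP")
            )
            placements.append(
                MutationPlacement(
                    mutation_id=f"{base}_sh.shared", trait=scenario.trait, branch="b",
                    source_qtls=(f"{base}_sh", f"{base}_sp"), delta_pct=delta_sh,
                )
            )
            placements.append(
                MutationPlacement(
                    mutation_id=f"{base}_sh.specific", trait=scenario.trait, branch="d",
                    source_qtls=(f"{base}_sp",), delta_pct=delta_sp,
                )
            )
            d_budget -= 1
        else:
            outcomes.append(AllelismOutcome(locus=f"{base}_sh", call="homologous"))
            placements.append(
                MutationPlacement(
                    mutation_id=f"{base}_sh", trait=scenario.trait, branch="b",
                    source_qtls=(f"{base}_sh", f"{base}_sp"),
                    delta_pct=(delta_sh + delta_sp) / 2.0,
                )
            )

    for branch, cross, budget in (("c", "SHxSL", counts.n_c), ("d", "SPxSL", max(d_budget, 0))):
        for i in range(budget):
            qid = f"{tag}_{branch}{i + 1}"
            delta = _draw_delta(rng, scenario.effect_mean, scenario.effect_sd)
            records.append(
                QTLRecord(
                    qtl_id=qid, cross=cross, trait=scenario.trait,
                    chromosome=chrom(), delta_pct=delta,
                )
            )
            placements.append(
                MutationPlacement(
                    mutation_id=qid, trait=scenario.trait, branch=branch,
                    source_qtls=(qid,), delta_pct=delta,
                )
            )

    truth_counts = BranchCounts(
        trait=scenario.trait,
        n_b=sum(1 for p in placements if p.branch == "b"),
        n_c=sum(1 for p in placements if p.branch == "c"),
        n_d=sum(1 for p in placements if p.branch == "d"),
    )
    return GeneratedInventory(
        records=tuple(records),
        outcomes=tuple(outcomes),
        truth_placements=tuple(placements),
        truth_counts=truth_counts,
    )
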