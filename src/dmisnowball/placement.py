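"""Collapse two crosses' QTL inventories into distinct mutations on branches.

Logic: a QTL detected in only one cross (SH×SL or SP×SL) must be due to a
mutation on the terminal branch unique to that cross (c for SH, d for SP).
A co-localized pair resolved as *homologous* by the allelism test is one
mutation on the shared internal branch b.  A *composite* locus contributes
one shared mutation on b plus one lineage-specific mutation on the
relevant terminal branch.  A co-localized pair resolved as
*lineage-specific* contributes terminal-branch mutations for each genuine
instance; an instance flagged as statistically confounded with pollen
sterility (a seed QTL that is a secondary consequence of pollen failure)
is dropped.  Each QTL is conservatively assumed to be underpinned by a
single mutation.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .allelism import AllelismOutcome
from .tables import CROSS_TERMINAL_BRANCH, QTLRecord, validate_colocal_symmetry

logger = logging.getLogger(__name__)

BRANCHES = ("b", "c", "d")


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class MutationPlacement:
    mutation_id: str
    trait: str
    branch: str
    source_qtls: tuple[str, ...]
    delta_pct: float

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise PlacementError(f"unknown branch {self.branch!r}")

    @property
    def epoch(self) -> str:
        return "early" if self.branch == "b" else "late"


@dataclass(frozen=True)
class BranchCounts:
    trait: str
    n_b: int
    n_c: int
    n_d: int

    def __post_init__(self) -> None:
        if min(self.n_b, self.n_c, self.n_d) < 0:
            raise PlacementError("branch counts must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_b + self.n_c + self.n_d

    @property
    def n_early(self) -> int:
        return self.n_b

    @property
    def n_late(self) -> int:
        return self.n_c + self.n_d

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_b, self.n_c, self.n_d)


def _outcome_index(outcomes: Iterable[AllelismOutcome]) -> Mapping[str, AllelismOutcome]:
    return {o.locus: o for o in outcomes}


def _pair_outcome(
    rec: QTLRecord, partner: QTLRecord, outcomes: Mapping[str, AllelismOutcome]
) -> AllelismOutcome:
    for key in (rec.qtl_id, partner.qtl_id):
        if key in outcomes:
            return outcomes[key]
    raise PlacementError(
        f"co-localized pair ({rec.qtl_id}, {partner.qtl_id}) has no allelism outcome"
    )


def collapse_inventory(
    records: Sequence[QTLRecord],
    outcomes: Iterable[AllelismOutcome],
) -> list[MutationPlacement]:
    """Resolve the joint inventory into distinct mutations with branches.

    ``outcomes`` must contain one :class:`AllelismOutcome` per co-localized
    pair, keyed (via its ``locus`` field) by either member's ``qtl_id``.
    An ``indeterminate`` outcome is an error: the user must resolve the
    locus before placement.
    """
    validate_colocal_symmetry(list(records))
    by_id = {r.qtl_id: r for r in records}
    outcome_map = _outcome_index(outcomes)
    placements: list[MutationPlacement] = []
    handled: set[str] = set()

    for rec in records:
        if rec.qtl_id in handled:
            continue
        if rec.colocal_partner is None:
            placements.append(
                MutationPlacement(
                    mutation_id=rec.qtl_id,
                    trait=rec.trait,
                    branch=CROSS_TERMINAL_BRANCH[rec.cross],
                    source_qtls=(rec.qtl_id,),
                    delta_pct=rec.delta_pct,
                )
            )
            handled.add(rec.qtl_id)
            continue

        partner = by_id[rec.colocal_partner]
        handled.update({rec.qtl_id, partner.qtl_id})
        sh_rec, sp_rec = (rec, partner) if rec.cross == "SHxSL" else (partner, rec)
        out = _pair_outcome(rec, partner, outcome_map)
        pair_ids = (sh_rec.qtl_id, sp_rec.qtl_id)
        base = out.locus or rec.qtl_id

        if out.call == "indeterminate":
            raise PlacementError(
                f"allelism outcome for pair {pair_ids} is indeterminate; "
                "resolve it before placement"
            )
        if out.call == "no_sterility":
            continue
        if out.call == "homologous":
            placements.append(
                MutationPlacement(
                    mutation_id=base,
                    trait=rec.trait,
                    branch="b",
                    source_qtls=pair_ids,
                    delta_pct=(sh_rec.delta_pct + sp_rec.delta_pct) / 2.0,
                )
            )
        elif out.call in ("composite_shared_plus_SP", "composite_shared_plus_SH"):
            specific = sp_rec if out.call.endswith("SP") else sh_rec
            placements.append(
                MutationPlacement(
                    mutation_id=f"{base}.shared",
                    trait=rec.trait,
                    branch="b",
                    source_qtls=pair_ids,
                    delta_pct=(sh_rec if specific is sp_rec else sp_rec).delta_pct,
                )
            )
            placements.append(
                MutationPlacement(
                    mutation_id=f"{base}.specific",
                    trait=rec.trait,
                    branch=CROSS_TERMINAL_BRANCH[specific.cross],
                    source_qtls=(specific.qtl_id,),
                    delta_pct=specific.delta_pct,
                )
            )
        elif out.call in ("lineage_specific_SP", "lineage_specific_SH"):
            keeper = sp_rec if out.call.endswith("SP") else sh_rec
            other = sh_rec if keeper is sp_rec else sp_rec
            placements.append(
                MutationPlacement(
                    mutation_id=keeper.qtl_id,
                    trait=keeper.trait,
                    branch=CROSS_TERMINAL_BRANCH[keeper.cross],
                    source_qtls=(keeper.qtl_id,),
                    delta_pct=keeper.delta_pct,
                )
            )
            # the co-localized instance in the other cross stands only if it
            # is a genuine, unconfounded signal of its own
            if not other.pollen_confounded:
                placements.append(
                    MutationPlacement(
                        mutation_id=other.qtl_id,
                        trait=other.trait,
                        branch=CROSS_TERMINAL_BRANCH[other.cross],
                        source_qtls=(other.qtl_id,),
                        delta_pct=other.delta_pct,
                    )
                )
        else:
            raise PlacementError(f"unknown allelism call {out.call!r}")
    return placements


def branch_counts(placements: Iterable[MutationPlacement]) -> dict[str, BranchCounts]:
    """Tabulate distinct mutations per branch, per trait."""
    tallies: dict[str, dict[str, int]] = defaultdict(lambda: {b: 0 for b in BRANCHES})
    for p in placements:
        tallies[p.trait][p.branch] += 1
    return {
        trait: BranchCounts(trait=trait, n_b=t["b"], n_c=t["c"], n_d=t["d"])
        for trait, t in sorted(tallies.items())
    }


@dataclass(frozen=True)
class InventorySummary:
    """QTL-level (not mutation-level) tallies across both crosses.

    A co-localized pair that involves a shared mutation (homologous or
    composite call) counts as one shared QTL; a co-localized pair resolved
    as lineage-specific counts as two unshared QTL.
    """

    n_qtl: int
    n_shared: int
    n_unshared: int
    n_unique_by_trait: dict[str, int]


def summarize_inventory(
    records: Sequence[QTLRecord], outcomes: Iterable[AllelismOutcome]
) -> InventorySummary:
    validate_colocal_symmetry(list(records))
    by_id = {r.qtl_id: r for r in records}
    outcome_map = _outcome_index(outcomes)
    n_qtl = 0
    n_shared = 0
    unique_by_trait: dict[str, int] = defaultdict(int)
    handled: set[str] = set()
    for rec in records:
        if rec.qtl_id in handled:
            continue
        if rec.colocal_partner is None:
            n_qtl += 1
            unique_by_trait[rec.trait] += 1
            handled.add(rec.qtl_id)
            continue
        partner = by_id[rec.colocal_partner]
        handled.update({rec.qtl_id, partner.qtl_id})
        call = _pair_outcome(rec, partner, outcome_map).call
        if call in ("homologous", "composite_shared_plus_SP", "composite_shared_plus_SH"):
            n_qtl += 1
            n_shared += 1
        else:
            n_qtl += 2
    return InventorySummary(
        n_qtl=n_qtl,
        n_shared=n_shared,
        n_unshared=n_qtl - n_shared,
        n_unique_by_trait=dict(unique_by_trait),
    )


def derived_ancestral_check(
    extra_crosses: Mapping[str, set],
    shared_locus_location,
) -> str:
    """Parsimony refinement of a shared-mutation placement on branch b.

    A shared SH/SP sterility allele could in principle be the *ancestral*
    state, with the causal derived mutations on the SL side.  If additional
    SL-sister species crosses show no QTL at the shared location, the
    single-derived-mutation-on-b explanation is more parsimonious.

    Returns ``"derived_on_b"`` or ``"possibly_ancestral"``.  With no
    extra-cross data at all there is no evidence either way.
    """
    if not extra_crosses:
        logger.warning("no extra-cross data: placement on b cannot be refined")
        return "possibly_ancestral"
    for locations in extra_crosses.values():
        if shared_locus_location in locations:
            return "possibly_ancestral"
    return "derived_on_b"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def extrapolate_counts(counts: BranchCounts, fraction: float = 1.0 / 3.0) -> BranchCounts:
    """Inflate late (terminal-branch) counts assuming some lineage-specific
    QTL hide two mutations.

    Each terminal count is scaled by (1 + fraction) and rounded to the
    nearest whole mutation (ties away from zero); the early count is
    untouched since shared loci were dissected directly by the allelism
    tests.
    """
    if not 0.0 <= fraction <= 1.0:
        raise PlacementError("fraction must lie in [0, 1]")
    return BranchCounts(
        trait=counts.trait,
        n_b=counts.n_b,
        n_c=_round_half_away(counts.n_c * (1.0 + fraction)),
        n_d=_round_half_away(counts.n_d * (1.0 + fraction)),
    )
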