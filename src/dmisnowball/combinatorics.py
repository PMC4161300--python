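"""Counting potential Dobzhansky-Muller interactions per focal substitution.

Two lineages diverge from a common ancestor; lineage I fixes K1 derived
alleles (temporal order i = 1..K1), lineage II fixes K2 (order j = 1..K2).
A potential incompatibility is any combination of alleles that were never
co-tested by selection in either lineage:

* **dd** — a derived allele in each lineage (pairwise);
* **da** — a derived allele against the *ancestral* allele, in the other
  lineage, at a locus substituted earlier on the focal allele's own
  lineage (pairwise);
* **ddd** — two derived alleles in one lineage plus a derived allele in
  the other (three-locus);
* **dda** — two derived alleles in one lineage plus the other lineage's
  ancestral allele at a locus substituted earlier than both.

The closed forms below are checked exhaustively against
:func:`enumerate_interactions`, a brute-force census over explicit
substitution histories.  The asymmetry between the classes is the point:
dd counts do not depend on when the focal allele arose, while da/dda
counts grow with its order index — later mutations participate in more
ancestral-allele interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

ENUMERATION_GUARD = 10**7


@dataclass(frozen=True)
class SubstitutionHistory:
    """Substitution counts of the two lineages (orders dense from 1)."""

    K1: int
    K2: int

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.K2 < 0:
            raise ValueError("substitution counts must be >= 0")


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def pairwise_dd(i: int, K_other: int) -> int:
    """Derived-derived partners of the i-th substitution: every derived
    allele in the other lineage, regardless of i."""
    if i < 1:
        raise ValueError("order index must be >= 1")
    if K_other < 0:
        raise ValueError("K_other must be >= 0")
    return K_other


def pairwise_da(i: int) -> int:
    """Derived-ancestral partners of the i-th substitution: the ancestral
    alleles (in the other lineage) at the i-1 loci substituted earlier on
    its own lineage."""
    if i < 1:
        raise ValueError("order index must be >= 1")
    return i - 1


def triple_counts(i: int, j: int, K_other: int) -> tuple[int, int]:
    """Three-locus interactions involving the i-th and j-th substitutions
    of one lineage (unordered pair, i != j).

    Returns ``(ddd, dda)``: ddd partners are the K_other derived alleles
    in the other lineage; dda partners are the ancestral alleles at loci
    substituted before *both* focal alleles, i.e. ``min(i, j) - 1``.
    """
    if i == j:
        raise ValueError("focal pair must involve two distinct substitutions")
    if i < 1 or j < 1:
        raise ValueError("order indices must be >= 1")
    if K_other < 0:
        raise ValueError("K_other must be >= 0")
    return K_other, min(i, j) - 1


def per_focal_triple_total(i: int, K_same: int, K_other: int) -> int:
    """All three-locus interactions (ddd + dda) involving focal allele i,
    summed over its same-lineage partners j != i.

    ``sum_j ddd = (K_same - 1) * K_other`` and
    ``sum_j dda = sum_{j<i}(j-1) + (K_same-i)(i-1)``.
    """
    if not 1 <= i <= K_same:
        raise ValueError("focal index outside the lineage's history")
    ddd = (K_same - 1) * K_other
    dda = (i - 1) * (i - 2) // 2 + (K_same - i) * (i - 1)
    return ddd + dda


def per_focal_new_triples(i: int, K_other: int) -> int:
    """Three-locus interactions *completed* by the i-th substitution.

    Snowball bookkeeping attributes each potential incompatibility to the
    substitution whose fixation creates it — the latest same-lineage
    member.  The i-th substitution completes a trio with each of its i-1
    earlier same-lineage partners and either a derived allele in the other
    lineage (``(i-1) * K_other`` ddd trios) or the other lineage's
    ancestral allele at a locus substituted before the partner
    (``sum_{j<i}(j-1) = (i-1)(i-2)/2`` dda trios).  Summing over i = 1..K
    recovers every trio exactly once within the lineage.
    """
    if i < 1:
        raise ValueError("order index must be >= 1")
    if K_other < 0:
        raise ValueError("K_other must be >= 0")
    return (i - 1) * K_other + (i - 1) * (i - 2) // 2


# ---------------------------------------------------------------------------
# brute-force enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_interactions(
    history: SubstitutionHistory,
    arity: int,
    classes: set[str] | frozenset[str],
) -> dict[tuple[int, int], int]:
    """Explicitly enumerate interactions and tally participation per focal
    derived allele.

    Alleles are keyed ``(lineage, order)`` with lineage in {1, 2}.  Every
    interaction is counted once per focal member: a dd pair contributes to
    both of its derived alleles; a triple contributes to the two derived
    alleles of its same-lineage focal pair (the other-lineage allele is the
    partner, not a focus).  Triples are restricted to two derived alleles
    in one lineage plus one allele (derived or ancestral) in the other.
    """
    bad = set(classes) - {"dd", "da", "ddd", "dda"}
    if bad:
        raise ValueError(f"unknown interaction classes: {sorted(bad)}")
    if arity not in (2, 3):
        raise ValueError("arity must be 2 or 3")
    K1, K2 = history.K1, history.K2
    if (max(K1, 1) * max(K2, 1)) ** (arity - 1) > ENUMERATION_GUARD:
        raise ValueError("history too large to enumerate; use the closed forms")

    counts: dict[tuple[int, int], int] = {
        **{(1, i): 0 for i in range(1, K1 + 1)},
        **{(2, j): 0 for j in range(1, K2 + 1)},
    }

    def derived(lineage: int):
        K = K1 if lineage == 1 else K2
        return [(lineage, idx) for idx in range(1, K + 1)]

    if arity == 2:
        if "dd" in classes:
            for a, b in itertools.product(derived(1), derived(2)):
                counts[a] += 1
                counts[b] += 1
        if "da" in classes:
            for lineage in (1, 2):
                for _, i in derived(lineage):
                    # ancestral partner exists at each locus substituted
                    # earlier on the focal lineage
                    for earlier in range(1, i):
                        counts[(lineage, i)] += 1
        return counts

    for lineage, other_K in ((1, K2), (2, K1)):
        K = K1 if lineage == 1 else K2
        for i, j in itertools.combinations(range(1, K + 1), 2):
            if "ddd" in classes:
                for _ in range(other_K):
                    counts[(lineage, i)] += 1
                    counts[(lineage, j)] += 1
            if "dda" in classes:
                for earlier in range(1, K + 1):
                    if earlier < i and earlier < j:
                        counts[(lineage, i)] += 1
                        counts[(lineage, j)] += 1
    return counts


def enumerate_pair_triples(
    history: SubstitutionHistory, i: int, j: int
) -> tuple[int, int]:
    """Brute-force (ddd, dda) census for one focal pair (i, j) in lineage I.

    Independent oracle for :func:`triple_counts`: loops over every explicit
    partner allele in lineage II rather than using the closed forms.
    """
    if i == j:
        raise ValueError("focal pair must involve two distinct substitutions")
    if not (1 <= i <= history.K1 and 1 <= j <= history.K1):
        raise ValueError("focal indices outside lineage I's history")
    ddd = sum(1 for _ in range(1, history.K2 + 1))
    dda = sum(1 for earlier in range(1, history.K1 + 1) if earlier < i and earlier < j)
    return ddd, dda
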