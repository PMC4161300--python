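"""Three-taxon trees: Newick I/O, pruning, and molecular-clock enforcement.

The pipeline works on a rooted three-taxon tree with topology
``((SH, SP), SL)``: SL is the recurrent (recipient) parent of both
introgression-line crosses, SH and SP are the two donor species.  Branches
are named by role:

* ``a`` — the SL terminal branch,
* ``b`` — the internal stem shared by SH and SP (the "early" branch),
* ``c`` — the SH terminal branch,
* ``d`` — the SP terminal branch ("late" branches are c and d).

Trees with more taxa are accepted and silently pruned down to the three
focal species (with a log line), since published multi-species trees are
the natural input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import dendropy

logger = logging.getLogger(__name__)

#: Relative tolerance used when testing the ultrametricity invariants.
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised when a Newick input cannot be mapped onto the 3-taxon roles."""


@dataclass(frozen=True)
class ThreeTaxonTree:
    """Branch lengths of the rooted tree ((SH, SP), SL).

    Lengths are in substitutions/site or arbitrary time units; every
    downstream quantity that matters (branch proportions, model selection)
    is invariant to rescaling all four lengths together.
    """

    t_a: float
    t_b: float
    t_c: float
    t_d: float

    def __post_init__(self) -> None:
        for name in ("t_a", "t_b", "t_c", "t_d"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise TreeError(f"branch length {name}={value!r} must be finite and >= 0")

    @property
    def ultrametric(self) -> bool:
        scale = max(self.t_a, self.t_b + max(self.t_c, self.t_d), 1e-300)
        tol = ULTRAMETRIC_RTOL * scale
        return (
            abs(self.t_c - self.t_d) <= tol
            and abs(self.t_a - (self.t_b + self.t_c)) <= tol
        )

    @property
    def depth_T(self) -> float:
        """Root-to-tip depth ``t_b + t_c`` (requires an ultrametric tree)."""
        if not self.ultrametric:
            raise TreeError("depth_T is defined only for ultrametric trees; run enforce_clock")
        return self.t_b + self.t_c

    @property
    def total_bcd(self) -> float:
        return self.t_b + self.t_c + self.t_d

    def scaled(self, factor: float) -> "ThreeTaxonTree":
        return ThreeTaxonTree(
            self.t_a * factor, self.t_b * factor, self.t_c * factor, self.t_d * factor
        )

    def to_newick(self, taxa: tuple[str, str, str] = ("SH", "SP", "SL")) -> str:
        sh, sp, sl = taxa
        return f"(({sh}:{self.t_c:.10g},{sp}:{self.t_d:.10g}):{self.t_b:.10g},{sl}:{self.t_a:.10g});"


@dataclass(frozen=True)
class TreeSet:
    """An ordered collection of trees (e.g. a posterior-sample stand-in)."""

    trees: tuple[ThreeTaxonTree, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("TreeSet must contain at least one tree")
        object.__setattr__(self, "trees", tuple(self.trees))

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def _map_tree(tree: dendropy.Tree, taxa: tuple[str, str, str]) -> ThreeTaxonTree:
    sh_name, sp_name, sl_name = taxa
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    for name in taxa:
        if name not in labels:
            raise TreeError(f"taxon {name!r} not found in tree (tips: {sorted(labels)})")
    extra = labels - set(taxa)
    if extra:
        logger.info("pruning %d extra taxa: %s", len(extra), sorted(extra))
        tree = tree.extract_tree_with_taxa_labels(list(taxa))

    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    sh, sp, sl = leaves[sh_name], leaves[sp_name], leaves[sl_name]

    def edge_len(node, who: str) -> float:
        length = node.edge.length
        if length is None:
            raise TreeError(f"missing branch length on the edge leading to {who!r}")
        return float(length)

    # topology check: SH and SP must be sisters to the exclusion of SL
    if sh.parent_node is not sp.parent_node or sh.parent_node is sl.parent_node:
        raise TreeError(
            f"tree does not have topology (({sh_name},{sp_name}),{sl_name})"
        )
    internal = sh.parent_node
    return ThreeTaxonTree(
        t_a=edge_len(sl, sl_name),
        t_b=edge_len(internal, f"ancestor of {sh_name}/{sp_name}"),
        t_c=edge_len(sh, sh_name),
        t_d=edge_len(sp, sp_name),
    )


def read_tree(path, taxa: tuple[str, str, str] = ("SH", "SP", "SL")) -> ThreeTaxonTree:
    """Read a Newick tree and map it to branch roles a/b/c/d.

    Parameters
    ----------
    path : str or os.PathLike
        Newick file with branch lengths.
    taxa : (SH label, SP label, SL label)
        Exact tip labels of the two donor species and the recipient.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return _map_tree(tree, taxa)


def read_tree_set(
    path, taxa: tuple[str, str, str] = ("SH", "SP", "SL"), source_label: str = ""
) -> TreeSet:
    """Read a multi-tree Newick file (one tree per statement) as a TreeSet."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    if not trees:
        raise TreeError(f"no trees found in {path}")
    return TreeSet(
        trees=tuple(_map_tree(t, taxa) for t in trees),
        source_label=source_label or str(path),
    )


def write_tree(tree: ThreeTaxonTree, path, taxa=("SH", "SP", "SL")) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick(taxa) + "\n")


def write_tree_set(trees: TreeSet, path, taxa=("SH", "SP", "SL")) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(t.to_newick(taxa) + "\n")


def enforce_clock(tree: ThreeTaxonTree) -> ThreeTaxonTree:
    """Force ultrametricity by averaging the two donor terminal branches.

    ``t_c' = t_d' = (t_c + t_d)/2`` and ``t_a' = t_b + t_c'``.  Idempotent,
    preserves ``t_b``.  This deliberately replaces penalized-likelihood
    rate smoothing: on a tree already pruned to three taxa the clock has a
    single degree of freedom and averaging is exact.
    """
    mean_term = (tree.t_c + tree.t_d) / 2.0
    return replace(tree, t_c=mean_term, t_d=mean_term, t_a=tree.t_b + mean_term)
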