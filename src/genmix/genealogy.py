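"""Local gene trees from phased haplotypes, and their bi-/trisections.

The chromosome is segmented into (overlapping) intervals in which every
pair of sites passes the four-gamete test, so the interval's haplotypes
are consistent with a single rooted tree under the infinite-sites model.
For each focal SNP a maximal compatible interval is grown, a rooted binary
perfect phylogeny is built over the distinct interval haplotypes, and the
tree is cut into at most seven haplotype clusterings:

* cut 1 -- bisection at the root (2 groups);
* cuts 2-3 -- trisections at the two depth-1 internal nodes (3 groups:
  everything outside the node, plus the node's two child clades);
* cuts 4-7 -- trisections at the four depth-2 internal nodes.

Nodes that do not exist (shallow trees) or are leaves yield no cut.

Determinism choices: the derived allele at a site is the minor allele; the
root is the all-ancestral haplotype (virtual if unobserved); multifurcating
nodes are resolved by ordering children by descending leaf count (ties by
smallest leaf haplotype string) and left-combining into a ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Optional

import numpy as np

from .errors import DataError
from .haplotypes import HaplotypeMatrix

__all__ = [
    "four_gamete_compatible",
    "pairwise_compatibility",
    "CompatibleInterval",
    "maximal_compatible_interval",
    "TreeNode",
    "GeneTree",
    "build_perfect_phylogeny",
    "FactorClustering",
    "extract_factors",
    "counts_matrix",
]


# ---------------------------------------------------------------------------
# four-gamete test and compatible intervals
# ---------------------------------------------------------------------------

def four_gamete_compatible(hap: HaplotypeMatrix, site_a: int, site_b: int) -> bool:
    """True iff fewer than 4 distinct gametes are observed at the site pair.

    Both sites must be polymorphic among the haplotype rows.
    """
    a = hap.alleles[:, site_a]
    b = hap.alleles[:, site_b]
    for col, site in ((a, site_a), (b, site_b)):
        if col.min() == col.max():
            raise DataError(f"site {site} is monomorphic")
    gametes = {(int(x), int(y)) for x, y in zip(a, b)}
    return len(gametes) < 4


def pairwise_compatibility(hap: HaplotypeMatrix) -> np.ndarray:
    """Boolean matrix of all-pairs four-gamete compatibility.

    Uses four boolean matrix products (one per gamete type), so the cost is
    a handful of BLAS calls rather than a Python loop over site pairs.
    """
    a = hap.alleles.astype(np.float32)
    na = 1.0 - a
    g11 = a.T @ a
    g10 = a.T @ na
    g01 = na.T @ a
    g00 = na.T @ na
    return ~((g11 > 0.5) & (g10 > 0.5) & (g01 > 0.5) & (g00 > 0.5))


@dataclass(frozen=True)
class CompatibleInterval:
    """Inclusive site-index interval around a focal SNP."""

    focal_site: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if not (self.left <= self.focal_site <= self.right):
            raise ValueError("interval must contain its focal site")

    @property
    def sites(self) -> np.ndarray:
        return np.arange(self.left, self.right + 1)


def maximal_compatible_interval(
    hap: HaplotypeMatrix,
    focal_site: int,
    compat: Optional[np.ndarray] = None,
) -> CompatibleInterval:
    """Grow a maximal pairwise-compatible interval around ``focal_site``.

    Single-site extensions alternate right, left, right, ... and each
    candidate is accepted only if compatible with every site already in the
    interval.  Once a side fails it stays closed (compatibility with a
    growing set is monotone), so the result cannot be extended on either
    side.  ``compat`` may carry a precomputed pairwise-compatibility matrix.
    """
    if compat is None:
        compat = pairwise_compatibility(hap)
    m = hap.n_sites
    left = right = focal_site
    right_open = right + 1 < m
    left_open = left > 0

    def ok(candidate: int) -> bool:
        return bool(np.all(compat[candidate, left : right + 1]))

    while right_open or left_open:
        if right_open:
            if ok(right + 1):
                right += 1
                right_open = right + 1 < m
            else:
                right_open = False
        if left_open:
            if ok(left - 1):
                left -= 1
                left_open = left > 0
            else:
                left_open = False
    return CompatibleInterval(focal_site, left, right)


# ---------------------------------------------------------------------------
# perfect phylogeny
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted binary gene tree.

    Leaves carry the distinct haplotype string (``hap``, tuple of 0/1 over
    the interval's informative sites) and the indices of matrix rows that
    match it.  Internal nodes have exactly two children.
    """

    children: list["TreeNode"] = field(default_factory=list)
    hap: Optional[tuple] = None
    rows: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_rows(self) -> list[int]:
        return [r for leaf in self.leaves() for r in leaf.rows]

    def min_hap(self) -> tuple:
        return min(leaf.hap for leaf in self.leaves())

    def n_leaves(self) -> int:
        return len(self.leaves())


@dataclass
class GeneTree:
    """Rooted binary perfect phylogeny over distinct interval haplotypes."""

    root: TreeNode
    interval: CompatibleInterval
    n_rows: int

    @property
    def n_leaves(self) -> int:
        return self.root.n_leaves()


def build_perfect_phylogeny(
    hap: HaplotypeMatrix, interval: CompatibleInterval
) -> GeneTree:
    """Build the rooted binary gene tree for a compatible interval.

    Every site's derived-allele carriers form a clade.  Sites monomorphic
    within the interval (none, after upstream MAF filtering on the full
    matrix, unless rows were subset) are ignored.
    """
    sub = hap.alleles[:, interval.left : interval.right + 1].astype(np.int8)
    n_rows = sub.shape[0]
    # polarize: derived allele = minor allele (ties: allele 1 is derived)
    freq1 = sub.mean(axis=0)
    derived_is_one = freq1 <= 0.5
    polar = np.where(derived_is_one, sub, 1 - sub).astype(np.uint8)
    # drop sites monomorphic across these rows
    poly = polar.max(axis=0) > polar.min(axis=0)
    polar = polar[:, poly]

    uniq, inverse = np.unique(polar, axis=0, return_inverse=True)
    n_haps = uniq.shape[0]
    leaf_rows: list[list[int]] = [[] for _ in range(n_haps)]
    for row, h in enumerate(inverse):
        leaf_rows[h].append(row)
    leaves = [
        TreeNode(hap=tuple(int(x) for x in uniq[h]), rows=leaf_rows[h])
        for h in range(n_haps)
    ]
    if n_haps == 1:
        return GeneTree(leaves[0], interval, n_rows)

    # laminar family of derived-carrier sets, one per distinct site pattern
    clusters = {frozenset(np.flatnonzero(uniq[:, j])) for j in range(uniq.shape[1])}
    clusters.discard(frozenset())
    clusters.discard(frozenset(range(n_haps)))
    ordered = sorted(clusters, key=lambda s: (-len(s), sorted(s)))

    universe = frozenset(range(n_haps))
    # containment forest: each cluster hangs under the smallest strict superset
    children_of: dict[frozenset, list[frozenset]] = {universe: []}
    for s in ordered:
        parent = universe
        # ordered by decreasing size, so the last strict superset seen wins
        for t in ordered:
            if len(t) <= len(s):
                break
            if s < t:
                parent = t
        if s == parent:  # pragma: no cover - defensive
            raise DataError("incompatible sites slipped past the four-gamete test")
        children_of.setdefault(s, [])
        children_of[parent].append(s)

    def covered(s: frozenset) -> frozenset:
        return frozenset().union(*children_of[s]) if children_of[s] else frozenset()

    def build(s: frozenset) -> TreeNode:
        kids = [build(t) for t in children_of[s]]
        for h in sorted(s - covered(s)):
            kids.append(leaves[h])
        return _binarize(kids)

    return GeneTree(build(universe), interval, n_rows)


def _binarize(kids: list[TreeNode]) -> TreeNode:
    """Resolve a multifurcation into a deterministic binary ladder."""
    if len(kids) == 1:
        return kids[0]
    kids = sorted(kids, key=lambda c: (-c.n_leaves(), c.min_hap()))
    return reduce(lambda a, b: TreeNode(children=[a, b]), kids)


# ---------------------------------------------------------------------------
# factor extraction and design counts
# ---------------------------------------------------------------------------

@dataclass
class FactorClustering:
    """Assignment of every haplotype row to one of 2 or 3 groups.

    ``cut_id`` numbers the tree cut (1 = root bisection, 2-3 = depth-1
    trisections, 4-7 = depth-2 trisections).  For a trisection, group 0 is
    the haplotypes outside the cut node, groups 1 and 2 its two child
    clades.  For the bisection, groups 0 and 1 are the two root clades.
    """

    cut_id: int
    n_groups: int
    group_of_row: np.ndarray  # (n_rows,) of int group labels

    def __post_init__(self) -> None:
        self.group_of_row = np.asarray(self.group_of_row, dtype=np.int64)
        if self.n_groups == 2 and self.cut_id != 1:
            raise ValueError("only the root cut (cut_id 1) may bisect")
        if np.any(self.group_of_row < 0) or np.any(self.group_of_row >= self.n_groups):
            raise ValueError("group labels out of range")

    def group_sizes(self) -> np.ndarray:
        """Haplotype copies per group."""
        return np.bincount(self.group_of_row, minlength=self.n_groups)


def extract_factors(tree: GeneTree) -> list[FactorClustering]:
    """Cut a gene tree into at most seven haplotype clusterings.

    Returns the root bisection followed by trisections at existing depth-1
    and depth-2 internal nodes (left to right); an empty list for a
    single-leaf tree.
    """
    root = tree.root
    if root.is_leaf:
        return []
    n_rows = tree.n_rows
    out: list[FactorClustering] = []

    def rows_under(node: TreeNode) -> np.ndarray:
        return np.asarray(node.leaf_rows(), dtype=np.int64)

    # cut 1: bisection at the root
    groups = np.zeros(n_rows, dtype=np.int64)
    groups[rows_under(root.children[1])] = 1
    out.append(FactorClustering(1, 2, groups))

    # cuts 2-3 at depth 1, cuts 4-7 at depth 2
    depth1 = list(root.children)
    depth2 = [c for node in depth1 if not node.is_leaf for c in node.children]
    for cut_id, node in zip(range(2, 4), depth1):
        if not node.is_leaf:
            out.append(_trisect(node, cut_id, n_rows))
    for cut_id, node in zip(range(4, 8), depth2):
        if not node.is_leaf:
            out.append(_trisect(node, cut_id, n_rows))
    return out


def _trisect(node: TreeNode, cut_id: int, n_rows: int) -> FactorClustering:
    groups = np.zeros(n_rows, dtype=np.int64)
    groups[np.asarray(node.children[0].leaf_rows(), dtype=np.int64)] = 1
    groups[np.asarray(node.children[1].leaf_rows(), dtype=np.int64)] = 2
    return FactorClustering(cut_id, 3, groups)


def counts_matrix(
    clustering: FactorClustering, hap: HaplotypeMatrix
) -> np.ndarray:
    """Per-individual haplotype-copy counts, ``(n_individuals, n_groups)``.

    Row ``i`` counts how many of individual ``i``'s two haplotypes fall in
    each group; rows sum to 2.
    """
    g = clustering.group_of_row
    if len(g) != hap.n_haplotypes:
        raise DataError("clustering does not cover all haplotype rows")
    n = hap.n_individuals
    counts = np.zeros((n, clustering.n_groups), dtype=np.int64)
    idx = np.arange(2 * n) // 2
    np.add.at(counts, (idx, g), 1)
    return counts
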