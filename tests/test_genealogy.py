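"""Four-gamete segmentation, perfect phylogeny, and tree cutting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import genmix as gx
from genmix.errors import DataError
from genmix.genealogy import _binarize, TreeNode

from conftest import make_hap


def brute_force_gametes(alleles, a, b):
    return {(int(x), int(y)) for x, y in zip(alleles[:, a], alleles[:, b])}


def compatible_matrix_from_pool(n_rows, n_sites, rng):
    """Pairwise-compatible matrix: rows drawn from a mutation genealogy."""
    pool = gx.founder_haplotype_pool(n_sites, rng, pool_size=8, min_clade=1)
    rows = pool[rng.integers(8, size=n_rows)]
    return rows


# ---------------------------------------------------------------------------
# four-gamete test
# ---------------------------------------------------------------------------

def test_four_gametes_present_is_incompatible(hap_factory):
    hap = hap_factory([[0, 0], [0, 1], [1, 0], [1, 1]])
    assert not gx.four_gamete_compatible(hap, 0, 1)


def test_three_gametes_is_compatible(hap_factory):
    hap = hap_factory([[0, 0], [0, 1], [1, 1], [1, 1]])
    assert gx.four_gamete_compatible(hap, 0, 1)


def test_monomorphic_site_rejected(hap_factory):
    hap = hap_factory([[0, 0], [0, 1]])
    with pytest.raises(DataError, match="monomorphic"):
        gx.four_gamete_compatible(hap, 0, 1)


@given(
    st.lists(
        st.tuples(st.integers(0, 1), st.integers(0, 1)),
        min_size=4,
        max_size=20,
    )
)
@settings(max_examples=60, derandomize=True)
def test_four_gamete_property(pairs):
    """Compatibility is exactly 'fewer than four gamete types observed'."""
    arr = np.array(pairs + [(0, 0), (1, 1)], dtype=np.uint8)
    if arr[:, 0].min() == arr[:, 0].max() or arr[:, 1].min() == arr[:, 1].max():
        return
    if len(arr) % 2:
        arr = np.vstack([arr, arr[0]])
    hap = make_hap(arr)
    expected = len({tuple(r) for r in arr}) < 4
    assert gx.four_gamete_compatible(hap, 0, 1) is expected


@pytest.mark.parametrize("seed", range(25))
def test_four_gamete_agrees_with_enumeration(seed):
    """Both the scalar test and the all-pairs matrix match brute force."""
    rng = np.random.default_rng(seed)
    alleles = rng.integers(0, 2, size=(20, 4)).astype(np.uint8)
    # ensure polymorphism
    alleles[0] = 0
    alleles[1] = 1
    hap = make_hap(alleles)
    compat = gx.pairwise_compatibility(hap)
    for a, b in itertools.combinations(range(4), 2):
        expected = len(brute_force_gametes(alleles, a, b)) < 4
        assert gx.four_gamete_compatible(hap, a, b) is expected
        assert compat[a, b] == expected


# ---------------------------------------------------------------------------
# maximal compatible intervals
# ---------------------------------------------------------------------------

def test_interval_covers_whole_chromosome_for_copied_site(hap_factory):
    col = np.array([0, 0, 1, 1, 0, 1])
    hap = hap_factory(np.tile(col[:, None], (1, 9)))
    iv = gx.maximal_compatible_interval(hap, 4)
    assert (iv.left, iv.right) == (0, 8)


def test_interval_degenerate_when_flanked_by_incompatible(hap_factory):
    # sites 0 and 2 show all four gametes against site 1
    hap = hap_factory(
        [
            [0, 0, 0],
            [0, 0, 1],
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
            [0, 1, 1],
        ]
    )
    iv = gx.maximal_compatible_interval(hap, 1)
    assert (iv.left, iv.right) == (1, 1)


@pytest.mark.parametrize("seed", range(15))
def test_interval_maximal_and_all_pairs_compatible(seed):
    rng = np.random.default_rng(seed)
    alleles = compatible_matrix_from_pool(16, 10, rng)
    # splice two incompatible-ish random blocks around it
    noise = rng.integers(0, 2, size=(16, 10)).astype(np.uint8)
    alleles = np.hstack([noise, alleles, noise[:, ::-1]])
    keep = (alleles.min(0) == 0) & (alleles.max(0) == 1)
    hap = make_hap(alleles[:, keep])
    focal = hap.n_sites // 2
    iv = gx.maximal_compatible_interval(hap, focal)
    sites = list(range(iv.left, iv.right + 1))
    for a, b in itertools.combinations(sites, 2):
        assert gx.four_gamete_compatible(hap, a, b)
    for cand in (iv.left - 1, iv.right + 1):
        if 0 <= cand < hap.n_sites:
            assert not all(
                gx.four_gamete_compatible(hap, cand, s) for s in sites
            )


# ---------------------------------------------------------------------------
# perfect phylogeny
# ---------------------------------------------------------------------------

def leaf_sets(node):
    """Derived clade row-sets of every node in the tree."""
    out = [frozenset(node.leaf_rows())]
    for c in node.children:
        out.extend(leaf_sets(c))
    return out


def test_single_site_root_bisection(hap_factory):
    hap = hap_factory([[0], [0], [0], [1]])
    tree = gx.build_perfect_phylogeny(
        hap, gx.CompatibleInterval(0, 0, 0)
    )
    assert tree.n_leaves == 2
    factors = gx.extract_factors(tree)
    assert factors[0].n_groups == 2
    # carriers vs non-carriers
    assert set(np.flatnonzero(factors[0].group_of_row == factors[0].group_of_row[3])) == {3}


def test_caterpillar_rooting_at_ancestral_haplotype(hap_factory):
    # haplotypes 00 (x2, ancestral), 10, 11: ladder ((11,10),00)
    hap = hap_factory([[0, 0], [0, 0], [1, 0], [1, 1]])
    tree = gx.build_perfect_phylogeny(hap, gx.CompatibleInterval(0, 0, 1))
    assert tree.n_leaves == 3
    # every site's derived carriers form a clade
    clades = set(leaf_sets(tree.root))
    assert frozenset({2, 3}) in clades  # derived at site 0
    assert frozenset({3}) in clades  # derived at site 1
    # the ancestral haplotype sits alone at the root split
    root_kids = [frozenset(c.leaf_rows()) for c in tree.root.children]
    assert frozenset({0, 1}) in root_kids


@pytest.mark.parametrize("seed", range(20))
def test_every_derived_set_is_a_clade(seed):
    """Clade-property oracle on compatible matrices up to 8 sites x 16 rows."""
    rng = np.random.default_rng(seed)
    alleles = compatible_matrix_from_pool(16, 8, rng)
    keep = (alleles.min(0) == 0) & (alleles.max(0) == 1)
    alleles = alleles[:, keep]
    if alleles.shape[1] == 0:
        pytest.skip("all sites monomorphic in this draw")
    hap = make_hap(alleles)
    iv = gx.CompatibleInterval(0, 0, hap.n_sites - 1)
    tree = gx.build_perfect_phylogeny(hap, iv)
    clades = set(leaf_sets(tree.root))
    all_rows = frozenset(range(16))
    for j in range(hap.n_sites):
        carriers = frozenset(np.flatnonzero(alleles[:, j]))
        derived = carriers if len(carriers) * 2 <= 16 else all_rows - carriers
        assert derived in clades or (all_rows - derived) in clades
    # leaves partition all rows
    leaves = tree.root.leaves()
    rows = sorted(r for leaf in leaves for r in leaf.rows)
    assert rows == list(range(16))
    haps = [leaf.hap for leaf in leaves]
    assert len(set(haps)) == len(haps)
    # binary internal nodes throughout
    def check(node):
        assert node.is_leaf or len(node.children) == 2
        for c in node.children:
            check(c)
    check(tree.root)


# ---------------------------------------------------------------------------
# factor extraction
# ---------------------------------------------------------------------------

def balanced_depth3_hap():
    """16 rows, 8 distinct haplotypes forming a complete depth-3 tree."""
    clades = [
        {0, 1, 2, 3},
        {4, 5, 6, 7},
        {0, 1},
        {2, 3},
        {4, 5},
        {6, 7},
        {1},
        {3},
        {5},
        {7},
    ]
    uniq = np.zeros((8, len(clades)), dtype=np.uint8)
    for j, cl in enumerate(clades):
        uniq[list(cl), j] = 1
    rows = np.repeat(uniq, 2, axis=0)
    return make_hap(rows)


def test_complete_depth3_tree_gives_seven_factors():
    hap = balanced_depth3_hap()
    tree = gx.build_perfect_phylogeny(
        hap, gx.CompatibleInterval(0, 0, hap.n_sites - 1)
    )
    factors = gx.extract_factors(tree)
    assert len(factors) == 7
    assert [f.n_groups for f in factors] == [2, 3, 3, 3, 3, 3, 3]
    assert [f.cut_id for f in factors] == [1, 2, 3, 4, 5, 6, 7]
    for f in factors:
        # groups partition all rows
        assert np.all(np.bincount(f.group_of_row, minlength=f.n_groups) > 0)
        assert len(f.group_of_row) == 16


def test_two_leaf_tree_gives_only_bisection(hap_factory):
    hap = hap_factory([[0], [1], [0], [1]])
    tree = gx.build_perfect_phylogeny(hap, gx.CompatibleInterval(0, 0, 0))
    factors = gx.extract_factors(tree)
    assert len(factors) == 1
    assert factors[0].n_groups == 2


def test_single_leaf_tree_gives_no_factors(hap_factory):
    hap = make_hap(np.zeros((4, 1), dtype=np.uint8))
    tree = gx.build_perfect_phylogeny(hap, gx.CompatibleInterval(0, 0, 0))
    assert gx.extract_factors(tree) == []


def test_caterpillar_factor_memberships_match_clades(hap_factory):
    # 4 distinct haplotypes in a ladder: clades {3}, {2,3}, {1,2,3}
    hap = hap_factory(
        [
            [0, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 1],
        ]
    )
    tree = gx.build_perfect_phylogeny(hap, gx.CompatibleInterval(0, 0, 2))
    factors = gx.extract_factors(tree)
    # ladder: root splits {1,2,3} | {0}; depth-1 node {1,2,3} splits {2,3}|{1};
    # depth-2 node {2,3} splits {3}|{2}
    assert [f.cut_id for f in factors] == [1, 2, 4]
    by_cut = {f.cut_id: f for f in factors}
    tri = by_cut[2]
    g = tri.group_of_row
    assert g[0] == 0  # outside the cut node
    assert {frozenset(np.flatnonzero(g == 1)), frozenset(np.flatnonzero(g == 2))} == {
        frozenset({2, 3}),
        frozenset({1}),
    }


def test_factor_count_bounds_on_random_trees():
    rng = np.random.default_rng(3)
    for _ in range(10):
        alleles = compatible_matrix_from_pool(16, 8, rng)
        keep = (alleles.min(0) == 0) & (alleles.max(0) == 1)
        alleles = alleles[:, keep]
        if alleles.shape[1] == 0:
            continue
        hap = make_hap(alleles)
        tree = gx.build_perfect_phylogeny(
            hap, gx.CompatibleInterval(0, 0, hap.n_sites - 1)
        )
        factors = gx.extract_factors(tree)
        if tree.n_leaves >= 2:
            assert 1 <= len(factors) <= 7
        for f in factors:
            sizes = f.group_sizes()
            assert sizes.sum() == 16


def test_binarize_orders_by_leaf_count_then_haplotype():
    a = TreeNode(hap=(0, 0), rows=[0])
    b = TreeNode(hap=(0, 1), rows=[1])
    big = TreeNode(children=[a, b])
    c = TreeNode(hap=(1, 0), rows=[2])
    root = _binarize([c, big])
    # the larger child is placed first (left)
    assert root.children[0] is big
    assert root.children[1] is c


# ---------------------------------------------------------------------------
# design counts
# ---------------------------------------------------------------------------

def test_counts_examples(hap_factory):
    hap = hap_factory([[0], [0], [0], [1]])  # ind0: 00, ind1: 01
    f = gx.FactorClustering(1, 2, np.array([0, 0, 0, 1]))
    counts = gx.counts_matrix(f, hap)
    assert counts.tolist() == [[2, 0], [1, 1]]

    # heterozygous across groups 1 and 3 of a trisection -> (1, 0) free counts
    hap2 = hap_factory([[0, 0], [0, 0]])
    tri = gx.FactorClustering(2, 3, np.array([0, 2]))
    c = gx.counts_matrix(tri, hap2)
    assert c.tolist() == [[1, 0, 1]]


def test_counts_column_sums_equal_group_totals():
    rng = np.random.default_rng(11)
    for _ in range(10):
        n_ind = int(rng.integers(2, 12))
        hap = make_hap(np.zeros((2 * n_ind, 1), dtype=np.uint8))
        groups = rng.integers(0, 3, size=2 * n_ind)
        groups[:3] = [0, 1, 2]  # all groups present
        f = gx.FactorClustering(2, 3, groups)
        counts = gx.counts_matrix(f, hap)
        # direct recount oracle
        for g in range(3):
            assert counts[:, g].sum() == np.sum(groups == g)
        assert counts.sum() == 2 * n_ind


def test_counts_requires_full_assignment(hap_factory):
    hap = hap_factory([[0], [1], [0], [1]])
    f = gx.FactorClustering(1, 2, np.array([0, 1]))  # only 2 of 4 rows
    with pytest.raises(DataError):
        gx.counts_matrix(f, hap)
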