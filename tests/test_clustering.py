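import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from phagenet import (
    GeneratorSpec,
    InfectionMatrix,
    cut_dendrogram,
    gen_modular,
    info_remaining,
    mrpp,
    select_groups,
    to_newick,
    two_way_order,
    ward_dendrogram,
)
from tests.conftest import random_matrix


def _mat(entries):
    a = np.asarray(entries)
    return InfectionMatrix(a,
                           tuple(f"r{i}" for i in range(a.shape[0])),
                           tuple(f"c{j}" for j in range(a.shape[1])))


def ess(x, groups):
    return sum(float(((x[g] - x[g].mean(axis=0)) ** 2).sum()) for g in groups)


# -- Ward dendrograms --------------------------------------------------------

def test_identical_rows_merge_at_zero():
    d = ward_dendrogram(_mat([[1, 0], [1, 0]]), "rows")
    assert len(d.merges) == 1 and d.heights[0] == 0.0


def test_three_point_hand_lance_williams():
    # rows [0,0],[0,1],[1,1]: first merge joins an adjacent pair at height 1
    d = ward_dendrogram(_mat([[0, 0], [0, 1], [1, 1]]), "rows")
    a, b, h, size = d.merges[0]
    assert h == pytest.approx(1.0) and {a, b} in ({0, 1}, {1, 2})
    assert size == 2
    # final Ward height: d(2, {0,1})^2 = (2*d02^2 + 2*d12^2 - d01^2)/3 = 5/3
    assert d.heights[1] == pytest.approx(np.sqrt(5 / 3))


def test_invariant_to_column_order(rng):
    m = random_matrix(rng, 8, 6)
    perm = m.permuted(None, rng.permutation(m.c))
    d1 = ward_dendrogram(m, "rows")
    d2 = ward_dendrogram(perm, "rows")
    assert d1.merges == d2.merges and d1.leaf_order == d2.leaf_order


def test_single_item_axis_is_trivial():
    d = ward_dendrogram(_mat([[1, 0]]), "rows")
    assert d.merges == () and d.leaf_order == (0,) and d.degenerate


def test_agrees_with_scipy_ward(rng):
    # independent route: scipy's ward implementation.  Binary profiles make
    # distance ties common and tie-breaks differ, so the tie-invariant
    # quantity is compared always (total ESS = sum h^2/2) and the full
    # height sequence whenever the trees coincide structurally
    exact_matches = 0
    for _ in range(10):
        m = random_matrix(rng, 9, 7)
        mine = ward_dendrogram(m, "rows")
        z = linkage(np.asarray(m.entries, float), method="ward")
        h_mine = np.array(sorted(mine.heights))
        h_scipy = np.array(sorted(z[:, 2]))
        assert (h_mine**2).sum() == pytest.approx((h_scipy**2).sum())
        exact_matches += np.allclose(h_mine, h_scipy, atol=1e-9)
    assert exact_matches >= 5


def test_heights_match_direct_ess_oracle(rng):
    # Ward height h of a merge satisfies ESS increase = h^2 / 2
    for _ in range(10):
        m = random_matrix(rng, 10, 8)
        x = np.asarray(m.entries, float)
        d = ward_dendrogram(m, "rows")
        clusters = {i: [i] for i in range(m.r)}
        nid = m.r
        prev_ess = 0.0
        for a, b, h, _ in d.merges:
            clusters[nid] = clusters.pop(a) + clusters.pop(b)
            nid += 1
            cur = ess(x, list(clusters.values()))
            assert cur - prev_ess == pytest.approx(h**2 / 2, abs=1e-9)
            prev_ess = cur


def test_merge_heights_nondecreasing(rng):
    for _ in range(10):
        m = random_matrix(rng, 10, 6)
        h = ward_dendrogram(m, "rows").heights
        assert all(h[i] <= h[i + 1] + 1e-9 for i in range(len(h) - 1))


# -- information remaining ---------------------------------------------------

def test_info_remaining_endpoints(rng):
    m = random_matrix(rng, 8, 6)
    info = info_remaining(ward_dendrogram(m, "rows"))
    assert info[0] == 100.0 and info[-1] == pytest.approx(0.0)
    assert len(info) == m.r


def test_info_remaining_two_tight_pairs():
    m = _mat([[1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
              [1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
              [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1],
              [0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1]])
    info = info_remaining(ward_dendrogram(m, "rows"))
    assert info[2] > 90.0  # after both within-pair merges


def test_info_remaining_identical_items_degenerate():
    d = ward_dendrogram(_mat([[1, 0], [1, 0], [1, 0]]), "rows")
    assert all(v == 100.0 for v in d.info_remaining)
    assert d.degenerate


# -- MRPP --------------------------------------------------------------------

def test_mrpp_duplicated_points_give_a_one():
    x = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
    dist = squareform(pdist(x))
    a, delta, p = mrpp(dist, [0, 0, 1, 1], n_perm=200, seed=1)
    assert delta == 0.0 and a == 1.0


def test_mrpp_random_labels_near_zero(rng):
    x = rng.normal(size=(16, 3))
    dist = squareform(pdist(x))
    stats = [mrpp(dist, rng.permutation([0] * 8 + [1] * 8),
                  n_perm=199, seed=s)[0] for s in range(20)]
    assert abs(np.mean(stats)) < 0.05
    ps = [mrpp(dist, rng.permutation([0] * 8 + [1] * 8),
               n_perm=199, seed=s)[2] for s in range(20)]
    assert np.mean(np.array(ps) > 0.05) >= 0.7


def test_mrpp_exhaustive_oracle_two_tight_pairs():
    # 4 points in two tight pairs; 3 distinct balanced labelings exist
    x = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
    dist = squareform(pdist(x))
    labelings = [(0, 0, 1, 1), (0, 1, 0, 1), (0, 1, 1, 0)]
    deltas = {}
    for lab in labelings:
        _, delta, _ = mrpp(dist, lab, n_perm=50, seed=0)
        deltas[lab] = delta
    assert min(deltas, key=deltas.get) == (0, 0, 1, 1)
    # correct pairing achieves the smallest attainable p: (b+1)/(n+1) with
    # b = count of balanced permutations tying the minimal delta
    a, delta, p = mrpp(dist, (0, 0, 1, 1), n_perm=999, seed=2)
    assert delta == pytest.approx(0.1)
    assert p < 0.4  # 8 of 24 raw permutations reproduce the optimal split
    assert a > 0.9


def test_mrpp_rejects_singleton_groups():
    dist = np.zeros((3, 3))
    with pytest.raises(ValueError, match="fewer than 2"):
        mrpp(dist, [0, 0, 1], n_perm=10, seed=0)


def test_mrpp_chance_correction_against_exact_expectation(rng):
    # classical MRPP uses the exact permutation expectation of delta, which
    # for size-weighted groups equals the overall mean pairwise distance
    x = rng.normal(size=(12, 4))
    dist = squareform(pdist(x))
    labels = np.array([0] * 6 + [1] * 6)
    a, delta, _ = mrpp(dist, labels, n_perm=4999, seed=3)
    mu_exact = dist[np.triu_indices(12, k=1)].mean()
    assert a == pytest.approx(1 - delta / mu_exact, abs=0.02)


# -- group selection ---------------------------------------------------------

def test_select_groups_recovers_four_planted_clusters():
    m, _ = gen_modular(GeneratorSpec(r=24, c=8, q=4, p_in=1.0, p_out=0.0))
    x = np.asarray(m.entries, float)
    d = ward_dendrogram(m, "rows")
    sel = select_groups(d, squareform(pdist(x)), k_max=6, n_perm=199, seed=0)
    assert sel.selected_k == 4 and not sel.truncated


def test_select_groups_homogeneous_points_select_nothing(rng):
    m = random_matrix(rng, 14, 10)
    x = np.asarray(m.entries, float)
    d = ward_dendrogram(m, "rows")
    sel = select_groups(d, squareform(pdist(x)), k_max=5, n_perm=199, seed=1)
    # a structureless matrix should not clear the gain threshold
    assert sel.selected_k is None or sel.selected_k == 2


def test_select_groups_truncation_below_true_k():
    m, _ = gen_modular(GeneratorSpec(r=24, c=8, q=4, p_in=1.0, p_out=0.0))
    x = np.asarray(m.entries, float)
    d = ward_dendrogram(m, "rows")
    sel = select_groups(d, squareform(pdist(x)), k_max=3, n_perm=199, seed=0)
    assert sel.selected_k == 3 and sel.truncated


# -- two-way ordering --------------------------------------------------------

def test_two_way_order_preserves_values(rng):
    m = random_matrix(rng, 10, 8)
    ordered, rows_d, cols_d = two_way_order(m)
    assert ordered.F == m.F
    assert sorted(ordered.row_degrees) == sorted(m.row_degrees)
    assert sorted(ordered.col_degrees) == sorted(m.col_degrees)


def test_two_way_order_idempotent(rng):
    m = random_matrix(rng, 8, 6)
    once, _, _ = two_way_order(m)
    twice, _, _ = two_way_order(once)
    assert np.array_equal(once.entries, twice.entries)
    assert once.row_labels == twice.row_labels


def test_two_way_order_makes_planted_blocks_contiguous():
    m, planted = gen_modular(GeneratorSpec(r=16, c=8, q=2, p_in=1.0,
                                           p_out=0.0, seed=4))
    ordered, rows_d, _ = two_way_order(m)
    groups = [planted.row_labels[i] for i in rows_d.leaf_order]
    changes = sum(groups[i] != groups[i + 1] for i in range(len(groups) - 1))
    assert changes == 1  # each block contiguous


def test_newick_export_parses_with_biopython(tmp_path, rng):
    from io import StringIO
    from Bio import Phylo

    m = random_matrix(rng, 7, 5)
    d = ward_dendrogram(m, "rows")
    tree = Phylo.read(StringIO(to_newick(d)), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(m.row_labels)


def test_cut_dendrogram_label_counts(rng):
    m = random_matrix(rng, 9, 6)
    d = ward_dendrogram(m, "rows")
    for k in (1, 3, m.r):
        labels = cut_dendrogram(d, k)
        assert len(np.unique(labels)) == k
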