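import numpy as np
import pytest

from phagenet import (
    DegenerateMatrixError,
    InfectionMatrix,
    br,
    gen_nested,
    GeneratorSpec,
    nodf,
    ntc,
    pack_matrix,
)
from tests.conftest import random_matrix


def _mat(entries):
    a = np.asarray(entries)
    return InfectionMatrix(a,
                           tuple(f"r{i}" for i in range(a.shape[0])),
                           tuple(f"c{j}" for j in range(a.shape[1])))


# -- packing -----------------------------------------------------------------

def test_pack_sorts_by_degree_with_stable_ties():
    m = _mat([[1, 0, 0], [1, 1, 1], [1, 1, 0]])  # k = (1, 3, 2)
    _, row_order, col_order = pack_matrix(m)
    assert list(row_order) == [1, 2, 0]
    m2 = _mat([[1, 0, 1], [1, 1, 0], [0, 0, 1]])  # d = (2, 1, 2)
    _, _, col_order = pack_matrix(m2)
    assert list(col_order) == [0, 2, 1]


def test_pack_of_packed_staircase_is_identity(staircase3):
    packed, row_order, col_order = pack_matrix(staircase3)
    assert list(row_order) == [0, 1, 2] and list(col_order) == [0, 1, 2]
    assert np.array_equal(packed.entries, staircase3.entries)


def test_pack_empty_matrix_is_degenerate():
    with pytest.raises(DegenerateMatrixError):
        pack_matrix(_mat([[0, 0], [0, 0]]))


# -- NODF --------------------------------------------------------------------

def nodf_oracle(a):
    """Independent brute-force NODF: explicit loops over all pairs."""
    def axis_pairs(x):
        vals = []
        n = x.shape[0]
        for i in range(n):
            for k in range(i + 1, n):
                fi, fk = x[i].sum(), x[k].sum()
                if fi == fk or min(fi, fk) == 0:
                    vals.append(0.0)
                else:
                    rich, poor = (x[i], x[k]) if fi > fk else (x[k], x[i])
                    overlap = int(np.logical_and(rich, poor).sum())
                    vals.append(100.0 * overlap / poor.sum())
        return vals
    pairs = axis_pairs(a) + axis_pairs(a.T)
    return sum(pairs) / len(pairs)


@pytest.mark.parametrize("entries,raw", [
    ([[1, 1, 1], [1, 1, 0], [1, 0, 0]], 100.0),   # perfect staircase
    ([[1, 1], [1, 1]], 0.0),                        # equal fills contribute 0
    ([[1, 1, 0], [0, 1, 1]], 50.0),                 # hand-enumerated pairs
])
def test_nodf_examples(entries, raw):
    res = nodf(_mat(entries))
    assert res.raw_score == pytest.approx(raw)
    assert res.score == pytest.approx(100.0 - raw)


def test_nodf_matches_bruteforce_oracle(rng):
    for _ in range(60):
        m = random_matrix(rng)
        assert nodf(m).raw_score == pytest.approx(
            nodf_oracle(np.asarray(m.entries)), abs=1e-12)


def test_nodf_degenerate_single_cell():
    with pytest.raises(DegenerateMatrixError):
        nodf(InfectionMatrix([[1]], ("a",), ("x",)))


def test_nodf_invariant_under_simultaneous_permutation(rng):
    m = random_matrix(rng, 8, 8)
    p = m.permuted(rng.permutation(m.r), rng.permutation(m.c))
    assert nodf(p).score == pytest.approx(nodf(m).score)


# -- temperature -------------------------------------------------------------

def test_ntc_zero_on_perfect_staircase(staircase3):
    assert ntc(staircase3).score == pytest.approx(0.0, abs=1e-9)


def test_ntc_full_matrix_degenerate():
    res = ntc(_mat(np.ones((3, 3), dtype=int)))
    assert res.score == 0.0 and res.degenerate


def test_ntc_antidiagonal_hotter_than_left_justified():
    a = np.zeros((6, 6), dtype=int)
    # checkerboard-corner: presences pushed along the anti-diagonal, which
    # degree packing cannot undo (all degrees tie)
    for i in range(6):
        a[i, 5 - i] = 1
        if i < 5:
            a[i, 4 - i] = 1
    anti = _mat(a)
    # same row degrees, presences left-justified (maximally packed layout)
    k = a.sum(axis=1)
    packed = _mat((np.arange(6)[None, :] < k[:, None]).astype(int))
    assert ntc(anti).score > ntc(packed).score


def test_ntc_invariant_under_permutation(rng):
    m = random_matrix(rng, 8, 8)
    p = m.permuted(rng.permutation(m.r), rng.permutation(m.c))
    assert ntc(p).score == pytest.approx(ntc(m).score, abs=1e-9)


def test_moving_presence_to_far_corner_heats_matrix():
    spec = GeneratorSpec(r=8, c=8, fill=9 / 16)
    m = gen_nested(spec)
    a = np.array(m.entries)
    # move the innermost presence of the first row to the far corner
    a[0, int(a[0].sum()) - 1] = 0
    a[-1, -1] = 1
    moved = _mat(a)
    assert ntc(moved).score >= ntc(m).score
    assert br(moved).score >= br(m).score


# -- BR ----------------------------------------------------------------------

@pytest.mark.parametrize("entries,expected", [
    ([[1, 1, 1], [1, 1, 0], [1, 0, 0]], 0),   # already packed
    ([[1, 0, 1], [1, 1, 0], [0, 0, 1]], 2),   # hand-packed oracle
    ([[0, 1]], 0),                              # filled column ordered first
])
def test_br_examples(entries, expected):
    assert br(_mat(entries)).score == expected


def test_br_invariant_to_row_permutation(rng):
    m = random_matrix(rng, 8, 8)
    p = m.permuted(rng.permutation(m.r), None)
    assert br(p).score == br(m).score


def test_br_zero_iff_equal_to_packed(rng):
    # BR = 0 exactly when the degree-packed arrangement is maximally packed
    # (every row's presences left-justified)
    hits = 0
    for _ in range(30):
        m = random_matrix(rng, 8, 8)
        packed, _, _ = pack_matrix(m)
        cols = np.arange(m.c)
        k = packed.row_degrees
        left_justified = np.array_equal(
            np.asarray(packed.entries),
            (cols[None, :] < k[:, None]).astype(int))
        hits += left_justified
        assert (br(m).score == 0) == left_justified
    # the suite must exercise both branches
    m0 = gen_nested(GeneratorSpec(r=6, c=6, fill=7 / 12))
    assert br(m0).score == 0
    assert hits < 30
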