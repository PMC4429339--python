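"""Nestedness of binary infection matrices: NODF, temperature (NTC), BR.

A matrix is nested when the interaction sets of specialists are subsets of
those of generalists.  Three measures are provided, all reported so that
*lower score = more nested* (0 = perfectly nested):

NODF
    pairwise overlap-and-decreasing-fill metric; computed in its canonical
    [0, 100] form (``raw_score``, higher = more nested) and reported
    rescaled as ``100 - NODF``.
NTC
    nestedness temperature: the normalised sum of squared "unexpectedness"
    of presences and absences on the wrong side of the isocline of perfect
    nestedness, scaled so the maximum expected temperature is 100.
BR
    discrepancy: the number of presences that would have to move to turn
    the matrix into its maximally packed (row-wise left-justified) form.

Temperature is notoriously implementation-sensitive (packing refinement,
isocline family, boundary handling differ between published calculators);
the variant here is fully specified and internally reproducible, but
cross-tool agreement is approximate by nature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .matrix import InfectionMatrix

__all__ = [
    "MeasureResult",
    "DegenerateMatrixError",
    "pack_matrix",
    "nodf",
    "ntc",
    "br",
    "NTC_UMAX",
]

#: Normalisation constant for temperature: the expected per-cell
#: unexpectedness of a maximally disordered matrix, so that T spans [0, 100].
NTC_UMAX = 0.04145


class DegenerateMatrixError(ValueError):
    """The matrix is too degenerate for the requested measure."""


@dataclass(frozen=True)
class MeasureResult:
    """A named structure score.

    ``lower_is_more_structured`` is True for the three nestedness scores
    (0 = perfectly nested) and False for bipartite modularity.
    ``raw_score`` keeps NODF's un-rescaled value; ``degenerate`` flags
    conventions applied to empty/full matrices.
    """

    measure_name: str
    score: float
    lower_is_more_structured: bool = True
    raw_score: float | None = None
    degenerate: bool = False


def pack_matrix(m: InfectionMatrix) -> tuple[InfectionMatrix, np.ndarray, np.ndarray]:
    """Maximally pack: rows by descending degree, columns by descending
    degree, ties kept in original order (stable).

    Returns the packed matrix and the row/column permutations applied, so
    the packing is reproducible and auditable.
    """
    if m.F < 1:
        raise DegenerateMatrixError("cannot pack a matrix with no interactions")
    row_order = np.argsort(-m.row_degrees, kind="stable")
    col_order = np.argsort(-m.col_degrees, kind="stable")
    return m.permuted(row_order, col_order), row_order, col_order


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def _nodf_axis(a: np.ndarray) -> tuple[float, int]:
    """Sum of paired NODF contributions over all unordered row pairs of
    ``a``, plus the pair count."""
    n = a.shape[0]
    if n < 2:
        return 0.0, 0
    deg = a.sum(axis=1)
    overlap = (a @ a.T).astype(float)
    total = 0.0
    for i in range(n):
        for k in range(i + 1, n):
            hi, lo = (i, k) if deg[i] > deg[k] else (k, i)
            # strictly decreasing fill, poorer row nonempty
            if deg[hi] > deg[lo] > 0:
                total += 100.0 * overlap[i, k] / deg[lo]
    return total, n * (n - 1) // 2


def nodf(m: InfectionMatrix) -> MeasureResult:
    """NODF over all row pairs and column pairs.

    A pair contributes ``100 * overlap / degree_of_poorer`` only when fills
    strictly decrease (richer degree > poorer degree > 0); equal-fill pairs
    and pairs with an empty poorer vector contribute 0.  The raw score is
    the mean contribution over all ``r(r-1)/2 + c(c-1)/2`` pairs; the
    reported score is ``100 - raw`` (0 = perfectly nested).
    """
    if m.r < 2 and m.c < 2:
        raise DegenerateMatrixError("NODF needs at least 2 rows or 2 columns")
    a = np.asarray(m.entries, dtype=np.int64)
    row_sum, row_pairs = _nodf_axis(a)
    col_sum, col_pairs = _nodf_axis(a.T)
    raw = (row_sum + col_sum) / (row_pairs + col_pairs)
    return MeasureResult("NODF", score=100.0 - raw, raw_score=raw)


# ---------------------------------------------------------------------------
# Temperature (NTC)
# ---------------------------------------------------------------------------

def _isocline(fill: float) -> tuple[float, callable]:
    """Monotone isocline of perfect nestedness for the given fill.

    One-parameter superellipse family ``u**p + v**p = 1`` on the unit
    square (u: column coordinate from the generalist edge, v: row
    coordinate from the generalist edge); the presence region is
    ``u**p + v**p < 1`` and its area is matched to ``fill`` by root
    finding on p (area is strictly increasing in p).
    """
    from scipy.special import gammaln

    def area(p: float) -> float:
        return float(np.exp(2 * gammaln(1 + 1 / p) - gammaln(1 + 2 / p)))

    lo, hi = 1e-3, 1e3
    p = brentq(lambda q: area(q) - fill, lo, hi, xtol=1e-12, rtol=1e-12)
    assert abs(area(p) - fill) < 1e-9

    def f(u: float) -> float:
        # v on the isocline at column coordinate u
        return (max(0.0, 1.0 - u ** p)) ** (1.0 / p)

    return p, f


def _unexpectedness(u: float, v: float, p: float) -> float:
    """Squared normalised diagonal distance of cell centre (u, v) to the
    isocline, measured along the 45-degree line through the cell."""
    # chord of the unit square along direction (1, 1) through (u, v)
    t_lo, t_hi = -min(u, v), min(1 - u, 1 - v)
    full = t_hi - t_lo
    if full <= 0:
        return 0.0

    def g(t: float) -> float:
        x = u + t
        inside = max(0.0, 1.0 - x ** p)
        return inside ** (1.0 / p) - (v + t)  # >0 inside presence region

    g_lo, g_hi = g(t_lo), g(t_hi)
    if g_lo <= 0:            # whole chord in absence region
        t_star = t_lo
    elif g_hi >= 0:          # whole chord in presence region
        t_star = t_hi
    else:
        t_star = brentq(g, t_lo, t_hi, xtol=1e-12)
    return (abs(t_star) / full) ** 2


def ntc(m: InfectionMatrix) -> MeasureResult:
    """Nestedness temperature of the packed matrix, in [0, 100].

    The matrix is degree-packed; cell centres are mapped to the unit
    square; presences falling in the absence region of the fill-matched
    isocline (and absences in the presence region) contribute their squared
    normalised diagonal distance to the isocline.  ``T = 100 * U /
    NTC_UMAX`` with ``U`` the mean unexpectedness per cell.  Completely
    full or empty matrices have no unexpected cells and score 0 with the
    degeneracy flag set.
    """
    if m.F == 0 or m.F == m.M:
        return MeasureResult("NTC", score=0.0, degenerate=True)
    packed, _, _ = pack_matrix(m)
    a = np.asarray(packed.entries)
    r, c = a.shape
    p, f = _isocline(m.fill)
    u_total = 0.0
    for i in range(r):
        v = (i + 0.5) / r
        for j in range(c):
            u = (j + 0.5) / c
            inside = (u ** p + v ** p) < 1.0
            if bool(a[i, j]) != inside:
                u_total += _unexpectedness(u, v, p)
    t = 100.0 * (u_total / (r * c)) / NTC_UMAX
    return MeasureResult("NTC", score=float(min(100.0, max(0.0, t))))


# ---------------------------------------------------------------------------
# BR discrepancy
# ---------------------------------------------------------------------------

def br(m: InfectionMatrix) -> MeasureResult:
    """Brualdi-Sanderson discrepancy.

    Columns are ordered by descending degree (stable ties); each row of the
    packed reference has its ``k_i`` presences left-justified in that
    order.  BR counts cells where the packed reference has a presence but
    the observed row does not — the number of presences that must move to
    reach a maximally packed matrix.
    """
    if m.M == 0 or m.F == 0:
        return MeasureResult("BR", score=0.0, degenerate=m.F == 0)
    col_order = np.argsort(-m.col_degrees, kind="stable")
    a = np.asarray(m.entries)[:, col_order]
    k = a.sum(axis=1)
    cols = np.arange(a.shape[1])
    packed = (cols[None, :] < k[:, None]).astype(np.int8)
    mismatches = int(((packed == 1) & (a == 0)).sum())
    return MeasureResult("BR", score=float(mismatches))
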