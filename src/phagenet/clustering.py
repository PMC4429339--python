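"""Two-way hierarchical clustering of infection matrices.

Rows (phage types) and columns (typing phages) are clustered independently
with Euclidean distances on the raw 0/1 profiles and Ward's
minimum-variance linkage, mirroring the classical two-way cluster diagram
of a typing scheme.  Dendrogram levels are also expressed on Wishart's
objective-function scale — the percentage of information (within-cluster
error sum of squares) remaining after each merge — and candidate group
numbers are screened with the multiresponse permutation procedure (MRPP).

Ward linkage uses the Lance-Williams recurrence on squared distances,

    d(k, i+j)^2 = ((n_i + n_k) d_ik^2 + (n_j + n_k) d_jk^2
                   - n_k d_ij^2) / (n_i + n_j + n_k),

with heights reported on the distance scale and ties broken toward the
lowest cluster indices, so leaf orders are identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrix import InfectionMatrix

__all__ = [
    "DendrogramResult",
    "GroupSelection",
    "ward_dendrogram",
    "info_remaining",
    "mrpp",
    "select_groups",
    "cut_dendrogram",
    "two_way_order",
    "to_newick",
]


@dataclass(frozen=True)
class GroupSelection:
    """MRPP screen over candidate group numbers k = 2..k_max.

    ``table`` rows are (k, A, p); ``selected_k`` is None when no k clears
    the gain threshold; ``truncated`` flags selection forced to k_max.
    """

    table: tuple[tuple[int, float, float], ...]
    selected_k: int | None
    truncated: bool = False
    epsilon: float = 0.01


@dataclass(frozen=True)
class DendrogramResult:
    """Agglomerative merge tree for one axis of the matrix.

    ``merges`` holds (cluster_a, cluster_b, height, new_size) with the
    scipy convention that original items are clusters 0..n-1 and the i-th
    merge creates cluster n+i.  ``info_remaining`` has one entry per level
    0..n-1: 100 before any merge, 0 after the last.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]
    heights: tuple[float, ...]
    info_remaining: tuple[float, ...]
    leaf_order: tuple[int, ...]
    degenerate: bool = False
    selected_groups: GroupSelection | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def linkage_matrix(self) -> np.ndarray:
        """Merge tree as a scipy-style (n-1) x 4 linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges],
                        dtype=float)


def _profiles(m: InfectionMatrix, axis: str) -> tuple[np.ndarray, tuple[str, ...]]:
    a = np.asarray(m.entries, dtype=float)
    if axis == "rows":
        return a, m.row_labels
    if axis == "columns":
        return a.T, m.col_labels
    raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")


def ward_dendrogram(m: InfectionMatrix, axis: str = "rows") -> DendrogramResult:
    """Ward/Euclidean dendrogram of one axis of the matrix.

    Merges always pick the minimum-height pair, and among equal-height
    pairs the one with the lowest (then second-lowest) cluster index, so
    the tree and its leaf order are deterministic.
    """
    x, labels = _profiles(m, axis)
    n = x.shape[0]
    if n < 1:
        raise ValueError("no items to cluster on this axis")
    if n == 1:
        return DendrogramResult(labels, (), (), (100.0,), (0,),
                                degenerate=True)
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist2: dict[tuple[int, int], float] = {}
    for ii in range(n):
        for jj in range(ii + 1, n):
            dist2[(ii, jj)] = float(d2[ii, jj])
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (min(a, b), max(a, b))
                v = dist2[key]
                if best is None or v < best[0] - 1e-12:
                    best = (v, a, b)
        v, a, b = best
        h = float(np.sqrt(max(v, 0.0)))
        na, nb = sizes[a], sizes[b]
        new = next_id
        next_id += 1
        merges.append((a, b, h, na + nb))
        # Lance-Williams update on squared distances
        for k in active:
            if k in (a, b):
                continue
            nk = sizes[k]
            dak = dist2[(min(a, k), max(a, k))]
            dbk = dist2[(min(b, k), max(b, k))]
            dab = v
            dist2[(min(new, k), max(new, k))] = (
                (na + nk) * dak + (nb + nk) * dbk - nk * dab
            ) / (na + nb + nk)
        active = [c for c in active if c not in (a, b)] + [new]
        sizes[new] = na + nb
        members[new] = members[a] + members[b]
    heights = tuple(h for _, _, h, _ in merges)
    leaf_order = tuple(members[next_id - 1])
    info = _info_levels(x, merges, n)
    return DendrogramResult(labels, tuple(merges), heights, info, leaf_order,
                            degenerate=all(h == 0 for h in heights))


def _info_levels(x: np.ndarray, merges, n: int) -> tuple[float, ...]:
    """Wishart information remaining (percent) at levels 0..n-1."""
    ess_total = _ess(x, [list(range(n))])
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    levels = [100.0]
    next_id = n
    for a, b, _, _ in merges:
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
        ess = _ess(x, list(clusters.values()))
        if ess_total == 0.0:
            levels.append(100.0)
        else:
            levels.append(100.0 * (1.0 - ess / ess_total))
    if ess_total == 0.0:
        return tuple(levels)
    levels[-1] = 0.0  # exact by construction; guard rounding
    return tuple(levels)


def _ess(x: np.ndarray, groups) -> float:
    total = 0.0
    for g in groups:
        pts = x[g]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def info_remaining(d: DendrogramResult) -> tuple[float, ...]:
    """Percentage of information remaining at each merge level (100 before
    any merge, 0 once all items are in one cluster)."""
    return d.info_remaining


def cut_dendrogram(d: DendrogramResult, k: int) -> np.ndarray:
    """Group labels (0..k-1, in leaf order of first appearance) from
    cutting the tree into k clusters."""
    n = d.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    for a, b, _, _ in d.merges[: n - k]:
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    labels = np.empty(n, dtype=int)
    for gid, (_, mem) in enumerate(sorted(clusters.items(),
                                          key=lambda kv: min(kv[1]))):
        labels[mem] = gid
    return labels


def mrpp(distances: np.ndarray, grouping, n_perm: int = 999,
         seed: int | None = None) -> tuple[float, float, float]:
    """Multiresponse permutation procedure.

    Parameters
    ----------
    distances
        Square symmetric pairwise distance matrix.
    grouping
        Group label per item; every group must have >= 2 members.
    n_perm
        Number of label permutations for the reference distribution.

    Returns
    -------
    (A, delta, p)
        ``delta`` is the size-weighted mean within-group distance;
        ``A = 1 - delta / mean(permuted deltas)`` is the chance-corrected
        within-group agreement (1 when all within-group distances are 0,
        near 0 for random grouping); ``p`` is the add-one permutation
        p-value of observing a delta this small.
    """
    dmat = np.asarray(distances, dtype=float)
    g = np.asarray(grouping)
    n = g.size
    if dmat.shape != (n, n):
        raise ValueError("distance matrix shape does not match grouping")
    labs, counts = np.unique(g, return_counts=True)
    if labs.size < 2:
        raise ValueError("MRPP needs at least 2 groups")
    if (counts < 2).any():
        bad = labs[counts < 2][0]
        raise ValueError(f"group {bad!r} has fewer than 2 members; "
                         "within-group mean distance undefined")

    def delta_of(perm_labels: np.ndarray) -> float:
        total = 0.0
        for lab, cnt in zip(labs, counts):
            idx = np.flatnonzero(perm_labels == lab)
            sub = dmat[np.ix_(idx, idx)]
            mean_within = sub[np.triu_indices(cnt, k=1)].mean()
            total += (cnt / n) * mean_within
        return total

    delta = delta_of(g)
    rng = np.random.default_rng(seed)
    perm_deltas = np.array([delta_of(rng.permutation(g))
                            for _ in range(n_perm)])
    mu = float(perm_deltas.mean())
    a_stat = 1.0 - delta / mu if mu > 0 else (1.0 if delta == 0 else np.nan)
    p = (int((perm_deltas <= delta).sum()) + 1) / (n_perm + 1)
    return float(a_stat), float(delta), float(p)


def select_groups(d: DendrogramResult, distances: np.ndarray,
                  k_max: int = 8, n_perm: int = 999,
                  seed: int | None = None,
                  epsilon: float = 0.01) -> GroupSelection:
    """Screen k = 2..k_max dendrogram cuts with MRPP.

    Seeks the fewest groups with the greatest gain in the A-statistic: the
    smallest k whose A-gain over k-1 exceeds ``epsilon`` while the further
    gain to k+1 falls below it.  Cuts producing singleton groups are
    recorded as NaN.  If gains are still above threshold at k_max the
    selection is truncated at k_max; if no k qualifies, ``selected_k`` is
    None.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, d.n_leaves)
    rows: list[tuple[int, float, float]] = []
    a_by_k: dict[int, float] = {1: 0.0}  # one group: no chance-corrected gain
    for k in range(2, k_max + 1):
        labels = cut_dendrogram(d, k)
        _, counts = np.unique(labels, return_counts=True)
        if (counts < 2).any():
            rows.append((k, float("nan"), float("nan")))
            a_by_k[k] = float("nan")
            continue
        a_stat, _, p = mrpp(distances, labels, n_perm=n_perm, seed=seed)
        rows.append((k, a_stat, p))
        a_by_k[k] = a_stat
    selected = None
    truncated = False
    for k in range(2, k_max + 1):
        a_k, a_prev = a_by_k.get(k), a_by_k.get(k - 1)
        if a_k is None or np.isnan(a_k) or a_prev is None or np.isnan(a_prev):
            continue
        gain = a_k - a_prev
        nxt = a_by_k.get(k + 1)
        if k == k_max and not (nxt is not None and not np.isnan(nxt)):
            # cannot see past the truncation point; handled below
            continue
        gain_next = (nxt - a_k) if (nxt is not None and not np.isnan(nxt)) else 0.0
        if gain > epsilon and gain_next <= epsilon:
            selected = k
            break
    if selected is None:
        # gains may still be rising at the truncation point
        a_last, a_prev = a_by_k.get(k_max), a_by_k.get(k_max - 1)
        if a_last is not None and a_prev is not None and \
                not np.isnan(a_last) and not np.isnan(a_prev) and \
                a_last - a_prev > epsilon:
            selected, truncated = k_max, True
    return GroupSelection(tuple(rows), selected, truncated, epsilon)


def two_way_order(m: InfectionMatrix) -> tuple[InfectionMatrix,
                                               DendrogramResult,
                                               DendrogramResult]:
    """Reorder rows and columns by their dendrogram leaf orders.

    Values are untouched; only the display order changes, yielding the
    two-way cluster layout in which related phage types and related typing
    phages sit together.
    """
    if m.r < 2 or m.c < 2:
        raise ValueError("two-way ordering needs at least 2 rows and 2 columns")
    rows = ward_dendrogram(m, "rows")
    cols = ward_dendrogram(m, "columns")
    ordered = m.permuted(rows.leaf_order, cols.leaf_order)
    return ordered, rows, cols


def to_newick(d: DendrogramResult) -> str:
    """Dendrogram as a Newick string with branch lengths on the height
    scale (leaf branch length = height of its first merge)."""
    n = d.n_leaves
    if n == 1:
        return f"{d.labels[0]}:0;"
    node_height = {i: 0.0 for i in range(n)}
    node_repr = {i: d.labels[i] for i in range(n)}
    next_id = n
    for a, b, h, _ in d.merges:
        la = node_repr.pop(a)
        lb = node_repr.pop(b)
        node_repr[next_id] = (
            f"({la}:{h - node_height[a]:g},{lb}:{h - node_height[b]:g})"
        )
        node_height[next_id] = h
        next_id += 1
    return node_repr[next_id - 1] + ";"
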