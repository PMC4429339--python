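"""Bipartite modularity (Barber's Q_B) and its LPAb+ maximiser.

Barber's modularity for a bipartite network with biadjacency matrix A,
row degrees k_i, column degrees d_j and F edges is

    Q_B = (1/F) * sum_ij (A_ij - k_i d_j / F) * delta(g_i, h_j)

where g_i / h_j are the module labels of row node i / column node j.  It
compares within-module edges with the degree-based expectation; Q_B = 0
for the all-in-one-module partition and approaches 1 - 1/q for q equal
perfectly separated blocks.

The maximiser follows the LPAb+ scheme: label-propagation sweeps in which
each node adopts the opposite-side label with the largest modularity gain,
alternated with greedy agglomeration of the module pair with the largest
positive gain, with the best partition kept over many randomised trials.
Every node update and every merge is non-decreasing in Q_B, so each trial
terminates at a local maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import InfectionMatrix
from .nestedness import MeasureResult

__all__ = ["Partition", "barber_modularity", "lpab_plus", "module_count"]


@dataclass(frozen=True)
class Partition:
    """Module labels for both node classes of a bipartite network.

    ``row_labels[i]`` (g_i) and ``col_labels[j]`` (h_j) are opaque integer
    module identifiers; a module may contain nodes of both classes.
    """

    row_labels: tuple[int, ...]
    col_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_labels", tuple(int(x) for x in self.row_labels))
        object.__setattr__(self, "col_labels", tuple(int(x) for x in self.col_labels))

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.row_labels) | set(self.col_labels)))

    def relabeled(self) -> "Partition":
        """Canonical form: labels renumbered 0..q-1 in order of first use."""
        mapping: dict[int, int] = {}
        for lab in list(self.row_labels) + list(self.col_labels):
            if lab not in mapping:
                mapping[lab] = len(mapping)
        return Partition(
            tuple(mapping[x] for x in self.row_labels),
            tuple(mapping[x] for x in self.col_labels),
        )


def module_count(p: Partition) -> int:
    """Number of distinct module labels attached to at least one node."""
    return len(set(p.row_labels) | set(p.col_labels))


def _score_matrix(m: InfectionMatrix) -> np.ndarray:
    """S_ij = A_ij - k_i d_j / F; Q_B = (1/F) sum of S over matched cells."""
    k = m.row_degrees.astype(float)
    d = m.col_degrees.astype(float)
    return np.asarray(m.entries, dtype=float) - np.outer(k, d) / m.F


def barber_modularity(m: InfectionMatrix, p: Partition) -> MeasureResult:
    """Evaluate Q_B for a given partition (higher = more modular)."""
    if m.F == 0:
        raise ValueError("Q_B is undefined for a matrix with no interactions")
    if len(p.row_labels) != m.r or len(p.col_labels) != m.c:
        raise ValueError("partition does not cover all nodes")
    g = np.asarray(p.row_labels)
    h = np.asarray(p.col_labels)
    s = _score_matrix(m)
    q = float(s[g[:, None] == h[None, :]].sum() / m.F)
    return MeasureResult("QB", score=q, lower_is_more_structured=False)


def _onehot(labels: np.ndarray, n_labels: int) -> np.ndarray:
    out = np.zeros((labels.size, n_labels))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _argmax_ties(gains: np.ndarray, current: np.ndarray | None,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-row argmax with ties resolved by: keep the current label when it
    is among the maximisers, otherwise pick uniformly at random."""
    best = gains.max(axis=1)
    is_max = gains >= best[:, None] - 1e-12
    n, L = gains.shape
    # random choice among maximisers via random keys
    keys = rng.random((n, L))
    keys[~is_max] = -1.0
    choice = keys.argmax(axis=1)
    if current is not None:
        keep = is_max[np.arange(n), current]
        choice[keep] = current[keep]
    return choice


def _sweep(s: np.ndarray, g: np.ndarray, h: np.ndarray,
           rng: np.random.Generator, max_sweeps: int = 200
           ) -> tuple[np.ndarray, np.ndarray]:
    """Alternate row/column label-adoption sweeps until a fixed point.

    Row nodes adopt column-side labels and vice versa; each adoption
    maximises the node's own modularity contribution, so Q_B never
    decreases and the loop terminates.
    """
    for _ in range(max_sweeps):
        labs = np.unique(np.concatenate([g, h]))
        remap = {int(l): i for i, l in enumerate(labs)}
        g = np.array([remap[int(x)] for x in g])
        h = np.array([remap[int(x)] for x in h])
        L = labs.size
        g_new = _argmax_ties(s @ _onehot(h, L), g, rng)
        h_new = _argmax_ties(s.T @ _onehot(g_new, L), h, rng)
        if np.array_equal(g_new, g) and np.array_equal(h_new, h):
            break
        g, h = g_new, h_new
    return g, h


def _qb_from_labels(s: np.ndarray, g: np.ndarray, h: np.ndarray, f: int) -> float:
    return float(s[g[:, None] == h[None, :]].sum() / f)


def _best_merge(m: InfectionMatrix, g: np.ndarray, h: np.ndarray
                ) -> tuple[float, int, int]:
    """Largest Q_B gain over all module pair merges, with the pair."""
    labs = np.unique(np.concatenate([g, h]))
    L = labs.size
    remap = {int(l): i for i, l in enumerate(labs)}
    gi = np.array([remap[int(x)] for x in g])
    hi = np.array([remap[int(x)] for x in h])
    a = np.asarray(m.entries, dtype=float)
    R = _onehot(gi, L)
    C = _onehot(hi, L)
    E = R.T @ a @ C                       # E[m, n]: edges rows(m) x cols(n)
    K = R.T @ m.row_degrees.astype(float)
    D = C.T @ m.col_degrees.astype(float)
    f = float(m.F)
    gain = (E + E.T) / f - (np.outer(K, D) + np.outer(D, K)) / f**2
    np.fill_diagonal(gain, -np.inf)
    if L < 2:
        return -np.inf, -1, -1
    idx = int(np.argmax(gain))
    i, j = divmod(idx, L)
    return float(gain[i, j]), int(labs[i]), int(labs[j])


def lpab_plus(m: InfectionMatrix, trials: int = 1000,
              seed: int | np.random.SeedSequence | None = None
              ) -> tuple[Partition, MeasureResult]:
    """Maximise Q_B by label propagation plus greedy agglomeration.

    Each trial starts from unique labels on the column nodes, propagates to
    a fixed point, then repeatedly merges the module pair with the largest
    strictly positive Q_B gain and re-propagates until no merge improves.
    The best partition over ``trials`` randomised trials is returned with
    its Q_B; a fixed ``seed`` makes the whole run reproducible.
    """
    if m.F < 1:
        raise ValueError("LPAb+ needs at least one interaction")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s = _score_matrix(m)
    f = m.F
    best_q = -np.inf
    best: tuple[np.ndarray, np.ndarray] | None = None
    for child in ss.spawn(trials):
        rng = np.random.default_rng(child)
        h = np.arange(m.c)
        # initial row sweep from unique column labels; rows have no prior label
        g = _argmax_ties(s @ _onehot(h, m.c), None, rng)
        g, h = _sweep(s, g, h, rng)
        q = _qb_from_labels(s, g, h, f)
        while True:
            gain, la, lb = _best_merge(m, g, h)
            if gain <= 1e-12:
                break
            g = np.where(g == lb, la, g)
            h = np.where(h == lb, la, h)
            g, h = _sweep(s, g, h, rng)
            q = _qb_from_labels(s, g, h, f)
        if q > best_q:
            best_q, best = q, (g.copy(), h.copy())
    if best_q < 0.0:
        # the single-module partition always attains Q_B = 0
        part = Partition((0,) * m.r, (0,) * m.c)
        return part, MeasureResult("QB", score=0.0, lower_is_more_structured=False)
    g, h = best
    part = Partition(tuple(g), tuple(h)).relabeled()
    return part, MeasureResult("QB", score=best_q, lower_is_more_structured=False)
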