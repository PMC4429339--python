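"""Synthetic infection matrices with planted structure.

Generators for testing every analysis stage without a laboratory typing
table: unstructured Bernoulli matrices, perfectly nested staircases,
planted modular (stochastic block) matrices, and a typing-scheme analogue
of the O157 layout — 66 phage types x 16 typing phages with four planted
phage groups of sizes 6, 4, 4 and 2 — that is simultaneously modular and
nested in expectation.

Every generator is driven by a single seed and returns a valid
:class:`~phagenet.matrix.InfectionMatrix`; planted truth (module labels)
is returned alongside where it exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import InfectionMatrix
from .modularity import Partition

__all__ = [
    "GeneratorSpec",
    "gen_random",
    "gen_nested",
    "gen_modular",
    "gen_typing_like",
    "TYPING_COLUMN_GROUPS",
]

#: Planted typing-phage group sizes of the O157 scheme analogue: three
#: T4-like groups of 6, 4 and 4 phages plus the T7-like pair.
TYPING_COLUMN_GROUPS: tuple[int, ...] = (6, 4, 4, 2)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters shared by the matrix generators.

    fill
        Target connectance F/M.
    q, p_in, p_out
        Planted module count and within/between-module connection
        probabilities (gen_modular).
    module_sizes
        Explicit column-group sizes (must sum to c); near-equal split when
        omitted.
    """

    r: int = 66
    c: int = 16
    fill: float = 0.5
    q: int = 4
    p_in: float = 0.9
    p_out: float = 0.05
    module_sizes: tuple[int, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not 0 <= self.fill <= 1:
            raise ValueError("fill must be in [0, 1]")
        if self.module_sizes is not None:
            sizes = tuple(int(s) for s in self.module_sizes)
            if sum(sizes) != self.c:
                raise ValueError("module_sizes must sum to c")
            object.__setattr__(self, "module_sizes", sizes)


def _labels(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(n))


def _split(n: int, q: int, sizes: tuple[int, ...] | None) -> np.ndarray:
    """Group label per item: explicit sizes, else near-equal blocks."""
    if sizes is None:
        base = [n // q + (1 if i < n % q else 0) for i in range(q)]
    else:
        base = list(sizes)
    return np.repeat(np.arange(len(base)), base)


def _proportional_split(n: int, weights: tuple[int, ...]) -> np.ndarray:
    """Split n items into groups proportional to weights (largest
    remainder), contiguous blocks."""
    total = sum(weights)
    exact = [n * w / total for w in weights]
    counts = [int(np.floor(e)) for e in exact]
    rema = sorted(range(len(weights)), key=lambda i: exact[i] - counts[i],
                  reverse=True)
    for i in rema[: n - sum(counts)]:
        counts[i] += 1
    return np.repeat(np.arange(len(weights)), counts)


def gen_random(spec: GeneratorSpec) -> InfectionMatrix:
    """Independent Bernoulli(fill) matrix — the model-1 null process."""
    rng = np.random.default_rng(spec.seed)
    a = (rng.random((spec.r, spec.c)) < spec.fill).astype(np.int8)
    return InfectionMatrix(a, _labels("PT", spec.r), _labels("TP", spec.c))


def gen_nested(spec: GeneratorSpec) -> InfectionMatrix:
    """Perfectly nested staircase at (approximately) the target fill.

    Row i carries its ones left-justified in the first k_i columns with
    k_i = round(c * (1 - i/r) * s), the scale s chosen so the realised
    fill is as close as possible to the target; degrees are nonincreasing
    down the rows, so the matrix equals its own packed form (BR = 0,
    temperature 0).  Row-degree ties are unavoidable when r exceeds the
    number of distinct degrees (r > c), in which case equal-fill pairs
    keep raw NODF below 100.
    """
    r, c = spec.r, spec.c

    def degrees(s: float) -> np.ndarray:
        k = np.round(c * (1 - np.arange(r) / r) * s)
        return np.clip(k, 0, c).astype(int)

    # ramp mean is ~c/2 at s=1; search s for the closest realised fill
    scales = np.linspace(0.05, 2.0, 1953)
    fills = np.array([degrees(s).sum() / (r * c) for s in scales])
    s_best = scales[np.argmin(np.abs(fills - spec.fill))]
    k = degrees(s_best)
    cols = np.arange(c)
    a = (cols[None, :] < k[:, None]).astype(np.int8)
    return InfectionMatrix(a, _labels("PT", r), _labels("TP", c))


def gen_modular(spec: GeneratorSpec) -> tuple[InfectionMatrix, Partition]:
    """Planted-partition (stochastic block) matrix.

    Rows and columns are split into q groups (column sizes from
    ``module_sizes`` when given); within-block cells are Bernoulli(p_in),
    between-block cells Bernoulli(p_out).  Returns the matrix and the
    planted partition.
    """
    if spec.q < 2:
        raise ValueError("gen_modular needs q >= 2")
    rng = np.random.default_rng(spec.seed)
    col_groups = _split(spec.c, spec.q, spec.module_sizes)
    row_groups = (_proportional_split(spec.r, spec.module_sizes)
                  if spec.module_sizes is not None
                  else _split(spec.r, spec.q, None))
    same = row_groups[:, None] == col_groups[None, :]
    p = np.where(same, spec.p_in, spec.p_out)
    a = (rng.random((spec.r, spec.c)) < p).astype(np.int8)
    m = InfectionMatrix(a, _labels("PT", spec.r), _labels("TP", spec.c))
    return m, Partition(tuple(row_groups), tuple(col_groups))


def gen_typing_like(seed: int | None = None, fill: float = 0.5,
                    noise: float = 0.02) -> tuple[InfectionMatrix, Partition]:
    """Typing-scheme analogue: 66 x 16, modular *and* nested.

    Columns form four planted groups of sizes 6, 4, 4 and 2; rows are
    assigned to groups proportionally.  Each row draws a target degree
    from a geometric-like gradient (a few near-universal phage types down
    to narrow specialists) scaled to the target fill, then places its
    presences module-first and spills over into the other groups in a
    fixed rotation — specialists stay inside their module (modularity)
    while generalists span all modules in a degree gradient (nestedness).
    A small Bernoulli(noise) flip is applied per cell.

    Returns the matrix and the planted module partition.
    """
    rng = np.random.default_rng(seed)
    r, c = 66, 16
    sizes = TYPING_COLUMN_GROUPS
    q = len(sizes)
    col_groups = np.repeat(np.arange(q), sizes)
    row_groups = _proportional_split(r, sizes)
    # geometric-like degree gradient scaled so mean degree ~ fill * c
    rank = np.arange(r) / (r - 1)
    gamma = np.log(0.12) / np.log(0.5)  # shape: steep tail of specialists
    base = 0.12 + (1.0 - 0.12) * (1 - rank) ** gamma
    base *= fill * c / (base.mean())
    k = np.clip(np.round(base + rng.normal(0, 0.75, size=r)), 1, c).astype(int)
    # per-group column orderings: own module first, then rotation
    col_idx_by_group = [np.flatnonzero(col_groups == g) for g in range(q)]
    a = np.zeros((r, c), dtype=np.int8)
    for i in range(r):
        g = row_groups[i]
        order = np.concatenate([col_idx_by_group[(g + off) % q]
                                for off in range(q)])
        a[i, order[: k[i]]] = 1
    if noise > 0:
        flips = rng.random((r, c)) < noise
        a = np.where(flips, 1 - a, a).astype(np.int8)
    m = InfectionMatrix(a, _labels("PT", r), _labels("TP", c))
    return m, Partition(tuple(row_groups), tuple(col_groups))
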