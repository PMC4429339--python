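"""Bernoulli null models and ensemble significance tests.

Two probabilistic null models judge whether the structure of an observed
infection matrix exceeds chance:

model 1 (uniform fill)
    every cell is an independent Bernoulli draw with p_ij = F/M, the
    observed connectance;
model 2 (degree-informed)
    p_ij = 0.5 * (d_j / r + k_i / c), so cells in heavy rows and heavy
    columns are more likely, preserving degree gradients in expectation.

Significance is one-sided in the *structured* direction of each measure:
larger for Q_B, smaller for the rescaled nestedness scores.  p-values use
the add-one rule p = (b + 1) / (N + 1) (never exactly 0); z-scores are
(observed - null mean) / null sd, so a structured matrix gives z > 0 for
modularity and z < 0 for nestedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .matrix import InfectionMatrix
from .nestedness import MeasureResult

__all__ = [
    "NullModelSpec",
    "NullEnsembleResult",
    "null_probabilities",
    "sample_null",
    "significance_test",
]

#: measures whose structured direction is "larger" (all others: "smaller")
_HIGHER_IS_STRUCTURED = {"QB"}


@dataclass(frozen=True)
class NullModelSpec:
    """Per-cell Bernoulli probabilities for one null model."""

    model_id: int
    p: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("null probabilities must lie in [0, 1]")
        p.setflags(write=False)
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class NullEnsembleResult:
    """Outcome of an ensemble significance test.

    ``p_is_bound`` is set when no null score was as extreme as the observed
    one (b = 0), i.e. when a study would report the p-value as "< 1/N".
    """

    measure_name: str
    observed: float
    model_id: int
    N: int
    null_scores: np.ndarray
    p_value: float
    p_is_bound: bool
    z_score: float
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_scores))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_scores, ddof=1))


def null_probabilities(m: InfectionMatrix, model_id: int) -> NullModelSpec:
    """Build the p_ij grid for null model 1 or 2 of the observed matrix."""
    if model_id == 1:
        p = np.full((m.r, m.c), m.F / m.M if m.M else 0.0)
    elif model_id == 2:
        k = m.row_degrees.astype(float)
        d = m.col_degrees.astype(float)
        p = 0.5 * (d[None, :] / m.r + k[:, None] / m.c)
    else:
        raise ValueError(f"unknown null model {model_id!r} (use 1 or 2)")
    return NullModelSpec(model_id, p, m.row_labels, m.col_labels)


def sample_null(spec: NullModelSpec,
                seed: int | np.random.Generator | None = None) -> InfectionMatrix:
    """Draw one matrix: independent Bernoulli(p_ij) per cell."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = (rng.random(spec.p.shape) < spec.p).astype(np.int8)
    return InfectionMatrix(a, spec.row_labels, spec.col_labels)


def significance_test(
    m: InfectionMatrix,
    measure: Callable[[InfectionMatrix], MeasureResult],
    model_id: int,
    N: int = 1000,
    seed: int | None = None,
    adaptive: bool = False,
    N_min: int = 100,
    N_step: int = 100,
    N_max: int = 5000,
    b_target: int = 5,
    resample_degenerate: bool = False,
) -> NullEnsembleResult:
    """Ensemble significance of ``measure(m)`` under one null model.

    Draws ``N`` null matrices (per-replicate RNG streams spawned from the
    master seed, so the run is reproducible bit-for-bit), evaluates the
    measure on each, and reports p and z in the measure's structured
    direction.  In ``adaptive`` mode the ensemble grows from ``N_min`` in
    steps of ``N_step`` until at least ``b_target`` null scores are as
    extreme as the observed one, or ``N_max`` is reached; this caps the
    work spent on clearly significant results while still resolving
    borderline ones.
    """
    if not adaptive and N < 2:
        raise ValueError("ensemble size must be >= 2")
    observed = measure(m)
    x = observed.score
    higher = observed.measure_name in _HIGHER_IS_STRUCTURED or \
        not observed.lower_is_more_structured
    spec = null_probabilities(m, model_id)
    ss = np.random.SeedSequence(seed)

    def extreme_count(scores: np.ndarray) -> int:
        return int((scores >= x).sum() if higher else (scores <= x).sum())

    scores: list[float] = []
    stream = _replicate_streams(ss)
    target = N_min if adaptive else N
    while True:
        while len(scores) < target:
            rng = next(stream)
            null_m = sample_null(spec, rng)
            if resample_degenerate:
                # optionally reject draws with empty rows/columns (bounded)
                for _ in range(1000):
                    if not ((null_m.row_degrees == 0).any()
                            or (null_m.col_degrees == 0).any()):
                        break
                    null_m = sample_null(spec, rng)
            scores.append(measure(null_m).score)
        arr = np.asarray(scores)
        b = extreme_count(arr)
        if not adaptive or b >= b_target or target >= N_max:
            break
        target = min(target + N_step, N_max)

    n = arr.size
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise ZeroDivisionError(
            f"null ensemble of {observed.measure_name} has zero variance "
            f"(all {n} null scores = {arr[0]:g}); z-score undefined"
        )
    z = (x - float(arr.mean())) / sd
    p = (b + 1) / (n + 1)
    return NullEnsembleResult(
        measure_name=observed.measure_name, observed=x, model_id=model_id,
        N=n, null_scores=arr, p_value=p, p_is_bound=(b == 0), z_score=z,
        seed=seed,
    )


def _replicate_streams(ss: np.random.SeedSequence):
    """Unbounded per-replicate generators from one master SeedSequence.

    Replicate i always gets the same stream regardless of how many
    replicates are drawn in total (counter scheme), so adaptive growth
    extends an ensemble instead of re-drawing it.
    """
    i = 0
    while True:
        yield np.random.default_rng(np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(i,)))
        i += 1
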