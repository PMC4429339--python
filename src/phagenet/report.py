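"""Full analysis pipeline: measures, null significance, clustering.

:func:`run_full_analysis` composes the stages into the canonical workflow
for a binary infection matrix — bipartite modularity via LPAb+, the three
nestedness scores, ensemble significance under both null models, and the
two-way Euclidean/Ward cluster analysis — and returns a machine-readable
report whose recorded seeds make the whole run reproducible.
"""

from __future__ import annotations

import datetime
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__ as _pkg_version
from .clustering import DendrogramResult, select_groups, to_newick, two_way_order, ward_dendrogram
from .matrix import InfectionMatrix
from .modularity import Partition, lpab_plus, module_count
from .nestedness import MeasureResult, br, nodf, ntc
from .nulls import NullEnsembleResult, significance_test

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis",
           "qb_measure", "measure_by_name"]

logger = logging.getLogger("phagenet")

REPORT_SCHEMA_VERSION = 1

#: report keys every run must produce (schema checked in tests)
REPORT_REQUIRED_KEYS = (
    "schema_version", "tool_version", "master_seed", "input",
    "measures", "null_tests", "clustering", "timestamps",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for :func:`run_full_analysis`.

    trials
        LPAb+ trials on the observed matrix (best Q_B kept).
    null_trials
        LPAb+ trials per null replicate (smaller; ensembles are large).
    ensemble_size
        Null replicates per model when not adaptive.
    adaptive
        Grow nestedness ensembles until enough extreme null scores are
        seen (modularity ensembles stay at ``ensemble_size``).
    models
        Which null models to run (subset of {1, 2}).
    seed
        Master seed; every stage seed is derived from it.
    """

    trials: int = 1000
    null_trials: int = 20
    ensemble_size: int = 1000
    adaptive: bool = True
    models: tuple[int, ...] = (1, 2)
    seed: int | None = None
    n_perm: int = 999
    k_max: int = 8
    skip_nulls: bool = False
    skip_clustering: bool = False


def qb_measure(trials: int, seed: int | None = None):
    """Measure function evaluating Q_B via LPAb+ (for null ensembles).

    Returns 0 with a degeneracy flag on an edgeless matrix, so retained
    degenerate null draws stay scoreable.
    """
    def _measure(m: InfectionMatrix) -> MeasureResult:
        if m.F == 0:
            return MeasureResult("QB", score=0.0,
                                 lower_is_more_structured=False,
                                 degenerate=True)
        _, res = lpab_plus(m, trials=trials, seed=seed)
        return res
    return _measure


def measure_by_name(name: str, trials: int = 20, seed: int | None = None):
    """Resolve a measure name in {QB, NODF, NTC, BR} to a callable."""
    name = name.upper()
    if name == "QB":
        return qb_measure(trials, seed)
    if name == "NODF":
        return nodf
    if name == "NTC":
        return ntc
    if name == "BR":
        return br
    raise ValueError(f"unknown measure {name!r}")


@dataclass
class AnalysisReport:
    """Structured result of a full run; serialises to JSON."""

    data: dict[str, Any]

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.data, indent=indent, default=_jsonify)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def table(self) -> str:
        """Human-readable measure x model summary (score, N, p, z)."""
        lines = ["measure    score       model  N      p-value     z-score"]
        meas = self.data["measures"]
        for name in ("QB", "NODF", "NTC", "BR"):
            if name not in meas:
                continue
            score = meas[name]["score"]
            tests = [t for t in self.data["null_tests"]
                     if t["measure"] == name]
            if not tests:
                lines.append(f"{name:<10} {score:<11.4f} -      -      -           -")
            for t in tests:
                p_str = (f"<1/{t['N']}" if t["p_is_bound"]
                         else f"{t['p_value']:.4g}")
                lines.append(
                    f"{name:<10} {score:<11.4f} {t['model']:<6} "
                    f"{t['N']:<6} {p_str:<11} {t['z_score']:.4f}"
                )
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _derive_seeds(seed: int | None, n: int) -> list[int]:
    """Stage seeds derived from the master seed (documented scheme:
    SeedSequence(master).generate_state)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n)]


def run_full_analysis(m: InfectionMatrix,
                      config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run measures, null-model significance and clustering on a matrix.

    Stage errors are caught and recorded under ``errors`` with the stage
    name; completed stages are always kept in the report.
    """
    cfg = config or AnalysisConfig()
    t0 = time.time()
    seeds = _derive_seeds(cfg.seed, 2 + 2 * len(cfg.models) * 4)
    seed_iter = iter(seeds)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": _pkg_version,
        "master_seed": cfg.seed,
        "input": {"rows": m.r, "cols": m.c, "F": m.F, "M": m.M,
                  "fill": m.fill},
        "measures": {},
        "null_tests": [],
        "clustering": None,
        "errors": {},
        "timestamps": {"started": _now()},
    }

    # -- observed measures ---------------------------------------------------
    lpab_seed = next(seed_iter)
    partition: Partition | None = None
    try:
        partition, qb_res = lpab_plus(m, trials=cfg.trials, seed=lpab_seed)
        report["measures"]["QB"] = {
            "score": qb_res.score, "trials": cfg.trials, "seed": lpab_seed,
            "modules": module_count(partition),
            "row_modules": list(partition.row_labels),
            "col_modules": list(partition.col_labels),
        }
        logger.info("Q_B = %.4f (%d modules, %d trials)",
                    qb_res.score, module_count(partition), cfg.trials)
    except Exception as exc:  # partial results flagged, never dropped
        report["errors"]["modularity"] = str(exc)
        logger.warning("modularity stage failed: %s", exc)
    for name, fn in (("NODF", nodf), ("NTC", ntc), ("BR", br)):
        try:
            res = fn(m)
            entry = {"score": res.score, "degenerate": res.degenerate}
            if res.raw_score is not None:
                entry["raw_score"] = res.raw_score
            report["measures"][name] = entry
            logger.info("%s = %.4f", name, res.score)
        except Exception as exc:
            report["errors"][f"nestedness:{name}"] = str(exc)
            logger.warning("%s stage failed: %s", name, exc)

    # -- null-model significance --------------------------------------------
    if not cfg.skip_nulls:
        for model in cfg.models:
            for name in ("QB", "NODF", "NTC", "BR"):
                if name not in report["measures"]:
                    continue
                mseed = next(seed_iter)
                adaptive = cfg.adaptive and name != "QB"
                measure = measure_by_name(name, trials=cfg.null_trials,
                                          seed=mseed)
                try:
                    t = time.time()
                    res = significance_test(
                        m, measure, model_id=model,
                        N=cfg.ensemble_size, seed=mseed, adaptive=adaptive,
                        N_max=max(cfg.ensemble_size, 5000) if adaptive
                        else cfg.ensemble_size,
                    )
                    report["null_tests"].append({
                        "measure": name, "model": model, "N": res.N,
                        "observed": res.observed,
                        "null_mean": res.null_mean, "null_sd": res.null_sd,
                        "p_value": res.p_value, "p_is_bound": res.p_is_bound,
                        "z_score": res.z_score, "seed": mseed,
                        "adaptive": adaptive,
                    })
                    logger.info(
                        "null model %d / %s: N=%d p=%.4g z=%.3f (%.1fs)",
                        model, name, res.N, res.p_value, res.z_score,
                        time.time() - t)
                except Exception as exc:
                    report["errors"][f"null:{name}:model{model}"] = str(exc)
                    logger.warning("null test %s/model %d failed: %s",
                                   name, model, exc)

    # -- two-way clustering ---------------------------------------------------
    if not cfg.skip_clustering:
        try:
            cl_seed = next(seed_iter)
            ordered, rows_d, cols_d = two_way_order(m)
            from scipy.spatial.distance import pdist, squareform
            entry: dict[str, Any] = {}
            for axis, dres in (("rows", rows_d), ("columns", cols_d)):
                x = (np.asarray(m.entries, dtype=float)
                     if axis == "rows" else np.asarray(m.entries, dtype=float).T)
                dist = squareform(pdist(x))
                sel = select_groups(dres, dist, k_max=min(cfg.k_max, x.shape[0] - 1),
                                    n_perm=cfg.n_perm, seed=cl_seed)
                entry[axis] = {
                    "leaf_order": list(dres.leaf_order),
                    "leaves": [dres.labels[i] for i in dres.leaf_order],
                    "info_remaining": list(dres.info_remaining),
                    "newick": to_newick(dres),
                    "mrpp_table": [list(row) for row in sel.table],
                    "selected_k": sel.selected_k,
                    "truncated": sel.truncated,
                }
            entry["seed"] = cl_seed
            report["clustering"] = entry
            logger.info("two-way clustering done (selected k: rows=%s cols=%s)",
                        entry["rows"]["selected_k"],
                        entry["columns"]["selected_k"])
        except Exception as exc:
            report["errors"]["clustering"] = str(exc)
            logger.warning("clustering stage failed: %s", exc)

    report["timestamps"]["finished"] = _now()
    report["timestamps"]["wall_seconds"] = time.time() - t0
    return AnalysisReport(report)


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()
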