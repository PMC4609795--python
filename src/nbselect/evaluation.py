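"""Replication harness: type-I error, power, sensitivity and specificity.

Each scenario is simulated ``n_reps`` times; every selector is applied to
every replication and the 2x2 confusion counts against the known truth mask
are averaged over replications before the ratios are formed (with fixed
class sizes this equals the mean of per-replication rates).  Statistical
selectors are scored both at the nominal level and at the Bonferroni level
``alpha / n_features``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import selectors
from .simdata import ScenarioConfig, simulate_dataset

__all__ = [
    "EvalMetrics",
    "confusion",
    "type1_power",
    "run_replications",
    "benchmark_tables",
    "PVALUE_METHODS",
]

#: selectors that yield p-values, hence nominal + Bonferroni levels
PVALUE_METHODS = ("bayseq", "deseq", "edger", "ranksum")


@dataclass
class EvalMetrics:
    """Averaged confusion counts and rates for one method at one level."""

    method_tag: str
    scenario_id: str
    level: str  # "nominal" or "bonferroni"
    tp: float
    fp: float
    tn: float
    fn: float
    sensitivity: float
    specificity: float
    type1: float
    power: float
    n_reps_used: int

    @classmethod
    def from_mean_counts(cls, method_tag, scenario_id, level, tp, fp, tn, fn, n_reps):
        sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
        spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
        type1 = fp / (fp + tn) if fp + tn > 0 else float("nan")
        power = sens
        return cls(method_tag, scenario_id, level, tp, fp, tn, fn,
                   sens, spec, type1, power, n_reps)


def confusion(selected: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """Standard 2x2 counts (tp, fp, tn, fn) of a selection against truth."""
    selected = np.asarray(selected, bool)
    truth = np.asarray(truth, bool)
    if selected.shape != truth.shape:
        raise ValueError("selected and truth masks must have equal length")
    tp = int(np.sum(selected & truth))
    fp = int(np.sum(selected & ~truth))
    tn = int(np.sum(~selected & ~truth))
    fn = int(np.sum(~selected & truth))
    return tp, fp, tn, fn


def type1_power(
    p_values: np.ndarray,
    truth: np.ndarray,
    alpha: float = 0.05,
    n_tests_for_bonferroni: int | None = None,
) -> tuple[float, float, float, float]:
    """Rejection rates among null and significant features at the nominal
    and Bonferroni-corrected levels.

    Returns (type1_nominal, power_nominal, type1_bonf, power_bonf); an empty
    truth class yields NaN for its rates.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    truth = np.asarray(truth, bool)
    if n_tests_for_bonferroni is None:
        n_tests_for_bonferroni = len(p)
    out = []
    for thr in (alpha, alpha / n_tests_for_bonferroni):
        rej = p < thr
        type1 = float(rej[~truth].mean()) if np.any(~truth) else float("nan")
        power = float(rej[truth].mean()) if np.any(truth) else float("nan")
        out.extend([type1, power])
    return out[0], out[1], out[2], out[3]


def _one_replication(config: ScenarioConfig, rep: int, methods, alpha, method_params):
    """Confusion counts for every (method, level) on one replication."""
    data = simulate_dataset(config, rep)
    # selector stream kept separate from the simulation stream
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, rep, 0xF5)).generate_state(2))
    out = {}
    for method in methods:
        params = dict(method_params.get(method, {}))
        try:
            res = selectors.select_features(method, data, alpha=alpha, rng=rng, **params)
            out[(method, "nominal")] = confusion(res.selected, data.truth)
            if method in PVALUE_METHODS:
                bonf = res.p_values < alpha / data.n_features
                out[(method, "bonferroni")] = confusion(bonf, data.truth)
        except Exception as exc:  # logged and excluded from the average
            warnings.warn(f"{method} failed on replication {rep}: {exc}", stacklevel=2)
            out[(method, "nominal")] = None
            if method in PVALUE_METHODS:
                out[(method, "bonferroni")] = None
    return out


def run_replications(
    config: ScenarioConfig,
    methods: list[str],
    n_reps: int | None = None,
    seed: int | None = None,
    workers: int = 1,
    alpha: float = 0.05,
    method_params: dict | None = None,
) -> pd.DataFrame:
    """Simulate, select and average over replications.

    Returns one row per (method, level) with mean confusion counts and the
    derived rates.  Deterministic for a fixed seed regardless of ``workers``
    (per-replication streams are derived from (seed, rep)).
    """
    if not methods:
        raise ValueError("methods must be nonempty")
    if n_reps is None:
        n_reps = config.n_reps
    if seed is not None:
        from dataclasses import replace
        config = replace(config, seed=seed)
    n_reps = min(n_reps, config.n_reps)
    method_params = method_params or {}

    if workers > 1:
        per_rep = Parallel(n_jobs=workers)(
            delayed(_one_replication)(config, rep, methods, alpha, method_params)
            for rep in range(n_reps))
    else:
        per_rep = [_one_replication(config, rep, methods, alpha, method_params)
                   for rep in range(n_reps)]

    rows = []
    keys = per_rep[0].keys()
    for key in keys:
        counts = [r[key] for r in per_rep if r[key] is not None]
        n_used = len(counts)
        if n_used == 0:
            continue
        tp, fp, tn, fn = np.mean(counts, axis=0)
        method, level = key
        rows.append(asdict(EvalMetrics.from_mean_counts(
            method, config.scenario_id, level, tp, fp, tn, fn, n_used)))
    return pd.DataFrame(rows)


def benchmark_tables(
    grid: list[ScenarioConfig],
    methods: list[str],
    n_reps: int = 1000,
    seed: int | None = None,
    workers: int = 1,
    alpha: float = 0.05,
    method_params: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Benchmark every method over every scenario of the grid.

    Returns ``{"long": tidy per-(scenario, method, level) table,
    "wide": sensitivity/specificity cells shaped like the published
    comparison table, "rates": type-I error and power series for the
    p-value-based methods}``.
    """
    frames = []
    for config in grid:
        frames.append(run_replications(config, methods, n_reps=n_reps, seed=seed,
                                       workers=workers, alpha=alpha,
                                       method_params=method_params))
    long = pd.concat(frames, ignore_index=True)

    wide = long.assign(
        cell=lambda d: d.apply(
            lambda r: f"{r.sensitivity:.2f}/{r.specificity:.2f}", axis=1),
        column=lambda d: d.method_tag + np.where(d.level == "bonferroni", " (Bonf)", ""),
    ).pivot(index="scenario_id", columns="column", values="cell")

    rates = long[long.method_tag.isin(PVALUE_METHODS)][
        ["scenario_id", "method_tag", "level", "type1", "power"]
    ].reset_index(drop=True)
    return {"long": long, "wide": wide, "rates": rates}
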