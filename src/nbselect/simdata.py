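"""Negative-binomial case/control count simulator.

Generates the scenario grid used throughout the benchmark: two balanced
groups, a leading block of truly differential ("significant") features whose
case-group mean and/or dispersion deviate from the control, and a bulk of
noise features identically distributed in both groups.  Counts are NB with
the mean/dispersion parameterisation ``Var = mu + phi * mu**2`` (``phi = 0``
degenerates to Poisson), the convention of the count-based differential
expression methods this package re-implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ScenarioConfig",
    "LabeledCountMatrix",
    "nb_sample",
    "simulate_dataset",
    "scenario_grid",
    "baseline_config",
    "write_scenario_grid",
    "read_scenario_grid",
]

#: Table of grid settings: s2n axis (A), case-mean axis (B), case-dispersion
#: axis (C).  The middle setting of each axis is the shared baseline.
_S2N_GRID = (0.01, 0.05, 0.1, 0.15, 0.20)
_MU_CASE_GRID = (10.0, 15.0, 20.0, 25.0, 30.0)
_PHI_CASE_GRID = (0.125, 0.5, 1.0, 2.0, 8.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    ``s2n`` is the ratio of significant to insignificant features.  With the
    default ``s2n_convention="ratio"`` the number of significant features is
    ``round(n_features * s2n / (1 + s2n))``; the alternative ``"fraction"``
    reads s2n as a fraction of all features, ``round(n_features * s2n)``.
    """

    scenario_id: str = "baseline"
    n_case: int = 20
    n_control: int = 20
    n_features: int = 500
    s2n: float = 0.1
    mu_sig_case: float = 20.0
    mu_sig_control: float = 5.0
    mu_noise: float = 5.0
    phi_sig_case: float = 1.0
    phi_sig_control: float = 1.0
    phi_noise: float = 1.0
    n_reps: int = 1000
    seed: int = 0
    s2n_convention: str = "ratio"

    def __post_init__(self) -> None:
        if min(self.mu_sig_case, self.mu_sig_control, self.mu_noise) <= 0:
            raise ValueError("all NB means must be positive")
        if min(self.phi_sig_case, self.phi_sig_control, self.phi_noise) < 0:
            raise ValueError("dispersions must be non-negative")
        if self.s2n <= 0:
            raise ValueError("s2n must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.s2n_convention not in ("ratio", "fraction"):
            raise ValueError(f"unknown s2n convention {self.s2n_convention!r}")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    @property
    def n_sig(self) -> int:
        if self.s2n_convention == "ratio":
            return int(round(self.n_features * self.s2n / (1.0 + self.s2n)))
        return int(round(self.n_features * self.s2n))


@dataclass
class LabeledCountMatrix:
    """Integer count matrix (features x samples) with binary group labels.

    ``labels`` is 1 for case, 0 for control.  ``truth`` marks the truly
    differential features and is ``None`` for real data.
    """

    counts: np.ndarray
    labels: np.ndarray
    truth: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.labels = np.asarray(self.labels).astype(int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (features x samples)")
        if self.counts.shape[1] != self.labels.shape[0]:
            raise ValueError("labels length must equal the number of samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=bool)
            if self.truth.shape[0] != self.counts.shape[0]:
                raise ValueError("truth mask length must equal n_features")
        if not self.feature_ids:
            self.feature_ids = [f"f{i:04d}" for i in range(self.counts.shape[0])]
        if not self.sample_ids:
            self.sample_ids = [f"s{j:02d}" for j in range(self.counts.shape[1])]

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def nb_sample(
    mean: float,
    dispersion: float,
    n: int,
    rng: np.random.Generator,
    size: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Draw i.i.d. NB counts with E[X]=mean, Var[X]=mean+dispersion*mean**2.

    ``dispersion = 0`` falls back to Poisson.  ``size`` overrides ``n`` with
    an arbitrary output shape.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    shape = size if size is not None else (int(n),)
    if dispersion == 0:
        return rng.poisson(mean, shape)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, shape)


def _rep_rng(config: ScenarioConfig, rep_index: int) -> np.random.Generator:
    # independent, reproducible stream per (scenario seed, replication)
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(rep_index + 1)[-1])


def simulate_dataset(config: ScenarioConfig, rep_index: int = 0) -> LabeledCountMatrix:
    """Simulate one replication of a scenario.

    The first ``config.n_sig`` features form the differential block: case
    samples draw from NB(mu_sig_case, phi_sig_case), controls from
    NB(mu_sig_control, phi_sig_control).  All remaining features draw from
    NB(mu_noise, phi_noise) in both groups.  Deterministic in
    ``(config.seed, rep_index)``.
    """
    if rep_index < 0 or rep_index >= config.n_reps:
        raise ValueError(f"rep_index {rep_index} outside [0, {config.n_reps})")
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, rep_index)).generate_state(4)
    )
    n_sig = config.n_sig
    n_noise = config.n_features - n_sig
    counts = np.empty((config.n_features, config.n_samples), dtype=np.int64)
    if n_sig:
        counts[:n_sig, : config.n_case] = nb_sample(
            config.mu_sig_case, config.phi_sig_case, 0, rng, size=(n_sig, config.n_case)
        )
        counts[:n_sig, config.n_case :] = nb_sample(
            config.mu_sig_control, config.phi_sig_control, 0, rng,
            size=(n_sig, config.n_control),
        )
    if n_noise:
        counts[n_sig:] = nb_sample(
            config.mu_noise, config.phi_noise, 0, rng,
            size=(n_noise, config.n_samples),
        )
    labels = np.r_[np.ones(config.n_case, int), np.zeros(config.n_control, int)]
    truth = np.zeros(config.n_features, bool)
    truth[:n_sig] = True
    sample_ids = [f"case{j:02d}" for j in range(config.n_case)] + [
        f"ctrl{j:02d}" for j in range(config.n_control)
    ]
    return LabeledCountMatrix(counts, labels, truth, sample_ids=sample_ids)


def baseline_config(**overrides) -> ScenarioConfig:
    """The shared baseline: n=20/20, 500 features, case NB(20,1) vs control
    NB(5,1), noise NB(5,1), s2n=0.1."""
    return replace(ScenarioConfig(), **overrides)


def scenario_grid(seed: int = 0, n_reps: int = 1000) -> list[ScenarioConfig]:
    """The full 15-scenario grid: A1-A5 vary s2n, B1-B5 the case mean of
    significant features, C1-C5 their case dispersion; everything else stays
    at baseline.  A3, B3 and C3 coincide with the baseline."""
    grid: list[ScenarioConfig] = []
    for i, s2n in enumerate(_S2N_GRID, 1):
        grid.append(baseline_config(scenario_id=f"A{i}", s2n=s2n, seed=seed, n_reps=n_reps))
    for i, mu in enumerate(_MU_CASE_GRID, 1):
        grid.append(baseline_config(scenario_id=f"B{i}", mu_sig_case=mu, seed=seed, n_reps=n_reps))
    for i, phi in enumerate(_PHI_CASE_GRID, 1):
        grid.append(baseline_config(scenario_id=f"C{i}", phi_sig_case=phi, seed=seed, n_reps=n_reps))
    return grid


def scenario_by_id(scenario_id: str, seed: int = 0, n_reps: int = 1000) -> ScenarioConfig:
    if scenario_id == "baseline":
        return baseline_config(seed=seed, n_reps=n_reps)
    for cfg in scenario_grid(seed=seed, n_reps=n_reps):
        if cfg.scenario_id == scenario_id:
            return cfg
    raise KeyError(f"unknown scenario {scenario_id!r}")


# -- plain-text (key=value) scenario-grid serialisation ----------------------

def write_scenario_grid(configs: Iterable[ScenarioConfig], path: str | Path) -> None:
    """One blank-line-separated key=value record per scenario."""
    records = []
    for cfg in configs:
        records.append("\n".join(f"{k}={v}" for k, v in asdict(cfg).items()))
    Path(path).write_text("\n\n".join(records) + "\n")


def read_scenario_grid(path: str | Path) -> list[ScenarioConfig]:
    text = Path(path).read_text().strip()
    configs = []
    field_types = {f.name: f.type for f in ScenarioConfig.__dataclass_fields__.values()}
    casts = {"int": int, "float": float, "str": str}
    for block in text.split("\n\n"):
        kwargs = {}
        for line in block.strip().splitlines():
            key, _, value = line.partition("=")
            key = key.strip()
            typ = field_types.get(key, "str")
            kwargs[key] = casts.get(typ, str)(value.strip())
        configs.append(ScenarioConfig(**kwargs))
    return configs
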