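"""Multi-batch time-series expression with planted regulatory programs.

Each batch is an independent realization of the same process: TF
trajectories follow a stationary AR(1) in z-score units, and every target
with a planted program takes its value at t+1 from a (linear, product, or
threshold) function of its driver TFs at t, plus Gaussian noise.  A program
may carry several pairwise-disjoint driver sets: drivers in the redundant
sets are jittered copies of the first set's drivers, so each set alone
predicts the target about equally well -- the ground truth the disjoint-set
search is meant to recover.  Targets without a program are plain AR(1)
noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tfsynergy.expression import ExpressionTimeSeries

__all__ = ["RegulatoryProgram", "SyntheticConfig", "generate_timeseries",
           "write_ground_truth", "default_config", "random_program_config",
           "random_gs_edges"]

LINK_KINDS = ("linear", "product", "threshold")


@dataclass(frozen=True)
class RegulatoryProgram:
    """Planted dependence of one target gene on one or more disjoint TF sets.

    ``coefficients`` weight the drivers of the first (primary) set; links:

    - ``linear``:    y = sum_j c_j x_j
    - ``product``:   y = prod_j (c_j x_j)
    - ``threshold``: y = +1 if sum_j c_j x_j > 0 else -1
    """

    target_id: str
    driver_sets: tuple[tuple[str, ...], ...]
    link_kind: str = "linear"
    coefficients: tuple[float, ...] = ()
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.link_kind not in LINK_KINDS:
            raise ValueError(f"unknown link kind {self.link_kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.driver_sets or any(len(s) == 0 for s in self.driver_sets):
            raise ValueError("driver_sets must be non-empty sets of TF ids")
        seen: set[str] = set()
        for s in self.driver_sets:
            if seen & set(s):
                raise ValueError("driver_sets must be pairwise disjoint")
            seen |= set(s)
        if self.target_id in seen:
            raise ValueError(f"target {self.target_id!r} cannot drive itself")
        coeffs = self.coefficients or tuple(1.0 for _ in self.driver_sets[0])
        if len(coeffs) != len(self.driver_sets[0]):
            raise ValueError("need one coefficient per primary driver")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in coeffs))

    def link(self, x: np.ndarray) -> np.ndarray:
        """Apply the link to driver values x of shape (n_drivers, ...)."""
        c = np.asarray(self.coefficients)[:, None]
        if self.link_kind == "linear":
            return (c * x).sum(axis=0)
        if self.link_kind == "product":
            return (c * x).prod(axis=0)
        s = (c * x).sum(axis=0)
        return np.where(s > 0, 1.0, -1.0)

    def to_dict(self) -> dict:
        return {"target_id": self.target_id,
                "driver_sets": [list(s) for s in self.driver_sets],
                "link_kind": self.link_kind,
                "coefficients": list(self.coefficients),
                "noise_sd": self.noise_sd}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of one simulated experiment; the seed fixes everything.

    ``batches`` lists per-batch timepoint counts (each >= 2); the default,
    four series of 38 timepoints, yields ~136 training pairs -- the scale
    of a typical aggregated bulk time-course compendium (roughly 70-200
    training samples per organism);
    ``tf_dynamics`` is the AR(1) autocorrelation of TF trajectories;
    ``redundancy_jitter_sd`` is the sd of the independent noise added when a
    redundant driver copies a primary driver's trajectory;
    ``emit_space`` chooses z-score output (default) or pseudo-TPM
    (``exp(z)``), the latter exercising the z-score entry point.
    """

    n_tfs: int = 20
    n_targets: int = 10
    batches: tuple[int, ...] = (38, 38, 38, 38)
    programs: tuple[RegulatoryProgram, ...] = ()
    tf_dynamics: float = 0.5
    redundancy_jitter_sd: float = 0.05
    emit_space: str = "zscore"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required: the output must be reproducible")
        if not 0 <= self.tf_dynamics < 1:
            raise ValueError("tf_dynamics must lie in [0, 1)")
        if any(b < 2 for b in self.batches) or not self.batches:
            raise ValueError("every batch needs at least 2 timepoints")
        if self.emit_space not in ("zscore", "tpm"):
            raise ValueError(f"unknown emit_space {self.emit_space!r}")

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def target_ids(self) -> list[str]:
        return [f"G{i:03d}" for i in range(1, self.n_targets + 1)]


def _ar1(rng: np.random.Generator, n_series: int, length: int, rho: float) -> np.ndarray:
    """Stationary AR(1) with N(0,1) marginals, shape (n_series, length)."""
    x = np.empty((n_series, length))
    x[:, 0] = rng.standard_normal(n_series)
    innov_sd = math.sqrt(1.0 - rho * rho)
    for t in range(1, length):
        x[:, t] = rho * x[:, t - 1] + innov_sd * rng.standard_normal(n_series)
    return x


def generate_timeseries(config: SyntheticConfig
                        ) -> tuple[ExpressionTimeSeries, list[RegulatoryProgram]]:
    """Simulate the configured experiment; returns the series and its ground truth.

    Within each batch: TF values are AR(1); redundant drivers are then
    overwritten with jittered copies of their primary counterparts (cyclic
    assignment within the program); each programmed target's value at t+1
    is its link applied to the primary drivers at t plus noise, with a free
    N(0,1) initial value; unprogrammed targets are AR(1).
    """
    tf_ids = config.tf_ids
    target_ids = config.target_ids
    universe = set(tf_ids)
    gene_ids = tf_ids + [g for g in target_ids if g not in universe]
    programmed = {}
    for prog in config.programs:
        unknown = {d for s in prog.driver_sets for d in s} - universe
        if unknown:
            raise ValueError(f"program for {prog.target_id!r} references unknown TFs: "
                             f"{sorted(unknown)}")
        if prog.target_id not in gene_ids:
            raise ValueError(f"program references unknown target {prog.target_id!r}")
        if prog.target_id in programmed:
            raise ValueError(f"duplicate program for target {prog.target_id!r}")
        programmed[prog.target_id] = prog

    rng = np.random.default_rng(config.seed)
    tf_pos = {t: i for i, t in enumerate(tf_ids)}

    blocks, meta_rows, col_names = [], [], []
    for b_idx, length in enumerate(config.batches):
        batch_id = f"B{b_idx + 1}"
        tf_vals = _ar1(rng, len(tf_ids), length, config.tf_dynamics)

        # redundant sets copy the primary set's signal, plus independent jitter
        for prog in programmed.values():
            primary = prog.driver_sets[0]
            for extra in prog.driver_sets[1:]:
                for j, tf in enumerate(extra):
                    src = primary[j % len(primary)]
                    tf_vals[tf_pos[tf]] = (
                        tf_vals[tf_pos[src]]
                        + config.redundancy_jitter_sd * rng.standard_normal(length))

        rows = {t: tf_vals[i] for t, i in tf_pos.items()}
        n_plain = sum(1 for g in target_ids if g not in programmed)
        plain_vals = _ar1(rng, n_plain, length, config.tf_dynamics) if n_plain else None
        k = 0
        for g in target_ids:
            if g in programmed:
                prog = programmed[g]
                drivers = np.stack([tf_vals[tf_pos[d]] for d in prog.driver_sets[0]])
                y = np.empty(length)
                y[0] = rng.standard_normal()
                signal = prog.link(drivers[:, :-1])
                y[1:] = signal + prog.noise_sd * rng.standard_normal(length - 1)
                rows[g] = y
            else:
                rows[g] = plain_vals[k]
                k += 1

        for t in range(length):
            col_names.append(f"{batch_id}_t{t}")
            meta_rows.append({"batch": batch_id, "timepoint": t})
        blocks.append(pd.DataFrame({g: rows[g] for g in gene_ids}).T)

    values = pd.concat(blocks, axis=1)
    values.columns = col_names
    values.index = gene_ids
    meta = pd.DataFrame(meta_rows, index=col_names)

    if config.emit_space == "tpm":
        values = np.exp(values)

    series = ExpressionTimeSeries(values=values, sample_meta=meta,
                                  tf_ids=tf_ids, space=config.emit_space)
    return series, list(config.programs)


def write_ground_truth(programs: list[RegulatoryProgram], path: str | Path) -> None:
    Path(path).write_text(json.dumps([p.to_dict() for p in programs], indent=2))


def random_program_config(seed: int, n_tfs: int = 20, n_targets: int = 100,
                          link_kind: str = "product", n_drivers: int = 2,
                          noise_sd: float = 0.3, **overrides) -> SyntheticConfig:
    """An experiment where every target has one randomly-drawn driver set.

    Used for benchmark-style studies: each target depends (through the
    chosen link) on ``n_drivers`` TFs drawn uniformly without replacement.
    """
    rng = np.random.default_rng(seed)
    base = SyntheticConfig(seed=seed, n_tfs=n_tfs, n_targets=n_targets, **overrides)
    tfs = base.tf_ids
    progs = []
    for g in base.target_ids:
        drivers = tuple(rng.choice(tfs, size=n_drivers, replace=False))
        progs.append(RegulatoryProgram(target_id=g, driver_sets=(drivers,),
                                       link_kind=link_kind,
                                       coefficients=tuple(1.0 for _ in drivers),
                                       noise_sd=noise_sd))
    return SyntheticConfig(seed=seed, n_tfs=n_tfs, n_targets=n_targets,
                           programs=tuple(progs), **overrides)


def random_gs_edges(seed: int, tf_ids: list[str], target_ids: list[str],
                    k_min: int = 2, k_max: int = 6) -> pd.DataFrame:
    """A random "gold standard": each target gets k ~ U[k_min, k_max] TF edges.

    Deliberately unrelated to any planted program -- the shape of a curated
    network whose edges carry no predictive signal.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in target_ids:
        k = int(rng.integers(k_min, k_max + 1))
        for tf in rng.choice(tf_ids, size=min(k, len(tf_ids)), replace=False):
            rows.append({"tf": tf, "target": g, "sign": "?"})
    return pd.DataFrame(rows)


def default_config(seed: int, **overrides) -> SyntheticConfig:
    """A small but non-trivial default experiment: 20 TFs, 10 targets, 3 batches.

    Half the targets get a linear two-driver program, the rest a redundant
    pair of driver sets, so both the minimal-set and the disjoint-set
    searches have planted structure to find.
    """
    base = SyntheticConfig(seed=seed, **{k: v for k, v in overrides.items()
                                         if k != "programs"})
    if "programs" in overrides:
        return SyntheticConfig(seed=seed, **overrides)
    tfs = base.tf_ids
    progs = []
    for i, g in enumerate(base.target_ids):
        a, b, c, d = (tfs[(4 * i) % base.n_tfs], tfs[(4 * i + 1) % base.n_tfs],
                      tfs[(4 * i + 2) % base.n_tfs], tfs[(4 * i + 3) % base.n_tfs])
        if i % 2 == 0:
            progs.append(RegulatoryProgram(target_id=g, driver_sets=((a, b),),
                                           coefficients=(1.0, -0.8), noise_sd=0.1))
        else:
            progs.append(RegulatoryProgram(target_id=g, driver_sets=((a, b), (c, d)),
                                           coefficients=(1.0, -0.8), noise_sd=0.1))
    return SyntheticConfig(seed=seed, programs=tuple(progs),
                           **{k: v for k, v in overrides.items() if k != "programs"})
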