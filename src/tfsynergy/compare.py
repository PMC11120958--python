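"""Paired non-parametric model comparison.

Two models evaluated on identical (target gene, test pair) observations
yield aligned per-observation absolute-error vectors; the Wilcoxon
signed-rank test on their differences decides whether one model is
significantly worse, and a percentile bootstrap gives a confidence interval
on the mean error difference.  :func:`compare_methods` assembles the full
pairwise matrix (mean RMSE row, CI per ordered method pair, significance
flags, and the star-set of methods statistically indistinguishable from the
best).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TestResult", "ComparisonTable", "paired_test", "paired_diff_ci",
           "compare_methods"]

#: below this many non-zero differences the exact Wilcoxon null is used
EXACT_N_MAX = 25


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    n_effective: int
    all_zero: bool = False


def _scipy_alternative(alternative: str) -> str:
    mapping = {"two_sided": "two-sided", "two-sided": "two-sided",
               "greater": "greater", "less": "less"}
    if alternative not in mapping:
        raise ValueError(f"unknown alternative {alternative!r}")
    return mapping[alternative]


def paired_test(errors_a, errors_b, alternative: str = "greater") -> TestResult:
    """Wilcoxon signed-rank test on paired error differences a - b.

    ``alternative="greater"`` asks whether model A's errors are larger
    (A worse than B).  Zero differences are dropped (Wilcoxon's original
    treatment); the exact null distribution is used when fewer than
    ``EXACT_N_MAX`` non-zero differences remain, otherwise the normal
    approximation with continuity correction.  All-zero differences return
    p = 1 with ``all_zero`` set.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"misaligned error vectors: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("paired test needs at least 2 pairs")
    alt = _scipy_alternative(alternative)
    d = a - b
    n_eff = int(np.count_nonzero(d))
    if n_eff == 0:
        return TestResult(statistic=0.0, p_value=1.0, alternative=alternative,
                          n_effective=0, all_zero=True)
    method = "exact" if n_eff < EXACT_N_MAX else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative=alt,
                         method=method, correction=(method == "approx"))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      alternative=alternative, n_effective=n_eff)


def paired_diff_ci(errors_a, errors_b, level: float = 0.95,
                   resamples: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval of the mean difference a - b.

    Deterministic given ``seed``; at least 100 resamples are required for
    the percentile endpoints to be meaningful.
    """
    if resamples < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"misaligned error vectors: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("confidence interval needs at least 2 pairs")
    d = a - b
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(resamples, d.size))
    means = d[idx].mean(axis=1)
    lo_q = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [lo_q, 1.0 - lo_q])
    return float(lo), float(hi)


@dataclass
class ComparisonTable:
    """Pairwise method comparison in the style of a CI matrix.

    ``ci[(i, j)]`` is the 95% CI of method i's error minus method j's error
    (negative favours i); ``significant[(i, j)]`` flags a two-sided Wilcoxon
    p < alpha; ``best_methods`` contains the lowest-mean-RMSE method and all
    methods not significantly different from it.
    """

    methods: list[str]
    mean_rmse: pd.Series
    ci: dict[tuple[str, str], tuple[float, float]]
    p_values: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    best_methods: set[str]
    alpha: float = 0.05
    n_observations: int = 0
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """The CI matrix as a DataFrame of formatted cells, '*' on best methods."""
        rows = {}
        for i in self.methods:
            row = {}
            for j in self.methods:
                if i == j:
                    row[j] = "-"
                else:
                    lo, hi = self.ci[(i, j)]
                    mark = "*" if self.significant[(i, j)] else ""
                    row[j] = f"({lo:.3f}, {hi:.3f}){mark}"
            rows[i] = row
        frame = pd.DataFrame(rows).T.loc[self.methods, self.methods]
        frame.insert(0, "mean_rmse", [
            f"{self.mean_rmse[m]:.3f}" + ("*" if m in self.best_methods else "")
            for m in self.methods])
        return frame

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("method").to_csv(path, sep="\t")

    def to_json(self) -> str:
        payload = {
            "methods": self.methods,
            "alpha": self.alpha,
            "n_observations": self.n_observations,
            "mean_rmse": {m: float(self.mean_rmse[m]) for m in self.methods},
            "best_methods": sorted(self.best_methods),
            "cells": [
                {"i": i, "j": j, "ci_low": self.ci[(i, j)][0],
                 "ci_high": self.ci[(i, j)][1], "p_value": self.p_values[(i, j)],
                 "significant": self.significant[(i, j)]}
                for i in self.methods for j in self.methods if i != j
            ],
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2)

    def to_html(self) -> str:
        """HTML table; significant cells carry the conventional colour classes

        (class ``better`` when the row method wins, ``worse`` when it loses).
        """
        head = "<tr><th>method</th><th>mean RMSE</th>" + "".join(
            f"<th>{j}</th>" for j in self.methods) + "</tr>"
        body = []
        for i in self.methods:
            cells = [f"<td>{self.mean_rmse[i]:.3f}</td>"]
            for j in self.methods:
                if i == j:
                    cells.append("<td>-</td>")
                    continue
                lo, hi = self.ci[(i, j)]
                cls = ""
                if self.significant[(i, j)]:
                    cls = ' class="better"' if hi < 0 else ' class="worse"'
                cells.append(f"<td{cls}>({lo:.3f}, {hi:.3f})</td>")
            body.append(f"<tr><th>{i}</th>" + "".join(cells) + "</tr>")
        return "<table>" + head + "".join(body) + "</table>"


def compare_methods(per_target_errors: dict[str, dict[str, np.ndarray]],
                    mode: str = "pooled", alpha: float = 0.05,
                    resamples: int = 10_000, seed: int = 0) -> ComparisonTable:
    """Build the pairwise comparison matrix across methods.

    Parameters
    ----------
    per_target_errors : dict
        ``method -> target -> per-test-pair absolute errors``; every method
        must cover the same targets with aligned error vectors.
    mode : {"pooled", "per_target"}
        Pairing granularity: one observation per (target, test pair)
        (default), or one per target using the target's RMSE.
    """
    methods = list(per_target_errors)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    target_sets = [tuple(sorted(per_target_errors[m])) for m in methods]
    if len(set(target_sets)) != 1:
        raise ValueError("methods were evaluated on different target sets")
    targets = list(target_sets[0])
    if mode not in ("pooled", "per_target"):
        raise ValueError(f"unknown pairing mode {mode!r}")

    def observable(method: str) -> np.ndarray:
        per_t = per_target_errors[method]
        if mode == "pooled":
            return np.concatenate([np.asarray(per_t[t], dtype=float) for t in targets])
        return np.array([float(np.sqrt(np.mean(np.asarray(per_t[t]) ** 2)))
                         for t in targets])

    obs = {m: observable(m) for m in methods}
    lengths = {len(v) for v in obs.values()}
    if len(lengths) != 1:
        raise ValueError("methods have misaligned error vectors")

    mean_rmse = pd.Series({
        m: float(np.mean([np.sqrt(np.mean(np.asarray(per_target_errors[m][t]) ** 2))
                          for t in targets]))
        for m in methods})

    ci: dict[tuple[str, str], tuple[float, float]] = {}
    p_values: dict[tuple[str, str], float] = {}
    significant: dict[tuple[str, str], bool] = {}
    for ii, i in enumerate(methods):
        for j in methods[ii + 1:]:
            pair_seed = (seed + zlib.crc32(f"{i}|{j}".encode())) % (2**31 - 1)
            lo, hi = paired_diff_ci(obs[i], obs[j], resamples=resamples,
                                    seed=pair_seed)
            p = paired_test(obs[i], obs[j], alternative="two_sided").p_value
            ci[(i, j)] = (lo, hi)
            ci[(j, i)] = (-hi, -lo)
            p_values[(i, j)] = p_values[(j, i)] = p
            significant[(i, j)] = significant[(j, i)] = bool(p < alpha)

    best = mean_rmse.idxmin()
    best_methods = {best} | {m for m in methods
                             if m != best and not significant[(best, m)]}
    return ComparisonTable(methods=methods, mean_rmse=mean_rmse, ci=ci,
                           p_values=p_values, significant=significant,
                           best_methods=best_methods, alpha=alpha,
                           n_observations=lengths.pop())
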