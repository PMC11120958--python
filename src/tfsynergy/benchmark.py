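"""Six-way method benchmark, ensemble comparison, and batch-effect harness.

The benchmark fits, per target gene: a forest and a ridge model on all TFs,
the same pair on the target's gold-standard (GS) regulators, a forest on
the top k_g TFs of the all-TF forest (k_g = the target's GS in-degree), and
a forest on the minimal TF set.  All methods are scored by RMSE on the same
held-out tail pairs, and compared with paired non-parametric statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tfsynergy.compare import ComparisonTable, compare_methods
from tfsynergy.expression import (ExpressionTimeSeries, GoldStandardNetwork,
                                  LaggedDataset, make_lagged_dataset)
from tfsynergy.models import (ModelConfig, derive_seed, ensemble_predict,
                              feature_importance_ranking, fit_regressor)
from tfsynergy.selection import SelectionConfig, min_disjoint_sets, minimal_set

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark",
           "run_ensemble_comparison", "run_batch_effect_analysis",
           "select_high_variance_targets"]


@dataclass(frozen=True)
class BenchmarkConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    alpha: float = 0.05
    ci_resamples: int = 10_000
    variance_fraction: float = 0.25  # batch-effect target eligibility
    comparison_mode: str = "pooled"
    seed: int = 42

    def model_for(self, *keys) -> ModelConfig:
        return ModelConfig(n_trees=self.model.n_trees, max_depth=self.model.max_depth,
                           ridge_alpha=self.model.ridge_alpha,
                           error_mode=self.model.error_mode,
                           cv_folds=self.model.cv_folds,
                           seed=derive_seed(self.seed, *keys))

    def selection_for(self, *keys) -> SelectionConfig:
        return SelectionConfig(alpha=self.alpha, model=self.model_for(*keys))


@dataclass
class BenchmarkReport:
    per_target_rmse: pd.DataFrame  # targets x methods
    per_target_errors: dict[str, dict[str, np.ndarray]]
    comparison: ComparisonTable
    excluded_targets: list[str]
    config: BenchmarkConfig

    @property
    def mean_rmse(self) -> pd.Series:
        return self.per_target_rmse.mean(axis=0)


def _test_errors(model, data: LaggedDataset) -> np.ndarray:
    return model.test_errors(data).to_numpy()


def run_benchmark(data: LaggedDataset, gs: GoldStandardNetwork,
                  targets: list[str] | None = None,
                  config: BenchmarkConfig | None = None) -> BenchmarkReport:
    """Evaluate the six modeling approaches on a common target set.

    Targets without at least one GS regulator present among the dataset's
    TFs are excluded (with a warning), so every method sees identical
    targets and test pairs.
    """
    config = config or BenchmarkConfig()
    in_degree = gs.in_degree
    candidates = list(targets) if targets is not None else sorted(
        set(gs.targets) & set(data.gene_ids))
    universe_all = set(data.tf_ids)

    eligible, excluded = [], []
    gs_features: dict[str, list[str]] = {}
    for g in candidates:
        regs = [t for t in gs.regulators_of(g) if t in universe_all and t != g]
        if regs and g in data.Y.columns:
            eligible.append(g)
            gs_features[g] = regs
        else:
            excluded.append(g)
    if excluded:
        warnings.warn(f"{len(excluded)} target(s) lack usable GS regulators "
                      "and were excluded from the benchmark")
    if not eligible:
        raise ValueError("no target has gold-standard regulators in the TF universe")

    methods = ["rf_all", "linear_all", "rf_gs", "linear_gs", "rf_topk", "rf_minimal"]
    errors: dict[str, dict[str, np.ndarray]] = {m: {} for m in methods}
    rmse_rows = {}

    for g in eligible:
        universe = sorted(universe_all - {g})
        m_all = fit_regressor(data, universe, g, kind="forest",
                              config=config.model_for(g, "rf_all"))
        errors["rf_all"][g] = _test_errors(m_all, data)

        m_lin = fit_regressor(data, universe, g, kind="ridge",
                              config=config.model_for(g, "linear_all"))
        errors["linear_all"][g] = _test_errors(m_lin, data)

        regs = gs_features[g]
        m_gs = fit_regressor(data, regs, g, kind="forest",
                             config=config.model_for(g, "rf_gs"))
        errors["rf_gs"][g] = _test_errors(m_gs, data)

        m_lgs = fit_regressor(data, regs, g, kind="ridge",
                              config=config.model_for(g, "linear_gs"))
        errors["linear_gs"][g] = _test_errors(m_lgs, data)

        k = int(in_degree[g])
        if k > len(universe):
            warnings.warn(f"k_g={k} for {g!r} exceeds the TF universe; clamped")
            k = len(universe)
        topk = feature_importance_ranking(m_all)[:k]
        m_topk = fit_regressor(data, topk, g, kind="forest",
                               config=config.model_for(g, "rf_topk"))
        errors["rf_topk"][g] = _test_errors(m_topk, data)

        minimal = minimal_set(g, universe, data,
                              config=config.selection_for(g, "rf_minimal"))
        errors["rf_minimal"][g] = _test_errors(minimal.final_model, data)

        rmse_rows[g] = {m: float(np.sqrt(np.mean(errors[m][g] ** 2))) for m in methods}

    comparison = compare_methods(errors, mode=config.comparison_mode,
                                 alpha=config.alpha, resamples=config.ci_resamples,
                                 seed=config.seed)
    table = pd.DataFrame(rmse_rows).T[methods]
    return BenchmarkReport(per_target_rmse=table, per_target_errors=errors,
                           comparison=comparison, excluded_targets=excluded,
                           config=config)


def run_ensemble_comparison(data: LaggedDataset, gs: GoldStandardNetwork,
                            targets: list[str] | None = None,
                            config: BenchmarkConfig | None = None
                            ) -> tuple[ComparisonTable, pd.DataFrame]:
    """Ensemble of the disjoint-set models versus the other forest methods.

    The ensemble averages the predictions of the per-disjoint-set models
    discovered for each target; the minimal-set method reuses the first
    discovered set's model, so a target with a single disjoint set makes
    the two methods coincide.  Returns the comparison table and the
    per-target RMSE table.
    """
    config = config or BenchmarkConfig()
    in_degree = gs.in_degree
    candidates = list(targets) if targets is not None else sorted(
        set(gs.targets) & set(data.gene_ids))
    universe_all = set(data.tf_ids)

    methods = ["ensemble_disjoint", "rf_all", "rf_gs", "rf_topk", "rf_minimal"]
    errors: dict[str, dict[str, np.ndarray]] = {m: {} for m in methods}
    rmse_rows = {}
    test_idx = data.test_index

    for g in candidates:
        regs = [t for t in gs.regulators_of(g) if t in universe_all and t != g]
        if not regs:
            continue
        universe = sorted(universe_all - {g})
        m_all = fit_regressor(data, universe, g, kind="forest",
                              config=config.model_for(g, "rf_all"))
        errors["rf_all"][g] = _test_errors(m_all, data)

        m_gs = fit_regressor(data, regs, g, kind="forest",
                             config=config.model_for(g, "rf_gs"))
        errors["rf_gs"][g] = _test_errors(m_gs, data)

        k = min(int(in_degree[g]), len(universe))
        topk = feature_importance_ranking(m_all)[:k]
        m_topk = fit_regressor(data, topk, g, kind="forest",
                               config=config.model_for(g, "rf_topk"))
        errors["rf_topk"][g] = _test_errors(m_topk, data)

        disjoint = min_disjoint_sets(g, universe, data,
                                     config=config.selection_for(g, "disjoint"))
        errors["rf_minimal"][g] = _test_errors(disjoint.per_set_models[0], data)
        ens = ensemble_predict(disjoint.per_set_models, data.X.loc[test_idx])
        errors["ensemble_disjoint"][g] = (
            (ens - data.Y.loc[test_idx, g]).abs().to_numpy())

        rmse_rows[g] = {m: float(np.sqrt(np.mean(errors[m][g] ** 2))) for m in methods}

    if not rmse_rows:
        raise ValueError("no target has gold-standard regulators in the TF universe")
    comparison = compare_methods(errors, mode=config.comparison_mode,
                                 alpha=config.alpha, resamples=config.ci_resamples,
                                 seed=config.seed)
    return comparison, pd.DataFrame(rmse_rows).T[methods]


def select_high_variance_targets(data: LaggedDataset, candidates: list[str],
                                 fraction: float = 0.25) -> list[str]:
    """The top ``fraction`` of candidates by training-partition target variance."""
    if not candidates:
        return []
    var = data.Y.loc[data.train_index, candidates].var(axis=0, ddof=0)
    n_keep = max(1, int(np.ceil(fraction * len(candidates))))
    return sorted(var.sort_values(ascending=False).index[:n_keep])


def run_batch_effect_analysis(series: ExpressionTimeSeries,
                              targets: list[str] | None = None,
                              config: BenchmarkConfig | None = None
                              ) -> tuple[dict[str, ComparisonTable], list[str]]:
    """Per batch: all-batch training versus single-batch training on that batch's tail.

    For each batch X, a forest on all TFs is trained once on every batch's
    training pairs and once on batch X's training pairs alone; both are
    scored on X's held-out tail, restricted to X's high-variance targets
    (top ``variance_fraction`` of training-partition variance).  Batches
    with no eligible target or too few pairs are skipped, and the skips
    reported.
    """
    config = config or BenchmarkConfig()
    if len(series.batches) < 2:
        raise ValueError("batch-effect analysis needs at least 2 batches")
    if series.space != "zscore":
        raise ValueError("normalize the series before the batch-effect analysis")

    full = make_lagged_dataset(series)
    candidates = list(targets) if targets is not None else [
        g for g in series.gene_ids if g not in set(series.tf_ids)]

    tables: dict[str, ComparisonTable] = {}
    notes: list[str] = []
    for batch in series.batches:
        sub = make_lagged_dataset(series.subset_batches([batch]))
        eligible = select_high_variance_targets(sub, [c for c in candidates
                                                      if c in sub.Y.columns],
                                                fraction=config.variance_fraction)
        if not eligible:
            notes.append(f"batch {batch}: skipped (no eligible high-variance targets)")
            continue
        if sub.n_train() < 2 or sub.n_test() < 1:
            notes.append(f"batch {batch}: skipped (too few lagged pairs)")
            continue

        errors: dict[str, dict[str, np.ndarray]] = {"all_batches": {},
                                                    "single_batch": {}}
        for g in eligible:
            universe = sorted(set(series.tf_ids) - {g})
            m_full = fit_regressor(full, universe, g, kind="forest",
                                   config=config.model_for(batch, g, "all"))
            preds = m_full.predict(sub.X.loc[sub.test_index])
            errors["all_batches"][g] = (
                (preds - sub.Y.loc[sub.test_index, g]).abs().to_numpy())
            m_single = fit_regressor(sub, universe, g, kind="forest",
                                     config=config.model_for(batch, g, "single"))
            errors["single_batch"][g] = _test_errors(m_single, sub)

        tables[str(batch)] = compare_methods(errors, mode=config.comparison_mode,
                                             alpha=config.alpha,
                                             resamples=config.ci_resamples,
                                             seed=derive_seed(config.seed, batch))
    if not tables:
        raise ValueError("every batch was skipped; no comparison possible")
    return tables, notes
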