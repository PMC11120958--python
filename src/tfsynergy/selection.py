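"""Minimal predictive TF sets and disjoint equally-predictive sets.

For each target gene the candidate TF set is iteratively cut in half along
the fitted model's feature-importance ranking; a halved set is kept only
while its training-error vector is not significantly worse (one-sided
paired Wilcoxon, alpha = 0.05) than the baseline error.  The survivor is
the target's *minimal TF set*.  Repeating the search on the remaining TFs
-- as long as the remainder alone can still match the all-TF baseline --
yields an ordered collection of pairwise-disjoint minimal sets, each of
which predicts the target about as well as using every TF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tfsynergy.compare import paired_test
from tfsynergy.expression import LaggedDataset
from tfsynergy.models import (FittedModel, ModelConfig, feature_importance_ranking,
                              fit_regressor, rmse)

__all__ = [
    "SelectionConfig",
    "MinimalSetResult",
    "DisjointSetsResult",
    "minimal_set",
    "min_disjoint_sets",
    "top_k_features",
    "results_to_json",
    "results_to_tsv",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the halving search.

    alpha
        Significance level of the one-sided gate "candidate worse than
        baseline".
    model_kind
        Estimator used throughout the search (forests by default; the
        importance ranking then comes from impurity importances).
    max_sets
        Optional cap on the number of disjoint sets per target (None means
        search until the remainder fails the gate or runs out).
    """

    alpha: float = 0.05
    model_kind: str = "forest"
    model: ModelConfig = field(default_factory=ModelConfig)
    max_sets: int | None = None


@dataclass
class MinimalSetResult:
    target_id: str
    selected: list[str]
    baseline_error: pd.Series
    final_error: pd.Series
    final_model: FittedModel
    halving_trace: list[tuple[int, float, float]]  # (set size, train RMSE, gate p)

    @property
    def size(self) -> int:
        return len(self.selected)


@dataclass
class DisjointSetsResult:
    target_id: str
    sets: list[list[str]]
    per_set_models: list[FittedModel]
    e_all: pd.Series
    termination_reason: str  # {"remainder_significantly_worse", "exhausted", "capped"}

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def validate_disjoint(self) -> None:
        seen: set[str] = set()
        for s in self.sets:
            if not s:
                raise ValueError("empty disjoint set")
            overlap = seen & set(s)
            if overlap:
                raise ValueError(f"sets are not pairwise disjoint: {sorted(overlap)}")
            seen |= set(s)


def _train_rmse(errors: pd.Series) -> float:
    return rmse(errors.to_numpy(), 0.0 * errors.to_numpy())


def minimal_set(target: str, tfs, data: LaggedDataset,
                baseline_error: pd.Series | None = None,
                config: SelectionConfig | None = None) -> MinimalSetResult:
    """Iterative importance-based halving down to a minimal predictive TF set.

    A model on all of ``tfs`` is fitted first; its training-error vector
    becomes the baseline unless one is supplied by the caller (the
    disjoint-set search passes the all-TF baseline down unchanged).  At
    each step the top half (floor(|F|/2), minimum 1) most influential TFs
    of the current model are refitted; the halved set is accepted while the
    paired one-sided test does not call its error significantly worse than
    the baseline.  The search stops at the first rejection or at a
    singleton set; a rejection of the very first halving returns the full
    input set.
    """
    config = config or SelectionConfig()
    tfs = sorted(set(tfs) - {target})
    if not tfs:
        raise ValueError("empty TF set")

    current = fit_regressor(data, tfs, target, kind=config.model_kind, config=config.model)
    if baseline_error is None:
        baseline = current.train_error_vector
    else:
        baseline = baseline_error
        if not baseline.index.equals(current.train_error_vector.index):
            raise ValueError("baseline error vector is not aligned with the training pairs")

    selected = list(current.feature_ids)
    final_model = current
    trace: list[tuple[int, float, float]] = [
        (len(selected), _train_rmse(current.train_error_vector), float("nan"))]

    while len(selected) > 1:
        half_size = max(1, len(selected) // 2)
        half = feature_importance_ranking(final_model)[:half_size]
        candidate = fit_regressor(data, half, target, kind=config.model_kind,
                                  config=config.model)
        gate = paired_test(candidate.train_error_vector, baseline, alternative="greater")
        trace.append((len(half), _train_rmse(candidate.train_error_vector), gate.p_value))
        if gate.p_value < config.alpha:  # significantly worse: reject the halving
            break
        selected = list(half)
        final_model = candidate

    return MinimalSetResult(
        target_id=target,
        selected=selected,
        baseline_error=baseline,
        final_error=final_model.train_error_vector,
        final_model=final_model,
        halving_trace=trace,
    )


def min_disjoint_sets(target: str, all_tfs, data: LaggedDataset,
                      config: SelectionConfig | None = None) -> DisjointSetsResult:
    """Ordered pairwise-disjoint minimal TF sets, each matching the all-TF error.

    The all-TF model's training error E_all is the fixed baseline.  The
    first set is the minimal set over all TFs; then, as long as a model on
    the remaining TFs is not significantly worse than E_all, another
    minimal set is extracted from the remainder.  Termination records
    whether the remainder failed the gate, ran out, or hit the configured
    cap.
    """
    config = config or SelectionConfig()
    universe = sorted(set(all_tfs) - {target})
    if not universe:
        raise ValueError("empty TF universe")

    m_all = fit_regressor(data, universe, target, kind=config.model_kind,
                          config=config.model)
    e_all = m_all.train_error_vector

    first = minimal_set(target, universe, data, baseline_error=e_all, config=config)
    sets = [first.selected]
    models = [first.final_model]
    remainder = sorted(set(universe) - set(first.selected))

    reason = "exhausted"
    while remainder:
        if config.max_sets is not None and len(sets) >= config.max_sets:
            reason = "capped"
            break
        m_r = fit_regressor(data, remainder, target, kind=config.model_kind,
                            config=config.model)
        gate = paired_test(m_r.train_error_vector, e_all, alternative="greater")
        if gate.p_value < config.alpha:
            reason = "remainder_significantly_worse"
            break
        nxt = minimal_set(target, remainder, data, baseline_error=e_all, config=config)
        sets.append(nxt.selected)
        models.append(nxt.final_model)
        remainder = sorted(set(remainder) - set(nxt.selected))

    result = DisjointSetsResult(target_id=target, sets=sets, per_set_models=models,
                                e_all=e_all, termination_reason=reason)
    result.validate_disjoint()
    return result


def top_k_features(data: LaggedDataset, target: str, k: int,
                   config: SelectionConfig | None = None) -> list[str]:
    """The k most influential TFs of the all-TF model for ``target``.

    This is the feature budget used to pit a learned TF set of the same
    size k_g against the gold-standard regulators of a target.
    """
    config = config or SelectionConfig()
    universe = sorted(set(data.tf_ids) - {target})
    if not 1 <= k <= len(universe):
        raise ValueError(f"k={k} out of range 1..{len(universe)}")
    model = fit_regressor(data, universe, target, kind=config.model_kind,
                          config=config.model)
    return feature_importance_ranking(model)[:k]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def results_to_json(results: list[DisjointSetsResult], path: str | Path | None = None) -> str:
    """Per-target disjoint sets with per-set summary RMSE and termination reason."""
    payload = []
    for r in results:
        payload.append({
            "target": r.target_id,
            "n_sets": r.n_sets,
            "termination_reason": r.termination_reason,
            "baseline_train_rmse": _train_rmse(r.e_all),
            "sets": [
                {"set_index": i, "tfs": s,
                 "train_rmse": _train_rmse(m.train_error_vector)}
                for i, (s, m) in enumerate(zip(r.sets, r.per_set_models), start=1)
            ],
        })
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def results_to_tsv(results: list[DisjointSetsResult], path: str | Path | None = None) -> str:
    """Flat (target, set_index, tf) table."""
    lines = ["target\tset_index\ttf"]
    for r in results:
        for i, s in enumerate(r.sets, start=1):
            for tf in s:
                lines.append(f"{r.target_id}\t{i}\t{tf}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
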