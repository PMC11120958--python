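"""Expression-matrix I/O, z-score normalization, and lagged train/test datasets.

The central objects are :class:`ExpressionTimeSeries` (a genes x samples
matrix with per-sample batch/timepoint metadata), the z-score transform
``z = (TPM - mu) / sigma`` applied per gene, and :class:`LaggedDataset`,
which pairs TF expression at timepoint ``t_i`` with gene expression at
``t_{i+1}`` inside each batch and reserves the tail of every batch for
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTimeSeries",
    "NormalizationParams",
    "GoldStandardNetwork",
    "LaggedDataset",
    "load_expression_matrix",
    "write_expression_matrix",
    "zscore_normalize",
    "split_train_test",
    "reserved_test_timepoints",
    "make_lagged_dataset",
    "load_gs_network",
]


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTimeSeries:
    """Genes x samples expression matrix with (batch, timepoint) metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes (index = gene ids), columns are samples.
    sample_meta : pandas.DataFrame
        Indexed by sample name, with integer columns ``batch`` (any hashable
        label coerced to str) and ``timepoint``.  Within a batch, timepoints
        must be the consecutive integers ``0 .. n``.
    tf_ids : list of str
        The transcription-factor subset of the gene ids.
    space : {"tpm", "zscore"}
        Which measurement space the values live in.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    tf_ids: list[str] = field(default_factory=list)
    space: str = "tpm"

    def __post_init__(self) -> None:
        if self.space not in ("tpm", "zscore"):
            raise ValueError(f"unknown expression space {self.space!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        missing_meta = [c for c in self.values.columns if c not in self.sample_meta.index]
        if missing_meta:
            raise ValueError(f"samples missing from metadata: {missing_meta}")
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        unknown_tfs = set(self.tf_ids) - set(self.values.index)
        if unknown_tfs:
            raise ValueError(f"tf_ids not present in the matrix: {sorted(unknown_tfs)}")
        for batch, meta in self.sample_meta.groupby("batch", sort=False):
            tps = np.sort(meta["timepoint"].to_numpy())
            if not np.array_equal(tps, np.arange(len(tps))):
                raise ValueError(
                    f"non-consecutive timepoints in batch {batch!r}: {tps.tolist()}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def batches(self) -> list:
        """Batch labels in first-appearance order."""
        return list(dict.fromkeys(self.sample_meta["batch"]))

    def batch_length(self, batch) -> int:
        return int((self.sample_meta["batch"] == batch).sum())

    def sample_at(self, batch, timepoint: int) -> str:
        meta = self.sample_meta
        hit = meta.index[(meta["batch"] == batch) & (meta["timepoint"] == timepoint)]
        if len(hit) != 1:
            raise KeyError(f"no unique sample for batch={batch!r}, t={timepoint}")
        return hit[0]

    def subset_batches(self, keep: list) -> "ExpressionTimeSeries":
        mask = self.sample_meta["batch"].isin(keep)
        cols = self.sample_meta.index[mask]
        return ExpressionTimeSeries(
            values=self.values[cols].copy(),
            sample_meta=self.sample_meta.loc[cols].copy(),
            tf_ids=list(self.tf_ids),
            space=self.space,
        )


@dataclass
class NormalizationParams:
    """Per-gene mean and population standard deviation of TPM values."""

    mu: pd.Series
    sigma: pd.Series
    fit_partition: str  # {"train_only", "all"}
    degenerate_genes: list[str] = field(default_factory=list)

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        """Map z-scores back to the original TPM scale (rows aligned to z)."""
        sigma = self.sigma.reindex(z.index)
        mu = self.mu.reindex(z.index)
        return z.mul(sigma, axis=0).add(mu, axis=0)


@dataclass
class GoldStandardNetwork:
    """Curated TF -> target edges restricted to genes seen in the expression data."""

    edges: pd.DataFrame  # columns: tf, target, sign
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.edges = self.edges.drop_duplicates(subset=["tf", "target"]).reset_index(drop=True)

    @property
    def tf_universe(self) -> set[str]:
        return set(self.edges["tf"])

    @property
    def targets(self) -> set[str]:
        return set(self.edges["target"])

    @property
    def in_degree(self) -> pd.Series:
        """k_g: number of distinct TFs with an edge into each target."""
        return self.edges.groupby("target")["tf"].nunique()

    def regulators_of(self, target: str) -> list[str]:
        return sorted(self.edges.loc[self.edges["target"] == target, "tf"].unique())


@dataclass
class LaggedDataset:
    """(input at t_i, target at t_{i+1}) sample pairs with a train/test split.

    ``X`` holds TF expression at the input timepoint of each pair, ``Y``
    holds all genes' expression at the target timepoint; both are indexed by
    pair id ``"<batch>:<i>-><i+1>"``.
    """

    X: pd.DataFrame
    Y: pd.DataFrame
    pairs: pd.DataFrame  # columns: batch, input_t, target_t, partition
    tf_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.Y.index) or not self.X.index.equals(self.pairs.index):
            raise ValueError("X, Y and pairs must share one pair index")
        bad = self.pairs[self.pairs["target_t"] != self.pairs["input_t"] + 1]
        if len(bad):
            raise ValueError("pairs must link consecutive timepoints")

    @property
    def train_index(self) -> pd.Index:
        return self.pairs.index[self.pairs["partition"] == "train"]

    @property
    def test_index(self) -> pd.Index:
        return self.pairs.index[self.pairs["partition"] == "test"]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.Y.columns)

    def n_train(self) -> int:
        return len(self.train_index)

    def n_test(self) -> int:
        return len(self.test_index)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table, tolerating '#' comment lines."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#", index_col=0)


def load_expression_matrix(matrix_path: str | Path, meta_path: str | Path,
                           tf_ids: list[str] | None = None,
                           space: str = "tpm") -> ExpressionTimeSeries:
    """Load a delimited genes x samples matrix plus its batch/timepoint sidecar.

    The matrix has gene ids in the first column and one column per sample;
    the sidecar maps every sample name to a ``batch`` label and an integer
    ``timepoint``.  Any sample column without metadata, non-numeric cell, or
    batch with non-consecutive timepoints is a hard error.
    """
    raw = _read_table(matrix_path)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {raw.index[r]!r}, sample {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    meta = _read_table(meta_path)
    if "batch" not in meta.columns or "timepoint" not in meta.columns:
        raise ValueError("metadata must have 'batch' and 'timepoint' columns")
    missing = [c for c in numeric.columns if c not in meta.index]
    if missing:
        raise ValueError(f"metadata missing for sample column(s): {missing}")
    meta = meta.loc[list(numeric.columns), ["batch", "timepoint"]].copy()
    meta["batch"] = meta["batch"].astype(str)
    meta["timepoint"] = meta["timepoint"].astype(int)
    meta.index.name = None
    values = numeric.astype(float).rename_axis(None).rename_axis(None, axis=1)
    return ExpressionTimeSeries(values=values, sample_meta=meta,
                                tf_ids=list(tf_ids or []), space=space)


def write_expression_matrix(series: ExpressionTimeSeries,
                            matrix_path: str | Path, meta_path: str | Path) -> None:
    """Write the matrix and metadata in the same TSV layout the loader reads."""
    series.values.rename_axis("gene").to_csv(matrix_path, sep="\t")
    series.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


def load_gs_network(path: str | Path, series: ExpressionTimeSeries) -> GoldStandardNetwork:
    """Load a TF -> target edge list restricted to genes present in ``series``.

    The file is tab/comma-delimited with columns ``tf`` and ``target`` and an
    optional ``sign`` column taking values in {+, -, ?}.  Edges touching a
    gene absent from the expression data are dropped (and counted); zero
    surviving edges is an error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, comment="#")
    cols = [c.lower() for c in table.columns]
    table.columns = cols
    if "tf" not in cols or "target" not in cols:
        raise ValueError("edge list must have 'tf' and 'target' columns")
    if "sign" not in cols:
        table["sign"] = "?"
    present = set(series.gene_ids)
    keep = table["tf"].isin(present) & table["target"].isin(present)
    n_dropped = int((~keep).sum())
    kept = table.loc[keep, ["tf", "target", "sign"]]
    if kept.empty:
        raise ValueError("no gold-standard edge touches genes present in the expression data")
    return GoldStandardNetwork(edges=kept.reset_index(drop=True), n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _training_samples(series: ExpressionTimeSeries) -> list[str]:
    """Samples whose timepoint is not a reserved test target in its batch."""
    out = []
    for batch in series.batches:
        n = series.batch_length(batch) - 1
        test_tps = reserved_test_timepoints(n)
        meta = series.sample_meta[series.sample_meta["batch"] == batch]
        out.extend(meta.index[~meta["timepoint"].isin(test_tps)])
    return out


def zscore_normalize(series: ExpressionTimeSeries, fit_partition: str = "train_only",
                     per_batch: bool = False) -> tuple[ExpressionTimeSeries, NormalizationParams]:
    """Transform TPM values to per-gene z-scores, z = (TPM - mu) / sigma.

    ``mu`` and ``sigma`` (population convention, divide-by-N) are computed
    over the fit partition: by default only over training-partition samples,
    so no test information leaks into the transform; ``fit_partition="all"``
    uses every sample.  Genes with sigma = 0 on the fit partition are
    excluded from the returned matrix and reported in
    ``NormalizationParams.degenerate_genes``.

    With ``per_batch=True`` the transform is fit and applied independently
    within each batch; a gene is degenerate if it is constant in any batch.
    """
    if series.space != "tpm":
        raise ValueError("series is already z-scored")
    if fit_partition not in ("train_only", "all"):
        raise ValueError(f"unknown fit_partition {fit_partition!r}")

    if per_batch:
        z_parts, mus, sigmas = [], [], []
        degenerate: set[str] = set()
        for batch in series.batches:
            sub = series.subset_batches([batch])
            fit_cols = sub.values.columns if fit_partition == "all" else _training_samples(sub)
            fit = sub.values[list(fit_cols)]
            mu = fit.mean(axis=1)
            sigma = fit.std(axis=1, ddof=0)
            degenerate |= set(sigma.index[sigma == 0])
            z_parts.append(sub.values.sub(mu, axis=0).div(sigma.replace(0, np.nan), axis=0))
            mus.append(mu)
            sigmas.append(sigma)
        z = pd.concat(z_parts, axis=1)[series.values.columns]
        keep = [g for g in series.gene_ids if g not in degenerate]
        params = NormalizationParams(mu=pd.concat(mus, axis=1).mean(axis=1),
                                     sigma=pd.concat(sigmas, axis=1).mean(axis=1),
                                     fit_partition=fit_partition,
                                     degenerate_genes=sorted(degenerate))
    else:
        fit_cols = series.values.columns if fit_partition == "all" else _training_samples(series)
        fit = series.values[list(fit_cols)]
        mu = fit.mean(axis=1)
        sigma = fit.std(axis=1, ddof=0)
        degenerate = set(sigma.index[sigma == 0])
        z = series.values.sub(mu, axis=0).div(sigma.replace(0, np.nan), axis=0)
        keep = [g for g in series.gene_ids if g not in degenerate]
        params = NormalizationParams(mu=mu, sigma=sigma, fit_partition=fit_partition,
                                     degenerate_genes=sorted(degenerate))

    zseries = ExpressionTimeSeries(
        values=z.loc[keep],
        sample_meta=series.sample_meta.copy(),
        tf_ids=[t for t in series.tf_ids if t in keep],
        space="zscore",
    )
    return zseries, params


# ---------------------------------------------------------------------------
# Tail split and lagged pairs
# ---------------------------------------------------------------------------

def reserved_test_timepoints(n: int) -> set[int]:
    """Timepoints of a batch ``t_0 .. t_n`` reserved as test-pair targets.

    The tail of every series is held out: for short series (n < 5) only t_n,
    for 5 <= n < 10 the last two timepoints, and for n >= 10 the last three.
    """
    if n < 1:
        raise ValueError("a batch needs at least two timepoints to form a lagged pair")
    if n < 5:
        return {n}
    if n < 10:
        return {n - 1, n}
    return {n - 2, n - 1, n}


def split_train_test(n: int) -> dict[int, str]:
    """Partition label for each lagged pair of one batch, keyed by target timepoint.

    A pair is labelled by the timepoint it predicts; its input is always the
    immediately preceding timepoint (which may itself be a training target).
    """
    test = reserved_test_timepoints(n)
    return {t: ("test" if t in test else "train") for t in range(1, n + 1)}


def make_lagged_dataset(series: ExpressionTimeSeries) -> LaggedDataset:
    """Enumerate within-batch (t_i -> t_{i+1}) pairs with the tail split applied.

    ``X`` carries TF expression at t_i, ``Y`` all genes at t_{i+1}; the total
    number of pairs is sum over batches of (batch length - 1).
    """
    if series.space != "zscore":
        raise ValueError("lagged datasets are built in z-score space; normalize first")
    if not series.tf_ids:
        raise ValueError("series has an empty TF list")
    rows_x, rows_y, recs, ids = [], [], [], []
    for batch in series.batches:
        n = series.batch_length(batch) - 1
        labels = split_train_test(n)
        for tgt in range(1, n + 1):
            s_in = series.sample_at(batch, tgt - 1)
            s_out = series.sample_at(batch, tgt)
            ids.append(f"{batch}:{tgt - 1}->{tgt}")
            rows_x.append(series.values.loc[series.tf_ids, s_in])
            rows_y.append(series.values[s_out])
            recs.append({"batch": batch, "input_t": tgt - 1, "target_t": tgt,
                         "partition": labels[tgt]})
    X = pd.DataFrame(rows_x, index=ids)
    Y = pd.DataFrame(rows_y, index=ids)
    pairs = pd.DataFrame(recs, index=ids)
    return LaggedDataset(X=X, Y=Y, pairs=pairs, tf_ids=list(series.tf_ids))
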