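import numpy as np
import pandas as pd
import pytest

from tfsynergy.expression import ExpressionTimeSeries, make_lagged_dataset
from tfsynergy.models import ModelConfig
from tfsynergy.synthetic import RegulatoryProgram, SyntheticConfig, generate_timeseries


@pytest.fixture
def tiny_series():
    """3 genes x 4 samples, one batch, hand-written values in TPM space."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [2.0, 1.0, 4.0, 3.0]],
        index=["TFA", "CONST", "G1"],
        columns=["s0", "s1", "s2", "s3"],
    )
    meta = pd.DataFrame({"batch": ["b1"] * 4, "timepoint": [0, 1, 2, 3]},
                        index=values.columns)
    return ExpressionTimeSeries(values=values, sample_meta=meta,
                                tf_ids=["TFA"], space="tpm")


@pytest.fixture
def quick_model():
    """Smaller forest for unit tests whose claim is not about default power."""
    return ModelConfig(n_trees=30, seed=0)


def planted_pair_config(seed, *, n_tfs=16, noise_sd=0.05, coefficients=(1.0, -0.8),
                        redundant=False, batches=None, link_kind="linear"):
    """One target driven by TF001+TF002 (optionally with a redundant copy set)."""
    sets = ((("TF001", "TF002"), ("TF003", "TF004")) if redundant
            else (("TF001", "TF002"),))
    prog = RegulatoryProgram(target_id="G001", driver_sets=sets,
                             link_kind=link_kind, coefficients=coefficients,
                             noise_sd=noise_sd)
    kwargs = {} if batches is None else {"batches": batches}
    return SyntheticConfig(n_tfs=n_tfs, n_targets=1, programs=(prog,),
                           seed=seed, **kwargs)


@pytest.fixture
def planted_dataset():
    """Lagged dataset with a clean two-driver linear target (seed 0)."""
    series, progs = generate_timeseries(planted_pair_config(0))
    return make_lagged_dataset(series), progs[0]
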