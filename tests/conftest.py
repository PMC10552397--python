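import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tppmelt as tp

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tr_design_small():
    """Four-temperature, two-replicate paired design (4 labeling sets)."""
    return tp.build_tr_design([40.0, 46.0, 52.0, 58.0], replicates=2)


@pytest.fixture
def noiseless():
    return tp.NoiseModel(cv=0.0, sample_scale_sd=0.0, missing_rate=0.0)


@pytest.fixture
def homogeneous_spec():
    """All proteins share one vehicle melting curve (T_m 52, slope -0.4).

    With a shared curve the global-curve normalization is exactly neutral,
    which makes noiseless runs exactly recoverable end to end.
    """
    def make(proportions):
        return tp.TruthSpec(
            proportions=proportions,
            tm_range=(52.0, 52.0), slope_range=(-0.4, -0.4),
            i_min_range=(0.05, 0.05),
        )
    return make


def matched_ratio_table(matrix):
    """Compound/vehicle intensity ratios at matched (temperature, replicate)."""
    cols = {}
    for (temp, rep), ann in matrix.samples.groupby(["temperature", "replicate"]):
        comp = ann.index[ann["treatment"] == "compound"][0]
        veh = ann.index[ann["treatment"] == "vehicle"][0]
        cols[(temp, rep)] = matrix.values[comp] / matrix.values[veh]
    return pd.DataFrame(cols)
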