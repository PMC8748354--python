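import numpy as np
import pandas as pd
import pytest

import mitoresponse as mr


@pytest.fixture
def small_cfg():
    """Compact synthetic design: 4 concentrations, sparse timepoints."""
    return mr.SynthConfig(
        seed=7,
        n_compounds=2,
        n_probes=60,
        concentrations=mr.synth.default_concentrations(4),
        timepoints=(0, 6, 12, 18, 24),
    )


@pytest.fixture
def noiseless_cfg(small_cfg):
    import dataclasses

    return dataclasses.replace(small_cfg, noise_sd=0.0)


@pytest.fixture
def normalized_experiment(small_cfg):
    truth = mr.default_ground_truth(small_cfg)
    exp = mr.gen_counts(small_cfg, truth)
    return mr.median_of_ratios(exp), truth


def make_de_table(rows):
    """DE table from (probe, condition, log2fc, padj, trend_p) tuples."""
    df = pd.DataFrame(rows, columns=["probe", "condition", "log2fc", "padj", "trend_p"])
    df["se"] = 1.0
    df["p_value"] = df["padj"]
    return df
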