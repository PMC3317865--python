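import warnings

import numpy as np
import pandas as pd
import pytest

import rppa_triscore as rt
from rppa_triscore import synth


@pytest.fixture(scope="session")
def sheet85():
    """The study design: 11 lines x 2 media x 2 treatments x 2 reps - 3 drops."""
    return rt.build_design(5, 6, 2, rt.DEFAULT_DROPPED)


@pytest.fixture(scope="session")
def sheet88():
    return rt.build_design(5, 6, 2)


@pytest.fixture(scope="session")
def small_sheet():
    """Compact balanced design: 2 glioma + 2 adenocarcinoma lines, 2 reps."""
    return rt.build_design(2, 2, 2)


@pytest.fixture(scope="session")
def pipeline_result():
    """One shared default pipeline run (seed 7), reused across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rt.run_pipeline(rt.PipelineConfig(n_proteins=40), seed=7)


def make_truth(sheet, proteins, seed=0, **cfg_kwargs):
    cfg = synth.default_effect_config(proteins, **cfg_kwargs)
    return rt.simulate_truth(sheet, proteins, cfg, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
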