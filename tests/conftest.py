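import numpy as np
import pytest

import tcswitch as t


@pytest.fixture(scope="session")
def wt():
    return t.default_params("wild_type")


@pytest.fixture(scope="session")
def t281r():
    return t.default_params("t281r")


@pytest.fixture(scope="session")
def t281r_dp2():
    return t.default_params("t281r_dp2")


@pytest.fixture(scope="session")
def detailed_wt():
    return t.default_params("detailed_wt")


@pytest.fixture(scope="session")
def detailed_t281r():
    return t.default_params("detailed_t281r")


@pytest.fixture(scope="session")
def decoupled_low_kd():
    return t.default_params("decoupled_low_kd")


@pytest.fixture(scope="session")
def decoupled_high_kd():
    return t.default_params("decoupled_high_kd")


@pytest.fixture(scope="session")
def t281r_folds(t281r):
    """Saddle-node locations of the T281R kinase-rate sweep (computed once)."""
    bt = t.bifurcation_sweep("reduced", t281r, "k_k", np.logspace(-4, 0, 25))
    assert len(bt.folds) == 2
    return sorted(bt.folds)


@pytest.fixture(scope="session")
def t281r_vf_folds(t281r):
    bt = t.bifurcation_sweep("reduced", t281r, "V_f", np.logspace(-2, 1, 25))
    assert len(bt.folds) == 2
    return sorted(bt.folds)
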