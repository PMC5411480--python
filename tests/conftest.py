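import numpy as np
import pytest

import tonebind as tb


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def params():
    """Canonical simulation parameters used across the suite."""
    return tb.ModelParams(sigma2_track=2.0, sigma2_sense=1.0)


@pytest.fixture(scope="session")
def exp1_curve():
    """Predicted P(up) over the 1-11 st interval scan, shared by the tests
    that read the psychometric curve (crossing point, octave symmetry)."""
    import json

    params = tb.ModelParams(2.0, 1.0)
    trials = tb.build_experiment("exp1", dict(reps=500), seed=101)
    table = tb.predict_condition(trials, params,
                                 rng=np.random.default_rng(202), n_sim=3)
    table["interval_st"] = [json.loads(c)["interval_st"]
                            for c in table["condition"]]
    table = table.sort_values("interval_st").reset_index(drop=True)
    return table
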