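import numpy as np
import pandas as pd
import pytest

import hepapod as hp


@pytest.fixture(scope="session")
def design():
    return hp.make_design(n_substances=1, top_conc=500.0, n_levels=9,
                          n_reps=4, n_runs=2)


@pytest.fixture(scope="session")
def planted_counts(design):
    """One Hill responder (BMC 10 uM, 8-fold) among 50 null probes."""
    responders = [
        hp.ResponderSpec("HILL_A", "hill", true_bmc=10.0, direction="up",
                         max_fold_change=8.0, noise_sd=0.2),
    ]
    return hp.simulate_counts(design, responders, n_null_probes=50,
                              mean_depth=3e5, seed=11)


@pytest.fixture(scope="session")
def planted_expr(planted_counts):
    return hp.normalize(planted_counts)


@pytest.fixture(scope="session")
def run1_profile(planted_expr):
    """(doses, responder values, all values) for substance S01 run R1."""
    meta = planted_expr.sample_meta
    sel = meta[(meta["substance"] == "S01") & (meta["run"] == "R1")]
    doses = sel["concentration"].to_numpy()
    y = planted_expr.values.loc["HILL_A", sel.index].to_numpy()
    return doses, y, planted_expr.values[sel.index]


def make_linear_data(a=5.0, b=2.0, sigma=0.5, n_reps=4, seed=0,
                     doses=(0.0, 0.05, 0.15, 0.5, 1.5)):
    """Replicated linear dose-response data with Gaussian noise."""
    rng = np.random.default_rng(seed)
    d = np.repeat(doses, n_reps)
    y = a + b * d + rng.normal(0, sigma, size=d.size)
    return d, y


@pytest.fixture
def toy_results():
    """Hand-built probe-fit table exercising each removal rule once.

    Rows: two clean survivors plus one failure per filter criterion.
    """
    return pd.DataFrame(
        {
            "probe_id": ["ok1", "ok2", "bad_p", "bad_ratio", "bad_low", "bad_fc"],
            "substance": ["S"] * 6,
            "run": ["R1"] * 6,
            "model": ["hill"] * 6,
            "bmc": [10.0, 20.0, 10.0, 10.0, 0.004, 10.0],
            "bmcl": [5.0, 10.0, 5.0, 1.0, 0.002, 5.0],
            "bmcu": [20.0, 40.0, 20.0, 41.0, 0.008, 20.0],
            "fit_p_value": [0.5, 0.9, 0.0005, 0.5, 0.5, 0.5],
            "max_fold_change": [4.0, 2.0, 4.0, 4.0, 4.0, 1.9],
            "direction": ["up"] * 6,
        }
    )
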