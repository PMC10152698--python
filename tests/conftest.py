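import numpy as np
import pandas as pd
import pytest

from indiri.synthetic_data import generate_cohort, thyroid_panel_spec


@pytest.fixture(scope="session")
def panel_specs():
    return thyroid_panel_spec(20000)


@pytest.fixture(scope="session")
def tsh_values(panel_specs):
    """Contaminated strongly right-skewed cohort, n=20000."""
    return generate_cohort(panel_specs["TSH"], seed=3)["value"].to_numpy()


@pytest.fixture(scope="session")
def gauss_sample():
    """Uncontaminated N(10, 1) sample, n=10000."""
    return np.random.default_rng(1).normal(10.0, 1.0, 10000)


@pytest.fixture()
def small_table():
    """A small balanced measurement table covering all sex x band cells."""
    rng = np.random.default_rng(5)
    rows = []
    for sex in ("F", "M"):
        for lo in (18, 30, 40, 50):
            for _ in range(30):
                rows.append(
                    {
                        "analyte": "A",
                        "value": float(np.exp(rng.normal(0.5, 0.3))),
                        "sex": sex,
                        "age": int(rng.integers(lo, lo + 10)),
                    }
                )
    return pd.DataFrame(rows)
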