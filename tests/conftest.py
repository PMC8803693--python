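import numpy as np
import pandas as pd
import pytest

from clppkit.pipeline import run_pipeline
from clppkit.synthetic_data import GeneratorConfig, generate_experiment


class Run:
    """Bundle of one generated experiment and its pipeline result."""

    def __init__(self, config):
        self.config = config
        self.plate, self.ri4, self.truth = generate_experiment(config)
        self.result = run_pipeline(self.plate, self.ri4)

    def solid_fits(self):
        f = self.result.fits
        return f[(f["matrix"] == "solid") & ~f["imputed"].astype(bool)]

    def labelled_fits(self):
        return self.solid_fits().merge(
            self.truth.wells, on=["sample_id", "substrate"], suffixes=("", "_true")
        )


@pytest.fixture(scope="session")
def default_run():
    """Default (noisy) synthetic experiment, full pipeline."""
    return Run(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_run():
    """Zero measurement noise, default failure-class mix, exact RI4."""
    return Run(GeneratorConfig(seed=5, noise_sd=0.0, ri4_sigma_norm=0.0))


def mini_readings(records):
    """Plate-table DataFrame from compact dicts, filling default metadata."""
    defaults = dict(
        sample_id="S1-d0", reactor_id=1, treatment="aerobic", day=0, matrix="solid"
    )
    return pd.DataFrame([{**defaults, **r} for r in records])


@pytest.fixture
def gompertz_oracle():
    """Closed-form model evaluation, written out independently."""

    def value(A, mu, lam, t):
        t = np.asarray(t, dtype=float)
        return A * np.exp(-np.exp((mu * np.e / A) * (lam - t) + 1.0))

    return value
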