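"""Shared fixtures: small seeded panels and cohorts, generated in-process."""

import numpy as np
import pandas as pd
import pytest

from phasedyn.panels import TimeSeriesPanel
from phasedyn.simulate import SimulationConfig, generate_cohort, generate_null_cohort

TR = 2.638


@pytest.fixture(scope="session")
def long_sine_panel():
    """Two identical 0.05 Hz cosine nodes, 2000 points — analytic identities."""
    t = np.arange(2000) * TR
    x = np.cos(2 * np.pi * 0.05 * t)
    return TimeSeriesPanel(values=np.vstack([x, x]), tr_seconds=TR)


@pytest.fixture(scope="session")
def small_config():
    """Tiny oscillator study: 3 groups x 6 subjects, 10 nodes."""
    return SimulationConfig(n_subjects=6, n_nodes=10)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, spec_seed=321)


@pytest.fixture(scope="session")
def small_null_cohort(small_config):
    return generate_null_cohort(small_config, spec_seed=322)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_design_frame(rng, labels):
    """Random covariates independent of group, as a cohort-like frame."""
    n = len(labels)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": labels,
            "age": rng.normal(65, 10, n),
            "sex": rng.integers(0, 2, n),
            "headcoil": rng.integers(0, 2, n),
            "motion": np.exp(rng.normal(-2.3, 0.5, n)),
        }
    )
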