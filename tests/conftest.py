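"""Shared fixtures.

The full toy experiment (four orientation presets, umbrella windows, WHAM,
shell analysis, buried areas) is expensive, so it runs once per session and
is shared by the end-to-end and acceptance tests.
"""

import numpy as np
import pytest

from dimerpmf.driver import ExperimentPlan, run_experiment, run_unrestrained_control
from dimerpmf.toygen import PotentialSpec1D, generate_umbrella_dataset


@pytest.fixture(scope="session")
def plan() -> ExperimentPlan:
    return ExperimentPlan(master_seed=3)


@pytest.fixture(scope="session")
def experiment_bundle(plan):
    """One full landscape experiment (all four orientation presets)."""
    return run_experiment(plan)


@pytest.fixture(scope="session")
def control_bundle(plan):
    """Orientationally unrestrained (k_rot = 0) control configuration."""
    return run_unrestrained_control(plan)


@pytest.fixture(scope="session")
def config_by_label(experiment_bundle):
    return {c["label"]: c for c in experiment_bundle["configurations"]}


@pytest.fixture(scope="session")
def double_well_spec() -> PotentialSpec1D:
    return PotentialSpec1D(
        "double_well", {"barrier": 3.0, "m1": 0.35, "m2": 0.65}, (0.0, 1.0)
    )


@pytest.fixture(scope="session")
def harmonic_spec() -> PotentialSpec1D:
    return PotentialSpec1D("harmonic", {"a": 8.0, "m": 0.5}, (0.0, 1.0))


@pytest.fixture(scope="session")
def harmonic_windows(harmonic_spec):
    """Umbrella windows on the harmonic oracle (moderate n, fast)."""
    centers = np.linspace(0.1, 0.9, 11)
    return generate_umbrella_dataset(harmonic_spec, centers, 40.0, 10_000, 7)
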