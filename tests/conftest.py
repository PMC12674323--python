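import numpy as np
import pandas as pd
import pytest

from compobench import SimulationConfig, default_design


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def toy_counts():
    """Deterministic 50-taxa x 6-sample count table with depth variation.

    Strictly positive so the classic (all-positive-taxa) geometric means
    exist; the frozen TMM / size-factor oracle values in the tests were
    computed on exactly this matrix.
    """
    rng = np.random.default_rng(20240817)
    lam = np.exp(rng.normal(3.0, 1.2, size=50))
    depth_scale = rng.uniform(0.5, 2.0, size=6)
    counts = rng.poisson(lam[:, None] * depth_scale[None, :]) + 1
    return pd.DataFrame(
        counts,
        index=[f"taxon{i:02d}" for i in range(50)],
        columns=[f"s{j}" for j in range(6)],
    )


@pytest.fixture(scope="session")
def small_config():
    """Reduced grid for fast end-to-end runs."""
    return SimulationConfig(
        effect_sizes=(1.0, 10.0),
        proportions=(0.1, 0.5),
        n_iterations=3,
        run_permanova=False,
    )


@pytest.fixture(scope="session")
def simulated_counts(design):
    """One default-scale simulated dataset (abundances + counts)."""
    from compobench import ScenarioSpec, simulate_cohort_study, simulate_sequencing

    rng = np.random.default_rng(42)
    spec = ScenarioSpec("unidirectional", 1.0, 0.25)
    abund, truth, _ = simulate_cohort_study(spec, rng, design=design)
    counts = simulate_sequencing(abund, rng=rng)
    return abund, counts, truth
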