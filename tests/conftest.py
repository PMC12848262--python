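import numpy as np
import pytest

from permquant import (
    CohortDesign,
    FitSettings,
    GeneratorTruth,
    fit_population,
    generate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic study (12 animals, seed 7), shared across tests."""
    series, serum, truth = generate_cohort(CohortDesign(), GeneratorTruth(), seed=7)
    return series, serum, truth


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Population fit of the shared cohort (expensive; computed once)."""
    series, _, _ = default_cohort
    fit = fit_population(series, FitSettings(seed=7))
    assert fit.converged
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
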