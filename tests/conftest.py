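import numpy as np
import pytest

from riversync import simulate
from riversync.dfa import DynamicFactorAnalysis


@pytest.fixture(scope="session")
def small_panel():
    """Complete 4-river, 8-year panel with known truth (m=1)."""
    truth = simulate.default_truth(seed=42, S=4, T=8, m=1, obs_sd=8.0, missing=False)
    panel, truth = simulate.simulate_panel(truth)
    return panel, truth


@pytest.fixture(scope="session")
def small_fit(small_panel):
    panel, _ = small_panel
    return DynamicFactorAnalysis(panel.center(), m=1, r_structure="diagonal_equal").fit(
        max_iter=200
    )


@pytest.fixture(scope="session")
def two_trend_fit():
    """Converged 2-trend fit on a 6-river panel with gaps."""
    truth = simulate.default_truth(seed=7, S=6, T=30, m=2, obs_sd=8.0)
    panel, truth = simulate.simulate_panel(truth)
    fit = DynamicFactorAnalysis(panel.center(), m=2, r_structure="diagonal_equal").fit(
        max_iter=500, tol=1e-6
    )
    return panel, truth, fit


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
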