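import numpy as np
import pytest

from adaptref.data_model import Sigma2Spec, simulate_population, validate_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """Three subjects, hand-written values."""
    return validate_table(
        [
            ("A", 1, 5.0),
            ("A", 2, 6.0),
            ("A", 3, 5.5),
            ("B", 1, 4.0),
            ("B", 2, 4.5),
            ("B", 3, 5.0),
            ("C", 1, 6.5),
            ("C", 2, 6.0),
            ("C", 3, 5.0),
        ]
    )


@pytest.fixture
def sim_table():
    """Medium simulated hierarchical dataset with heterogeneous WSV."""
    table, params = simulate_population(
        I=30, n_per_subject=15, mu=10.0, tau2=4.0,
        sigma2_spec=Sigma2Spec.from_ratios(0.5, 0.25), seed=7,
    )
    return table, params
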