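import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from raschkit.instrument import InstrumentSpec, ItemSpec, ResponseMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# fixed 8 persons x 5 dichotomous items, mixed raw scores, no extremes;
# shared by the estimation unit tests and the grid-oracle check
SMALL_DICH = np.array([
    [0, 0, 1, 0, 1],
    [1, 0, 0, 0, 0],
    [0, 1, 1, 0, 1],
    [1, 1, 1, 0, 1],
    [0, 0, 0, 0, 1],
    [0, 0, 0, 1, 1],
    [1, 0, 1, 0, 0],
    [0, 1, 1, 1, 0],
])


@pytest.fixture(scope="session")
def small_dich_matrix():
    spec = InstrumentSpec(
        [ItemSpec(f"i{j}", "D", 2, "g") for j in range(5)])
    matrix = ResponseMatrix(
        persons=[f"p{n}" for n in range(8)],
        items=[f"i{j}" for j in range(5)],
        values=SMALL_DICH.copy(),
    )
    return matrix, spec


@pytest.fixture(scope="session")
def bank300():
    """One seeded 300 x 20 dichotomous bank calibration, reused across tests."""
    import raschkit as rk
    cfg = rk.dichotomous_bank_config()
    matrix, truth = rk.generate(cfg, seed=1)
    result = rk.RaschModel(matrix, cfg.spec).fit()
    return cfg, matrix, truth, result
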