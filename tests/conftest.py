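import numpy as np
import pytest

from nlgrn.datamodel import (
    GeneEdge,
    GeneExpressionDataset,
    InferredNetwork,
    ModelParameters,
    NltEdge,
    TimeGrid,
)
from nlgrn.estimation import GAConfig, multi_start
from nlgrn.synthetic import SyntheticSpec, generate_benchmark, reference_time_grid

GRID_SPAN = 168.0


@pytest.fixture
def small_grid():
    return TimeGrid((0.0, 1.0, 2.0, 4.0, 8.0))


@pytest.fixture
def small_dataset(small_grid):
    rng = np.random.default_rng(11)
    values = rng.uniform(0.2, 2.0, size=(3, small_grid.count))
    return GeneExpressionDataset(("A", "B", "C"), small_grid, values)


@pytest.fixture
def decay_dataset():
    """Single-gene pure-decay observations on the reference grid."""
    grid = reference_time_grid()
    t = grid.as_array()
    values = np.exp(-0.5 * t)[None, :]
    return GeneExpressionDataset(("A",), grid, values)


@pytest.fixture
def decay_model():
    net = InferredNetwork(("A",))
    params = ModelParameters(alpha={}, beta={}, degradation={"A": 0.5})
    return net, params


# ---------------------------------------------------------------------------
# the shared recovery benchmark: a well-identified 5-gene system fitted once
# at the acceptance scale (pop 60, 200 generations, 10 restarts) and reused
# by every test that needs a good fit
# ---------------------------------------------------------------------------

# strong couplings and a small support keep the sign pattern identifiable
# at the error level a scaled-down GA reaches: weakly coupled benchmarks have
# deep wrong-sign local minima within the fitting tolerance
RECOVERY_SPEC = SyntheticSpec(
    m=5,
    m1=4,
    n1=2,
    noise_sd=0.0,
    seed=4,
    alpha_range=(3.0 / GRID_SPAN, 6.0 / GRID_SPAN),
    beta_range=(3.0 / GRID_SPAN, 6.0 / GRID_SPAN),
    degradation_range=(0.05, 0.2),
    x0_range=(0.3, 3.0),
)

RECOVERY_GA = GAConfig(
    generations=200,
    population=60,
    n_restarts=10,
    top_k=10,
    base_seed=0,
    alpha_bounds=(-6.0 / GRID_SPAN, 6.0 / GRID_SPAN),
    beta_bounds=(-6.0 / GRID_SPAN, 6.0 / GRID_SPAN),
    k_bounds=(0.0, 0.5),
    normalize="none",
    rtol=1e-5,
    atol=1e-7,
)


@pytest.fixture(scope="session")
def recovery_benchmark():
    avg, reps, truth = generate_benchmark(RECOVERY_SPEC)
    return avg, truth


@pytest.fixture(scope="session")
def recovery_fits(recovery_benchmark):
    """Ten-restart GA fit on the true support (slow: several minutes)."""
    avg, truth = recovery_benchmark
    return multi_start(truth.network, avg, RECOVERY_GA)
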