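import numpy as np
import pytest

from fpnet.design import TrialDesign
from fpnet.synth import Coupling, CouplingScenario, Oscillator


@pytest.fixture
def two_node_design() -> TrialDesign:
    """Minimal 1 frontal + 1 parietal layout at the standard trial geometry."""
    return TrialDesign(frontal_nodes=("F1",), parietal_nodes=("P1",))


@pytest.fixture
def theta_pair_scenario() -> CouplingScenario:
    """Theta-tuned pair with the standard 0.4 coupling over 3000-6000 ms."""
    return CouplingScenario(
        couplings=[Coupling("F1", "P1", "theta", (3000.0, 6000.0), 0.4)],
        oscillators={"F1": (Oscillator(6.0, 0.65),), "P1": (Oscillator(6.0, 0.65),)},
        default_oscillators=(),
    )


@pytest.fixture
def null_scenario() -> CouplingScenario:
    """No couplings; independent theta oscillators at every node."""
    return CouplingScenario()


def simulate_stationary_var(coefs: np.ndarray, n_samples: int, seed: int, burn: int = 500) -> np.ndarray:
    """Direct VAR simulation used as an independent data source in tests."""
    coefs = np.asarray(coefs, dtype=float)
    p, n, _ = coefs.shape
    rng = np.random.default_rng(seed)
    total = n_samples + burn
    x = np.zeros((total, n))
    eps = rng.standard_normal((total, n))
    for t in range(p, total):
        acc = eps[t].copy()
        for k in range(p):
            acc += coefs[k] @ x[t - 1 - k]
        x[t] = acc
    return x[burn:].T
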