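import numpy as np
import pytest

from msamd.builder import build_extended, build_ideal_helix
from msamd.simulator import AnnealingSchedule, ConvergenceCriterion, anneal, minimize

ALA11 = "AAAAAAAAAAA"
ALPHA1_SEQ = "ELLKKLLEELKG"


@pytest.fixture(scope="session")
def helix11():
    return build_ideal_helix(ALA11)


@pytest.fixture(scope="session")
def extended11():
    return build_extended(ALA11)


@pytest.fixture(scope="session")
def helix12():
    return build_ideal_helix(ALPHA1_SEQ)


@pytest.fixture(scope="session")
def short_schedule():
    """A very short annealing program for cheap dynamics tests."""
    return AnnealingSchedule(heat_ps=2.0, hold_ps=1.0, cool_ps=2.0,
                             max_production_ps=100.0)


@pytest.fixture(scope="session")
def short_criterion():
    return ConvergenceCriterion(window_ps=10.0, std_threshold=0.2,
                                sample_interval_ps=0.5)


@pytest.fixture(scope="session")
def minimized11():
    return minimize(build_extended(ALA11))


@pytest.fixture(scope="session")
def anneal_outputs(minimized11, short_schedule):
    """50 short annealing outputs of Ala11 — a pool of varied but valid
    simulator conformations reused by round-trip and assignment tests."""
    return [anneal(minimized11, short_schedule, seed=1000 + i) for i in range(50)]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
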