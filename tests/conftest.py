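import numpy as np
import pytest

from diffdcm.dynamics import (DrivingInput, FluctuationSpec, ModelParameters)
from diffdcm.graph import AdjacencyGraph, binarize, normalize_connectome
from diffdcm.synth import gen_connectome, gen_observations, gen_parameters
from diffdcm.dynamics import simulate


@pytest.fixture
def fig1_graph() -> AdjacencyGraph:
    """Three-node path graph: node 0 linked to 1 and 2, no 1-2 edge."""
    w = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    return binarize(normalize_connectome(w), 0.5)


def random_graph(n: int, rng: np.random.Generator,
                 density: float = 0.6) -> AdjacencyGraph:
    """Random binarized graph with at least one edge."""
    while True:
        mask = np.triu(rng.random((n, n)) < density, 1)
        k = (mask | mask.T)
        if k.any():
            w = k.astype(float)
            return binarize(normalize_connectome(w), 0.5)


def make_subject(seed: int, sigma_true: float, n: int = 4, t_samples: int = 600,
                 dt: float = 2.16, snr: float = 10.0,
                 amplitude: float = 0.05, smoothness: float = 0.75):
    """Synthetic resting-state subject used across inversion tests."""
    conn = gen_connectome(n, 0.8, seed=seed)
    graph = binarize(conn, 0.5)
    params = gen_parameters(graph, "stable", sigma_true=sigma_true,
                            seed=seed + 100)
    fluct = FluctuationSpec(amplitude=amplitude, smoothness=smoothness,
                            seed=seed + 200)
    inp = DrivingInput.zeros(1, t_samples, dt)
    traj = simulate(params, graph, inp, np.zeros(n), fluct)
    obs, noise_sd = gen_observations(traj, snr, seed=seed + 300)
    return graph, params, traj, obs


@pytest.fixture
def decay_params() -> ModelParameters:
    return ModelParameters(p=-np.eye(3), sigma=0.0, q=np.zeros((1, 3)))
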