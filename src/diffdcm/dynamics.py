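"""The generalised neuronal state equation and its integration.

The model couples regional drift, graph diffusion, external driving input
and smooth stochastic fluctuations:

    dx_i/dt = sum_j p_ij x_j + sigma * sum_j k_ij (x_i - x_j)
              + sum_j q_ji v_j + omega_i(t)

The diffusion term equals ``sigma * (L @ x)`` with ``L = D - K`` the graph
Laplacian, so the drift matrix of the linear system is ``J = P + sigma L``.
Note the sign convention: the diffusion term enters with ``+sigma L``, which
is *anti*-smoothing (``L`` is positive semidefinite), so a larger diffusion
coefficient is destabilising.  This is deliberate — it is what makes a
*reduction* in diffusivity the stabilising direction.

Integration defaults to the exact one-step discretisation of the linear
system (matrix exponential, inputs held constant over each step);
Euler--Maruyama is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.ndimage import gaussian_filter1d

from .graph import AdjacencyGraph

__all__ = [
    "ModelParameters",
    "DrivingInput",
    "FluctuationSpec",
    "Trajectory",
    "ObservedSeries",
    "drift_diffusion_rhs",
    "drift_matrix",
    "discretize",
    "simulate",
    "observe",
    "minmax_normalize",
]

OVERFLOW_GUARD = 1e9  #: |x| beyond this truncates the trajectory (diverged)


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the generalised state equation.

    Attributes
    ----------
    p : (N, N) array
        Intrinsic coupling matrix (units 1/s); reduces to the classic DCM
        ``A`` matrix when the diffusion coefficient is zero.
    sigma : float
        Diffusion coefficient (1/s); must be nonnegative — it plays the
        role of a rate constant.
    q : (M, N) array
        Extrinsic coupling, ``q[j, i]`` routing input channel ``j`` into
        region ``i``.
    """

    p: np.ndarray
    sigma: float
    q: np.ndarray

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.p, dtype=float))
        q = np.atleast_2d(np.asarray(self.q, dtype=float))
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q)) and np.isfinite(self.sigma)):
            raise ValueError("model parameters must be finite")
        if self.sigma < 0:
            raise ValueError("diffusion coefficient sigma must be nonnegative")
        if p.shape[0] != p.shape[1]:
            raise ValueError("p must be square")
        if q.shape[1] != p.shape[0]:
            raise ValueError("q must have one column per region")

    @property
    def n_regions(self) -> int:
        return self.p.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.q.shape[0]


@dataclass(frozen=True)
class DrivingInput:
    """External driving input: ``M`` channels sampled on a fixed grid."""

    v: np.ndarray
    dt: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.v, dtype=float))
        object.__setattr__(self, "v", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("driving input must be finite")
        if v.shape[1] < 2:
            raise ValueError("driving input needs at least two samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.channel_labels:
            object.__setattr__(self, "channel_labels",
                               [f"input_{i}" for i in range(v.shape[0])])

    @property
    def n_samples(self) -> int:
        return self.v.shape[1]

    @staticmethod
    def zeros(n_channels: int, n_samples: int, dt: float) -> "DrivingInput":
        return DrivingInput(np.zeros((n_channels, n_samples)), dt)

    def resample(self, dt: float, n_samples: int) -> "DrivingInput":
        """Linear interpolation onto a new time grid."""
        t_old = np.arange(self.n_samples) * self.dt
        t_new = np.arange(n_samples) * dt
        v = np.vstack([np.interp(t_new, t_old, row) for row in self.v])
        return DrivingInput(v, dt, list(self.channel_labels))


@dataclass(frozen=True)
class FluctuationSpec:
    """Smooth (non-Markovian) state fluctuations omega.

    Realised as white Gaussian noise convolved with a Gaussian kernel of
    width ``smoothness`` seconds, rescaled so the marginal standard
    deviation equals ``amplitude``.
    """

    amplitude: float = 0.0
    smoothness: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("fluctuation amplitude must be nonnegative")
        if self.smoothness <= 0:
            raise ValueError("fluctuation smoothness must be positive")

    def sample(self, n_regions: int, n_samples: int, dt: float) -> np.ndarray:
        """Draw an (N, T) realisation of omega on the simulation grid."""
        if self.amplitude == 0.0:
            return np.zeros((n_regions, n_samples))
        rng = np.random.default_rng(self.seed)
        white = rng.standard_normal((n_regions, n_samples))
        sd_samples = self.smoothness / dt
        if sd_samples < 1e-6:
            smooth = white
        else:
            smooth = gaussian_filter1d(white, sigma=sd_samples, axis=1, mode="wrap")
            smooth /= smooth.std(axis=1, keepdims=True).clip(1e-12)
        return self.amplitude * smooth


@dataclass(frozen=True)
class Trajectory:
    """Latent states ``x`` (N regions x T samples) on a fixed time grid."""

    x: np.ndarray
    dt: float
    t0: float = 0.0
    diverged: bool = False

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class ObservedSeries:
    """Noisy observations of the latent states (identity mapping + noise)."""

    y: np.ndarray
    dt: float
    normalization: dict | None = None
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        y = np.atleast_2d(np.asarray(self.y, dtype=float))
        object.__setattr__(self, "y", y)
        if not self.region_labels:
            object.__setattr__(self, "region_labels",
                               [f"region_{i}" for i in range(y.shape[0])])

    @property
    def n_regions(self) -> int:
        return self.y.shape[0]

    @property
    def n_samples(self) -> int:
        return self.y.shape[1]


# ---------------------------------------------------------------------------
# Model algebra

def drift_matrix(params: ModelParameters, graph: AdjacencyGraph) -> np.ndarray:
    """System matrix ``J = P + sigma L`` of the linear flow."""
    if params.n_regions != graph.n_regions:
        raise ValueError("parameter and graph dimensions disagree")
    return params.p + params.sigma * graph.laplacian


def drift_diffusion_rhs(x: np.ndarray, v: np.ndarray, params: ModelParameters,
                        graph: AdjacencyGraph) -> np.ndarray:
    """Deterministic part of dx/dt: ``P x + sigma L x + Q^T v``.

    The diffusion term is computed through the Laplacian; it is identical to
    the pairwise-gradient form ``sigma * sum_j k_ij (x_i - x_j)``.
    """
    x = np.asarray(x, dtype=float)
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if x.shape[0] != params.n_regions or x.shape[0] != graph.n_regions:
        raise ValueError("state dimension mismatch")
    if v.shape[0] != params.n_inputs:
        raise ValueError("input dimension mismatch")
    return drift_matrix(params, graph) @ x + params.q.T @ v


def discretize(j: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact one-step discretisation of ``dx/dt = J x + u(t)``.

    Returns ``(A, G)`` with ``A = expm(J dt)`` and
    ``G = int_0^dt expm(J s) ds``, so that for input held constant over a
    step, ``x_{t+1} = A x_t + G u_t``.  Computed jointly via the augmented
    matrix exponential, which is robust when ``J`` is singular.
    """
    n = j.shape[0]
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = j * dt
    aug[:n, n:] = np.eye(n) * dt
    e = expm(aug)
    return e[:n, :n], e[:n, n:]


def simulate(params: ModelParameters, graph: AdjacencyGraph, input: DrivingInput,
             x0: np.ndarray, fluct: FluctuationSpec | None = None,
             method: str = "exact") -> Trajectory:
    """Integrate the generalised state equation.

    Parameters
    ----------
    method : {"exact", "euler"}
        "exact" propagates each step with the matrix exponential of
        ``J dt`` (inputs and fluctuations held constant over the step);
        "euler" uses Euler--Maruyama.

    With zero fluctuation amplitude the result is deterministic; otherwise
    it is reproducible given ``fluct.seed``.  If the state norm exceeds the
    overflow guard the trajectory is truncated and flagged ``diverged``
    rather than raising — unstable systems are a studied behaviour.
    """
    if method not in ("exact", "euler"):
        raise ValueError(f"unknown integration method {method!r}")
    fluct = fluct or FluctuationSpec(0.0)
    n = params.n_regions
    t_steps = input.n_samples
    dt = input.dt
    x0 = np.asarray(x0, dtype=float).reshape(n)

    j = drift_matrix(params, graph)
    u = params.q.T @ input.v + fluct.sample(n, t_steps, dt)  # (N, T) total input

    x = np.empty((n, t_steps))
    x[:, 0] = x0
    if method == "exact":
        a, g = discretize(j, dt)
        step = lambda xc, uc: a @ xc + g @ uc
    else:
        step = lambda xc, uc: xc + dt * (j @ xc + uc)

    diverged = False
    last = t_steps
    for t in range(1, t_steps):
        xn = step(x[:, t - 1], u[:, t - 1])
        if not np.all(np.isfinite(xn)) or np.abs(xn).max() > OVERFLOW_GUARD:
            diverged = True
            last = t
            break
        x[:, t] = xn
    if diverged:
        x = x[:, :last]
    return Trajectory(x=x, dt=dt, diverged=diverged)


def observe(traj: Trajectory, noise_sd: float, seed: int = 0,
            region_labels: list[str] | None = None) -> ObservedSeries:
    """Observe latent states through the identity map plus i.i.d. Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    y = traj.x.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(y.shape)
    return ObservedSeries(y=y, dt=traj.dt, region_labels=list(region_labels or []))


def minmax_normalize(series: ObservedSeries) -> ObservedSeries:
    """Scale each region's series to [0, 1], recording the original range."""
    y = series.y
    lo = y.min(axis=1)
    hi = y.max(axis=1)
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate range: constant row cannot be min-max normalised")
    ynorm = (y - lo[:, None]) / (hi - lo)[:, None]
    return replace(series, y=ynorm,
                   normalization={"min": lo.tolist(), "max": hi.tolist()})


def minmax_rows(arr: np.ndarray) -> np.ndarray:
    """Row-wise min-max scaling of a plain array (constant rows map to 0)."""
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    lo = arr.min(axis=1, keepdims=True)
    rng = arr.max(axis=1, keepdims=True) - lo
    rng[rng == 0] = 1.0
    return (arr - lo) / rng


# ---------------------------------------------------------------------------
# I/O: rows = regions, first column = label, `# dt=...` header comment

def write_series(path, y: np.ndarray, dt: float, labels: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dt={dt}\n")
        pd.DataFrame(np.atleast_2d(y), index=labels).to_csv(fh, sep="\t", header=False)


def read_series(path) -> tuple[np.ndarray, float, list[str]]:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# dt="):
            raise ValueError("series file must start with a '# dt=' header line")
        dt = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    return df.to_numpy(dtype=float), dt, [str(i) for i in df.index]
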