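"""Seeded synthetic data: connectomes, parameters, cohorts, pre-ictal input.

No subject data accompany the method, so every downstream analysis is
exercised on synthetic material that emulates the study conditions: an
8-node "seizure network" (bilateral mid-frontal, mid-frontal orbital,
precuneus and thalamus), BOLD-like series at a repetition time of 2.16 s
with 296 retained volumes, weighted connectomes normalised to a maximum of
1, a two-group cohort whose diffusion coefficients differ by construction
(patients above controls), and a ramping pre-ictal-like driving envelope
normalised to [0, 1].  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dynamics import (DrivingInput, FluctuationSpec, ModelParameters,
                       ObservedSeries, Trajectory, observe, simulate)
from .graph import AdjacencyGraph, WeightedConnectome, binarize, normalize_connectome
from .stability import jacobian

__all__ = [
    "SEIZURE_NETWORK_LABELS",
    "seizure_network_labels",
    "CohortSpec",
    "SubjectBundle",
    "gen_connectome",
    "gen_parameters",
    "gen_preictal",
    "gen_observations",
    "gen_cohort",
    "demo_unstable_fixture",
    "star_fixture",
]

#: The eight regions implicated in generalised spike-and-wave discharges:
#: the four named bilateral regions of the seizure network.
SEIZURE_NETWORK_LABELS = (
    "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Precuneus_L", "Precuneus_R",
    "Thalamus_L", "Thalamus_R",
)


def seizure_network_labels() -> list[str]:
    """Region labels of the 8-node seizure network."""
    return list(SEIZURE_NETWORK_LABELS)


def gen_connectome(n: int, edge_density: float = 0.5, seed: int = 0,
                   labels: list[str] | None = None,
                   ensure_connected_at: float = 0.5) -> WeightedConnectome:
    """Random weighted connectome: log-normal weights on a connected graph.

    The topology is Bernoulli(``edge_density``), redrawn (up to 100
    attempts) until connected.  Present edges carry log-normal weights
    mapped monotonically into ``[ensure_connected_at, 1]`` after
    normalisation, so binarizing at the downstream working threshold
    (default 50 %) recovers exactly the drawn topology — in particular a
    connected graph.  The matrix is symmetric, zero-diagonal, max 1.
    """
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must lie in (0, 1]")
    if not 0 <= ensure_connected_at < 1:
        raise ValueError("ensure_connected_at must lie in [0, 1)")
    for attempt in range(100):
        rng = np.random.default_rng((seed, attempt))
        mask = np.triu(rng.random((n, n)) < edge_density, 1)
        if not mask.any():
            continue
        if not nx.is_connected(nx.from_numpy_array(mask | mask.T)):
            continue
        raw = rng.lognormal(mean=0.0, sigma=0.75, size=int(mask.sum()))
        lo = ensure_connected_at
        span = raw.max() - raw.min()
        scaled = (lo + (1.0 - lo) * (raw - raw.min()) / span if span > 0
                  else np.ones_like(raw))
        w = np.zeros((n, n))
        w[mask] = scaled
        w = w + w.T
        return normalize_connectome(w, labels or
                                    ([] if n != 8 else seizure_network_labels()))
    raise RuntimeError(f"could not draw a connected graph at density {edge_density}")


def gen_parameters(graph: AdjacencyGraph, regime: str = "stable",
                   sigma_true: float = 0.2, seed: int = 0,
                   designated_nodes: tuple[int, ...] = (0, 1),
                   stable_margin: float = 0.05) -> ModelParameters:
    """Ground-truth parameters with a prescribed stability regime.

    Self-couplings are drawn negative; for ``regime="stable"`` they are
    deepened until ``max Re eig(P + sigma L) < -stable_margin``.  For
    ``regime="unstable_subset"`` the designated (seizure-prone) nodes'
    self-couplings are then inflated until the leading real part lies in
    (0.01, 0.1), with the unstable mode loading chiefly on those nodes.
    One input channel is routed to the designated nodes.
    """
    if regime not in ("stable", "unstable_subset"):
        raise ValueError("regime must be 'stable' or 'unstable_subset'")
    if sigma_true < 0:
        raise ValueError("sigma_true must be nonnegative")
    n = graph.n_regions
    rng = np.random.default_rng(seed)
    diag = -np.abs(rng.normal(0.6, 0.1, size=n))
    p = np.diag(diag)
    lap = graph.laplacian

    def lead(pm):
        return float(np.linalg.eigvals(pm + sigma_true * lap).real.max())

    for _ in range(500):
        if lead(p) < -stable_margin:
            break
        p[np.diag_indices(n)] *= 1.2
    else:
        raise RuntimeError("could not reach the stable regime in 500 steps")

    q = np.zeros((1, n))
    for d in designated_nodes:
        q[0, d] = 1.0

    if regime == "unstable_subset":
        # deepen the non-designated self-couplings first so the eventual
        # unstable mode loads chiefly on the designated nodes
        others = [i for i in range(n) if i not in designated_nodes]
        p[others, others] *= 1.5
        bump = np.zeros(n)
        for d in designated_nodes:
            bump[d] = 1.0
        step = 0.05
        delta = 0.0
        for _ in range(500):
            trial = p + np.diag(bump * (delta + step))
            lam = lead(trial)
            if lam >= 0.1:
                step *= 0.5
                continue
            delta += step
            if 0.01 < lam < 0.1:
                p = trial
                break
        else:
            raise RuntimeError("could not reach the unstable_subset regime")

    return ModelParameters(p=p, sigma=float(sigma_true), q=q)


def gen_preictal(duration_s: float, dt: float, seed: int = 0) -> DrivingInput:
    """Pre-ictal-like driving envelope in [0, 1].

    A low, slowly varying baseline with a smoothly ramping oscillatory
    burst occupying the final third of the record (amplitude-modulated
    ~3 Hz oscillation rendered at the requested sampling interval), then
    min-max normalised.  Stands in for the envelope of frontal EEG activity
    leading into a generalised discharge.
    """
    if duration_s < 10 * dt:
        raise ValueError("duration must cover at least 10 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt)
    n = t.size
    baseline = 0.05 * np.abs(np.convolve(rng.standard_normal(n),
                                         np.ones(5) / 5.0, mode="same"))
    onset = duration_s * 2.0 / 3.0
    ramp = np.clip((t - onset) / (duration_s - onset + 1e-12), 0.0, 1.0)
    ramp = ramp * ramp * (3 - 2 * ramp)  # smoothstep
    osc = 0.7 + 0.3 * np.sin(2 * np.pi * 3.0 * t)
    v = baseline + ramp * osc
    v = v - v.min()
    v = v / v.max()
    return DrivingInput(v[None, :], dt, ["preictal"])


def gen_observations(traj: Trajectory, snr: float, seed: int = 0,
                     labels: list[str] | None = None) -> tuple[ObservedSeries, float]:
    """Observe a trajectory at a target signal-to-noise ratio.

    SNR is std(latent)/std(noise) per region, combined by the geometric
    mean; one shared noise standard deviation realises it.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    sds = traj.x.std(axis=1).clip(1e-12)
    noise_sd = float(np.exp(np.mean(np.log(sds)))) / snr
    return observe(traj, noise_sd, seed=seed, region_labels=labels), noise_sd


@dataclass(frozen=True)
class CohortSpec:
    """Two-group synthetic cohort specification.

    Defaults mirror the study conditions: 15 subjects per group, the 8-node
    seizure network, 296 retained volumes at a repetition time of 2.16 s,
    and patients generated with a higher diffusion coefficient than
    controls.
    """

    n_per_group: int = 15
    n_regions: int = 8
    t_samples: int = 296
    dt: float = 2.16
    sigma_patient: float = 0.4
    sigma_control: float = 0.1
    snr: float = 10.0
    seed: int = 0
    edge_density: float = 0.5
    threshold: float = 0.5
    fluct_amplitude: float = 0.05
    fluct_smoothness: float = 1.0

    def __post_init__(self):
        if self.sigma_patient <= self.sigma_control:
            raise ValueError("sigma_patient must exceed sigma_control")
        if self.n_regions < 2:
            raise ValueError("need at least two regions")


@dataclass(frozen=True)
class SubjectBundle:
    subject_id: str
    group: str
    connectome: WeightedConnectome
    graph: AdjacencyGraph
    params: ModelParameters
    trajectory: Trajectory
    observed: ObservedSeries
    sigma_true: float
    noise_sd: float
    seed: int

    def manifest_entry(self) -> dict:
        return {"subject_id": self.subject_id, "group": self.group,
                "sigma_true": self.sigma_true, "noise_sd": self.noise_sd,
                "seed": self.seed,
                "p_diag_true": np.diag(self.params.p).tolist()}


def gen_cohort(spec: CohortSpec) -> list[SubjectBundle]:
    """Generate a two-group cohort of synthetic subjects.

    Each subject gets their own connectome, ground-truth parameters in the
    stable regime (resting-state-like), a simulated latent trajectory
    driven by smooth fluctuations, and noisy observations at the requested
    SNR.  Patients use ``sigma_patient``, controls ``sigma_control``.
    """
    labels = (seizure_network_labels() if spec.n_regions == 8
              else [f"region_{i}" for i in range(spec.n_regions)])
    subjects: list[SubjectBundle] = []
    base = np.random.default_rng(spec.seed).integers(0, 2**31 - 1)
    idx = 0
    for group, sigma in (("patient", spec.sigma_patient),
                         ("control", spec.sigma_control)):
        for k in range(spec.n_per_group):
            sub_seed = int((base + 7919 * idx) % (2**31 - 1))
            conn = gen_connectome(spec.n_regions, spec.edge_density,
                                  seed=sub_seed, labels=labels)
            graph = binarize(conn, spec.threshold)
            params = gen_parameters(graph, "stable", sigma_true=sigma,
                                    seed=sub_seed + 1)
            fluct = FluctuationSpec(amplitude=spec.fluct_amplitude,
                                    smoothness=spec.fluct_smoothness,
                                    seed=sub_seed + 2)
            inp = DrivingInput.zeros(1, spec.t_samples, spec.dt)
            traj = simulate(params, graph, inp, np.zeros(spec.n_regions), fluct)
            obs, noise_sd = gen_observations(traj, spec.snr, seed=sub_seed + 3,
                                             labels=labels)
            subjects.append(SubjectBundle(
                subject_id=f"{group}_{k:02d}", group=group, connectome=conn,
                graph=graph, params=params, trajectory=traj, observed=obs,
                sigma_true=sigma, noise_sd=noise_sd, seed=sub_seed))
            idx += 1
    return subjects


# ---------------------------------------------------------------------------
# Shipped intervention fixtures (constructed, deterministic)

def demo_unstable_fixture(t_samples: int = 300, dt: float = 2.16):
    """Unstable 8-node system whose instability lives in the gradients.

    Homogeneous self-coupling ``p0 = -0.2`` on a complete graph with
    diffusion coefficient chosen so every non-uniform Laplacian mode grows
    slowly (leading real part ~0.012/s) while the uniform mode stays
    stable.  Driving the two mid-frontal targets alone excites the unstable
    non-uniform modes; perfect mirroring makes the input uniform across
    nodes, leaving only the stable uniform mode excited — the geometry that
    makes gradient-minimising stimulation maximally effective.

    Returns ``(params, graph, preictal, cfg)``.
    """
    labels = seizure_network_labels()
    n = 8
    w = np.ones((n, n)) - np.eye(n)
    conn = normalize_connectome(w, labels)
    graph = binarize(conn, 0.5)
    p0 = -0.2
    sigma = 0.0265  # leading rate p0 + 8*sigma = +0.012 per second
    q = np.zeros((1, n))
    q[0, 0] = q[0, 1] = 1.0
    params = ModelParameters(p=p0 * np.eye(n), sigma=sigma, q=q)
    assert not jacobian(params, graph).stable
    preictal = gen_preictal(t_samples * dt, dt, seed=42)
    from .intervention import InterventionConfig
    cfg = InterventionConfig(target_nodes=(0, 1),
                             stimulated_nodes=tuple(range(2, n)),
                             n_models=1000)
    return params, graph, preictal, cfg


def star_fixture(t_samples: int = 150, dt: float = 1.0):
    """Five-node fixture where exactly one node couples to the target.

    Node 0 is the driven target; node 1 is its sole structural neighbour;
    nodes 2--4 are isolated.  The only instability is the antisymmetric
    diffusion mode on the (0, 1) edge, so stimulating node 1 can suppress
    the target while stimulating any isolated node cannot (N/A).

    Returns ``(params, graph, preictal, cfg)``.
    """
    n = 5
    k = np.zeros((n, n), dtype=np.int64)
    k[0, 1] = k[1, 0] = 1
    d = k.sum(axis=1)
    graph = AdjacencyGraph(k=k, d=d, laplacian=np.diag(d) - k, threshold=0.5,
                           region_labels=[f"node_{i}" for i in range(n)])
    p = -0.05 * np.eye(n)
    sigma = 0.05  # antisymmetric (0,1) mode rate: -0.05 + 2*sigma = +0.05
    q = np.zeros((1, n))
    q[0, 0] = 1.0
    params = ModelParameters(p=p, sigma=sigma, q=q)
    assert not jacobian(params, graph).stable
    preictal = gen_preictal(t_samples * dt, dt, seed=7)
    from .intervention import InterventionConfig
    cfg = InterventionConfig(target_nodes=(0,),
                             stimulated_nodes=(1, 2, 3, 4),
                             n_models=200)
    return params, graph, preictal, cfg
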