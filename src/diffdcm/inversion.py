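"""Variational Bayesian inversion of the graph-diffusive state-space model.

The generative model is linear-Gaussian once discretised, so inference uses
the standard exact machinery for that class: the marginal likelihood of the
observations given parameters is computed by a Kalman filter (latent states
integrated out analytically), parameters and the two noise log-precisions
are optimised to maximise the log-joint under Gaussian priors, and the
posterior is the Laplace (Gaussian) approximation at the optimum.  Latent
states are recovered by Rauch--Tung--Striebel smoothing at the posterior
mean.  The variational free energy

    F = <log p(d | theta, m)>_q  -  KL[q(theta), p(theta | m)]
        (accuracy)                  (complexity)

is evaluated under the Laplace posterior; it is the quantity used for model
comparison downstream.

The number of free parameters is kept well below the number of time points
(about a tenth) by *functional-connectivity priors*: all self-coupling
terms are free, but off-diagonal couplings are freed only for the region
pairs with the strongest empirical correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from ._kalman import kalman_loglik, kalman_smooth
from .dynamics import DrivingInput, ObservedSeries, discretize
from .graph import AdjacencyGraph

__all__ = [
    "PriorSpec",
    "PosteriorDensity",
    "InversionSettings",
    "build_fc_priors",
    "invert",
    "free_energy",
    "group_average",
    "DiffusionDCM",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Priors

@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors over the free parameters of the model.

    Parameter names follow a fixed layout: ``p[i,j]`` entries (diagonal
    first, then the selected off-diagonal pairs), ``sigma``, ``q[j,i]``
    entries, then the two noise log-precisions ``lambda_x`` (state
    fluctuations) and ``lambda_y`` (observation noise).  A zero prior
    variance fixes the parameter at its prior mean.

    ``sigma_scale`` selects the parameterisation of the diffusion
    coefficient: "natural" (default; the value itself, which keeps the
    sigma = 0 reduction inside the parameter space for Bayesian model
    reduction) or "log" (strict positivity).
    """

    n_regions: int
    names: list[str]
    mean: np.ndarray
    variance: np.ndarray
    free_mask_p: np.ndarray          # (N, N) bool
    free_mask_q: np.ndarray          # (M, N) bool
    sigma_free: bool = True
    sigma_scale: str = "natural"
    n_inputs: int = 0

    def __post_init__(self):
        if self.sigma_scale not in ("natural", "log"):
            raise ValueError("sigma_scale must be 'natural' or 'log'")
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be nonnegative")

    @property
    def n_parameters(self) -> int:
        return len(self.names)

    @property
    def free(self) -> np.ndarray:
        """Boolean mask of parameters with nonzero prior variance."""
        return self.variance > 0

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def with_sigma_fixed(self, value: float = 0.0) -> "PriorSpec":
        """Prior with the diffusion coefficient pinned (variance zero)."""
        i = self.index_of("sigma")
        mean = self.mean.copy()
        var = self.variance.copy()
        mean[i] = value
        var[i] = 0.0
        return replace(self, mean=mean, variance=var, sigma_free=False)


def build_fc_priors(y: ObservedSeries, graph: AdjacencyGraph, max_free: int,
                    input_regions: list[int] | None = None,
                    sigma_scale: str = "natural",
                    sigma_prior_mean: float = 0.1,
                    timepoint_rule: str = "warn") -> PriorSpec:
    """Construct functional-connectivity priors for the coupling matrix.

    All ``N`` self-couplings are free (prior mean -0.5 1/s, variance 1).
    Off-diagonal couplings are freed in symmetric pairs, ranked by the
    absolute Pearson correlation between the corresponding rows of ``y``,
    until the total number of free ``p`` entries reaches ``max_free``.  The
    diffusion coefficient is free (prior mean ``sigma_prior_mean``,
    variance 1); extrinsic couplings ``q`` are freed only for the
    designated input-receiving regions.  Noise log-precisions carry
    N(3, 16) hyperpriors.

    ``timepoint_rule`` controls the "roughly ten time points per free
    parameter" budget: "warn" trims the off-diagonal selection with a
    warning, "error" raises, "ignore" skips the check.
    """
    n = graph.n_regions
    if y.n_regions != n:
        raise ValueError("series and graph dimensions disagree")
    if max_free < n:
        raise ValueError(f"max_free must be at least N={n} (diagonal is always free)")
    if timepoint_rule not in ("warn", "error", "ignore"):
        raise ValueError("timepoint_rule must be 'warn', 'error' or 'ignore'")

    input_regions = list(input_regions or [])
    n_inputs = 1 if input_regions else 0

    budget = max_free
    if timepoint_rule != "ignore":
        cap = y.n_samples // 10 - (1 + len(input_regions))  # sigma + q share the budget
        if budget > cap:
            msg = (f"free-parameter budget {budget} exceeds ~T/10 rule "
                   f"(T={y.n_samples}); capped at {cap}")
            if timepoint_rule == "error":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            budget = cap
    if budget < n:
        raise ValueError("time-point budget cannot accommodate the diagonal")

    # rank off-diagonal pairs by |Pearson r| between observed rows
    yc = y.y - y.y.mean(axis=1, keepdims=True)
    sd = yc.std(axis=1).clip(1e-12)
    corr = (yc @ yc.T) / (y.n_samples * np.outer(sd, sd))
    pairs = [(abs(corr[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    free_p = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(free_p, True)
    used = n
    for _, i, j in pairs:
        if used + 2 > budget:
            break
        free_p[i, j] = free_p[j, i] = True
        used += 2

    free_q = np.zeros((n_inputs, n), dtype=bool)
    for r in input_regions:
        free_q[0, r] = True

    names: list[str] = []
    mean: list[float] = []
    var: list[float] = []
    for i in range(n):
        names.append(f"p[{i},{i}]")
        mean.append(-0.5)
        var.append(1.0)
    for i in range(n):
        for j in range(n):
            if i != j and free_p[i, j]:
                names.append(f"p[{i},{j}]")
                mean.append(0.0)
                var.append(1.0)
    names.append("sigma")
    if sigma_scale == "log":
        mean.append(float(np.log(sigma_prior_mean)))
    else:
        mean.append(float(sigma_prior_mean))
    var.append(1.0)
    for j in range(n_inputs):
        for i in range(n):
            if free_q[j, i]:
                names.append(f"q[{j},{i}]")
                mean.append(0.5)
                var.append(1.0)
    names += ["lambda_x", "lambda_y"]
    mean += [3.0, 3.0]
    var += [16.0, 16.0]

    return PriorSpec(n_regions=n, names=names, mean=np.array(mean),
                     variance=np.array(var), free_mask_p=free_p,
                     free_mask_q=free_q, sigma_free=True,
                     sigma_scale=sigma_scale, n_inputs=n_inputs)


# ---------------------------------------------------------------------------
# Posterior container

@dataclass(frozen=True)
class PosteriorDensity:
    """Gaussian posterior over the free parameters, with free energy."""

    names: list[str]
    mean: np.ndarray
    covariance: np.ndarray
    free_energy: float
    accuracy: float
    complexity: float
    hyper_posterior: dict
    trajectory_estimate: np.ndarray | None
    convergence: dict
    priors: PriorSpec

    def __post_init__(self):
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")

    def param(self, name: str) -> tuple[float, float]:
        """Posterior (mean, variance) of one named parameter."""
        i = self.names.index(name)
        return float(self.mean[i]), float(self.covariance[i, i])

    @property
    def sigma_posterior(self) -> tuple[float, float]:
        """Posterior (mean, variance) of sigma on the natural scale.

        Under the log parameterisation the natural-scale moments follow by
        the delta method.
        """
        m, v = self.param("sigma")
        if self.priors.sigma_scale == "log":
            return float(np.exp(m)), float(np.exp(2 * m) * v)
        return m, v

    @property
    def p_mean(self) -> np.ndarray:
        """Posterior-mean intrinsic coupling matrix."""
        n = self.priors.n_regions
        p = np.zeros((n, n))
        for k, name in enumerate(self.names):
            if name.startswith("p["):
                i, j = map(int, name[2:-1].split(","))
                p[i, j] = self.mean[k]
        return p


@dataclass(frozen=True)
class InversionSettings:
    max_iter: int = 128
    f_tol: float = 1e-4
    demean: bool = True
    state_prior_var: float = 1.0
    hessian_step: float = 1e-3
    seed: int = 0
    n_restarts: int = 3
    restart_jitter: float = 0.25


# ---------------------------------------------------------------------------
# Likelihood machinery

class _Model:
    """Maps a parameter vector to the discretised state space and its likelihood."""

    def __init__(self, y: ObservedSeries, input: DrivingInput | None,
                 graph: AdjacencyGraph, priors: PriorSpec,
                 settings: InversionSettings):
        if not np.all(np.isfinite(y.y)):
            raise ValueError("observed series contains non-finite values")
        self.priors = priors
        self.graph = graph
        self.settings = settings
        self.n = graph.n_regions
        self.dt = y.dt
        self.yd = y.y - y.y.mean(axis=1, keepdims=True) if settings.demean else y.y
        if input is not None:
            if input.n_samples != y.n_samples:
                raise ValueError("input and series must share the time grid")
            self.v = input.v
        else:
            self.v = None
        # index bookkeeping over the *free* subset
        self.free_idx = np.flatnonzero(priors.free)
        self.fixed_idx = np.flatnonzero(~priors.free)
        self._p_entries = []
        for k, name in enumerate(priors.names):
            if name.startswith("p["):
                i, j = map(int, name[2:-1].split(","))
                self._p_entries.append((k, i, j))
        self._q_entries = []
        for k, name in enumerate(priors.names):
            if name.startswith("q["):
                j, i = map(int, name[2:-1].split(","))
                self._q_entries.append((k, j, i))
        self.k_sigma = priors.index_of("sigma")
        self.k_lx = priors.index_of("lambda_x")
        self.k_ly = priors.index_of("lambda_y")

    # -- parameter plumbing -------------------------------------------------
    def full_theta(self, theta_free: np.ndarray) -> np.ndarray:
        th = self.priors.mean.copy()
        th[self.free_idx] = theta_free
        return th

    def unpack(self, th: np.ndarray):
        n = self.n
        p = np.zeros((n, n))
        for k, i, j in self._p_entries:
            p[i, j] = th[k]
        sigma = th[self.k_sigma]
        if self.priors.sigma_scale == "log":
            sigma = np.exp(sigma)
        q = np.zeros((self.priors.n_inputs, n))
        for k, j, i in self._q_entries:
            q[j, i] = th[k]
        return p, sigma, q, th[self.k_lx], th[self.k_ly]

    # -- densities ----------------------------------------------------------
    def loglik(self, theta_free: np.ndarray) -> float:
        th = self.full_theta(theta_free)
        p, sigma, q, lx, ly = self.unpack(th)
        j = p + sigma * self.graph.laplacian
        # reject steps where the one-step propagator overflows
        if np.abs(j).max() * self.dt > 200.0:
            return -1e12
        a, g = discretize(j, self.dt)
        if not np.all(np.isfinite(a)) or np.abs(a).max() > 1e8:
            return -1e12
        if self.v is not None and q.size:
            b = g @ (q.T @ self.v)
        else:
            b = np.zeros_like(self.yd)
        qn = float(np.exp(-lx))
        rn = float(np.exp(-ly))
        if not (1e-14 < qn < 1e6 and 1e-14 < rn < 1e6):
            return -1e12
        # fluctuations enter through the one-step input integral G, so the
        # discrete process-noise covariance is G G^T scaled by their variance
        qcov = qn * (g @ g.T) + 1e-12 * np.eye(self.n)
        try:
            ll = kalman_loglik(a, b, qcov, rn, self.yd,
                               p0=self.settings.state_prior_var)
        except np.linalg.LinAlgError:
            return -1e12
        return ll if np.isfinite(ll) else -1e12

    def log_prior(self, theta_free: np.ndarray) -> float:
        mu = self.priors.mean[self.free_idx]
        var = self.priors.variance[self.free_idx]
        d = theta_free - mu
        return float(-0.5 * np.sum(d * d / var)
                     - 0.5 * np.sum(np.log(2 * np.pi * var)))

    def neg_log_joint(self, theta_free: np.ndarray) -> float:
        return -(self.loglik(theta_free) + self.log_prior(theta_free))

    def smoothed_states(self, theta_free: np.ndarray) -> np.ndarray:
        th = self.full_theta(theta_free)
        p, sigma, q, lx, ly = self.unpack(th)
        a, g = discretize(p + sigma * self.graph.laplacian, self.dt)
        if self.v is not None and q.size:
            b = g @ (q.T @ self.v)
        else:
            b = np.zeros_like(self.yd)
        qcov = float(np.exp(-lx)) * (g @ g.T) + 1e-12 * np.eye(self.n)
        return kalman_smooth(a, b, qcov, float(np.exp(-ly)),
                             self.yd, p0=self.settings.state_prior_var)


def _fd_hessian(fn, x: np.ndarray, step: float) -> np.ndarray:
    """Central finite-difference Hessian."""
    n = x.size
    h = step * np.maximum(1.0, np.abs(x))
    hess = np.empty((n, n))
    f0 = fn(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = fn(x + e)
        fm[i] = fn(x - e)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fn(x + ei + ej)
            fmm = fn(x - ei - ej)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    return hess


def _spd_inverse(h: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Inverse of a symmetrised matrix with an eigenvalue floor."""
    h = 0.5 * (h + h.T)
    w, vmat = np.linalg.eigh(h)
    w = np.maximum(w, floor)
    return (vmat / w) @ vmat.T


def _gaussian_kl(mu_q, cov_q, mu_p, var_p) -> float:
    """KL[q || p] with diagonal Gaussian p."""
    k = mu_q.size
    d = mu_q - mu_p
    tr = float(np.sum(np.diag(cov_q) / var_p))
    mah = float(np.sum(d * d / var_p))
    _, logdet_q = np.linalg.slogdet(cov_q)
    logdet_p = float(np.sum(np.log(var_p)))
    return 0.5 * (tr + mah - k + logdet_p - logdet_q)


def invert(y: ObservedSeries, input: DrivingInput | None, graph: AdjacencyGraph,
           priors: PriorSpec, settings: InversionSettings | None = None
           ) -> PosteriorDensity:
    """Fit the model by maximising the variational free energy.

    The log-joint (log likelihood from the Kalman filter plus Gaussian log
    prior) is maximised by L-BFGS with monotone line search; the posterior
    covariance is the inverse finite-difference Hessian at the optimum
    (Laplace approximation), with free energy decomposed into accuracy and
    complexity.  With no free parameters (all prior variances zero) the
    posterior equals the prior and F reduces to the accuracy term.
    """
    settings = settings or InversionSettings()
    model = _Model(y, input, graph, priors, settings)
    free = model.free_idx
    mu0 = priors.mean[free]
    var0 = priors.variance[free]

    if free.size == 0:
        ll = model.loglik(np.empty(0))
        return PosteriorDensity(
            names=list(priors.names), mean=priors.mean.copy(),
            covariance=np.zeros((0, 0)), free_energy=ll, accuracy=ll,
            complexity=0.0, hyper_posterior=_hyper_summary(priors, priors.mean,
                                                           np.zeros(len(priors.names))),
            trajectory_estimate=model.smoothed_states(np.empty(0)),
            convergence={"iterations": 0, "delta_f": 0.0, "converged": True},
            priors=priors)

    rng = np.random.default_rng(settings.seed)
    # data-driven starting point for the noise log-precisions: observation
    # noise guessed at a fifth of the data scale, state noise at the scale
    # the flow integral imparts per step
    x_init = mu0.copy()
    data_sd = float(np.exp(np.mean(np.log(model.yd.std(axis=1).clip(1e-9)))))
    for name, guess in (("lambda_y", -2.0 * np.log(0.2 * data_sd)),
                        ("lambda_x", -2.0 * np.log(max(data_sd / max(y.dt, 1e-3),
                                                       1e-9)))):
        k = priors.index_of(name)
        pos = np.flatnonzero(free == k)
        if pos.size:
            x_init[pos[0]] = guess

    best = None
    for restart in range(max(1, settings.n_restarts)):
        x0 = x_init.copy()
        if restart > 0:
            x0 = x0 + settings.restart_jitter * np.sqrt(var0) * rng.standard_normal(x0.size)
        trace: list[float] = []
        res = minimize(model.neg_log_joint, x0, method="L-BFGS-B",
                       callback=lambda xk: trace.append(-model.neg_log_joint(xk)),
                       options={"maxiter": settings.max_iter,
                                "ftol": settings.f_tol * 1e-4,
                                "maxcor": 20})
        if best is None or res.fun < best[0].fun:
            best = (res, trace)
        # retry from a jittered start only if the fit never left the
        # overflow-penalty plateau
        if best[0].fun < 1e11:
            break
    res, trace = best

    theta = res.x
    hess = _fd_hessian(model.neg_log_joint, theta, settings.hessian_step)
    cov = _spd_inverse(hess)

    ll_map = model.loglik(theta)
    kl = _gaussian_kl(theta, cov, mu0, var0)
    # <log p(d|theta)>_q to second order: ll(mu) + 0.5 tr(cov @ H_ll),
    # with H_ll recovered from the joint Hessian minus the prior precision.
    h_ll = -(hess - np.diag(1.0 / var0))
    accuracy = ll_map + 0.5 * float(np.sum(cov * h_ll))
    f = accuracy - kl

    delta_f = abs(trace[-1] - trace[-2]) if len(trace) >= 2 else 0.0
    converged = bool(res.success or res.status == 0 or delta_f < settings.f_tol)

    full_mean = model.full_theta(theta)
    full_cov = np.zeros((len(priors.names), len(priors.names)))
    full_cov[np.ix_(free, free)] = cov

    return PosteriorDensity(
        names=list(priors.names), mean=full_mean, covariance=full_cov,
        free_energy=float(f), accuracy=float(accuracy), complexity=float(kl),
        hyper_posterior=_hyper_summary(priors, full_mean, np.diag(full_cov)),
        trajectory_estimate=model.smoothed_states(theta),
        convergence={"iterations": int(res.nit), "delta_f": float(delta_f),
                     "converged": converged, "f_trace": [float(v) for v in trace]},
        priors=priors)


def _hyper_summary(priors: PriorSpec, mean: np.ndarray, var_diag: np.ndarray) -> dict:
    out = {}
    for name in ("lambda_x", "lambda_y"):
        i = priors.index_of(name)
        out[name] = {"mean": float(mean[i]), "variance": float(var_diag[i])}
    return out


def free_energy(y: ObservedSeries, input: DrivingInput | None,
                graph: AdjacencyGraph, posterior: PosteriorDensity,
                priors: PriorSpec,
                settings: InversionSettings | None = None
                ) -> tuple[float, float, float]:
    """Evaluate (F, accuracy, complexity) for a given Gaussian posterior.

    Accuracy is the posterior expectation of the log likelihood (second
    order around the posterior mean); complexity is the Gaussian KL from
    prior to posterior, which vanishes exactly when the posterior equals
    the prior.
    """
    settings = settings or InversionSettings()
    model = _Model(y, input, graph, priors, settings)
    free = model.free_idx
    theta = posterior.mean[free]
    cov = posterior.covariance[np.ix_(free, free)]
    if free.size == 0:
        ll = model.loglik(theta)
        return ll, ll, 0.0
    sign, _ = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("posterior covariance is singular")
    mu0 = priors.mean[free]
    var0 = priors.variance[free]
    kl = _gaussian_kl(theta, cov, mu0, var0)
    hess = _fd_hessian(model.neg_log_joint, theta, settings.hessian_step)
    h_ll = -(hess - np.diag(1.0 / var0))
    accuracy = model.loglik(theta) + 0.5 * float(np.sum(cov * h_ll))
    return float(accuracy - kl), float(accuracy), float(kl)


def group_average(posteriors: list[PosteriorDensity]) -> PosteriorDensity:
    """Fixed-effects Bayesian averaging of subject posteriors.

    Precisions add, means are precision-weighted, and the group free energy
    is the sum of member free energies (log evidences multiply).
    """
    if not posteriors:
        raise ValueError("need at least one posterior")
    names = posteriors[0].names
    for p in posteriors[1:]:
        if p.names != names:
            raise ValueError("posteriors are over different parameter sets")
    free = np.flatnonzero(posteriors[0].priors.free)
    prec = np.zeros((free.size, free.size))
    pm = np.zeros(free.size)
    for p in posteriors:
        cov = p.covariance[np.ix_(free, free)]
        lam = _spd_inverse(cov)
        prec += lam
        pm += lam @ p.mean[free]
    cov_g = _spd_inverse(prec)
    mu_g_free = cov_g @ pm
    mu_g = posteriors[0].priors.mean.copy()
    mu_g[free] = mu_g_free
    cov_full = np.zeros((len(names), len(names)))
    cov_full[np.ix_(free, free)] = cov_g
    f = float(sum(p.free_energy for p in posteriors))
    acc = float(sum(p.accuracy for p in posteriors))
    kl = float(sum(p.complexity for p in posteriors))
    return PosteriorDensity(
        names=list(names), mean=mu_g, covariance=cov_full, free_energy=f,
        accuracy=acc, complexity=kl,
        hyper_posterior=_hyper_summary(posteriors[0].priors, mu_g, np.diag(cov_full)),
        trajectory_estimate=None,
        convergence={"iterations": 0, "delta_f": 0.0, "converged": True},
        priors=posteriors[0].priors)


# ---------------------------------------------------------------------------
# scikit-learn style front end

class DiffusionDCM(BaseEstimator):
    """Graph-diffusive DCM estimator with a scikit-learn interface.

    Parameters
    ----------
    graph : AdjacencyGraph
        Binarized structural connectivity defining the Laplacian.
    dt : float
        Sampling interval of the series in seconds.
    max_free : int or None
        Budget of free intrinsic-coupling entries for the
        functional-connectivity priors; defaults to ``N + 6`` (diagonal
        plus three correlation-ranked pairs), capped by the time-point rule.
    input_regions : list of int or None
        Regions receiving the external driving input (frees their ``q``).
    sigma_scale : {"natural", "log"}
        Parameterisation of the diffusion coefficient.

    Attributes
    ----------
    posterior_ : PosteriorDensity
    free_energy_ : float
    sigma_ : float
        Posterior mean of the diffusion coefficient (natural scale).
    states_ : ndarray of shape (N, T)
        Smoothed latent-state estimates.
    """

    def __init__(self, graph: AdjacencyGraph | None = None, dt: float = 2.16,
                 max_free: int | None = None,
                 input_regions: list[int] | None = None,
                 sigma_scale: str = "natural", max_iter: int = 128,
                 demean: bool = True, seed: int = 0):
        self.graph = graph
        self.dt = dt
        self.max_free = max_free
        self.input_regions = input_regions
        self.sigma_scale = sigma_scale
        self.max_iter = max_iter
        self.demean = demean
        self.seed = seed

    def fit(self, X, y=None, U=None):
        """Fit the model to a multivariate series.

        ``X`` is (T, N) in scikit-learn orientation (samples by regions) or
        an :class:`ObservedSeries`.  ``U`` optionally carries the driving
        input as a :class:`DrivingInput` or (T, M) array.
        """
        if self.graph is None:
            raise ValueError("graph must be provided")
        if isinstance(X, ObservedSeries):
            series = X
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            series = ObservedSeries(y=X.T, dt=self.dt)
        if U is not None and not isinstance(U, DrivingInput):
            U = DrivingInput(np.asarray(U, dtype=float).T, series.dt)
        max_free = self.max_free if self.max_free is not None \
            else self.graph.n_regions + 6
        priors = build_fc_priors(series, self.graph, max_free=max_free,
                                 input_regions=self.input_regions,
                                 sigma_scale=self.sigma_scale)
        settings = InversionSettings(max_iter=self.max_iter,
                                     demean=self.demean, seed=self.seed)
        post = invert(series, U, self.graph, priors, settings)
        self.priors_ = priors
        self.posterior_ = post
        self.free_energy_ = post.free_energy
        self.sigma_ = post.sigma_posterior[0]
        self.states_ = post.trajectory_estimate
        self.n_iter_ = post.convergence["iterations"]
        return self

    def score(self, X=None, y=None):
        """Variational free energy of the fitted model."""
        if not hasattr(self, "posterior_"):
            raise ValueError("estimator is not fitted")
        return self.free_energy_
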