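"""Bayesian model reduction: scoring the non-diffusive model (sigma = 0).

Given the Gaussian posterior and prior of the full model, the evidence of
any model that differs only in its (Gaussian) prior follows analytically —
no refitting.  The reduced model of interest pins the diffusion
coefficient at zero by collapsing its prior to a point mass, realised
numerically as a tiny prior variance.  The log Bayes factor
``F(sigma = 0) - F(sigma != 0)`` then scores non-diffusivity against
diffusivity, and free energies are mapped to model probabilities by a
softmax (the standard posterior-probability transform over log
evidences, invariant to the arbitrary additive constant in F).  The naive
ratio ``F_1 / (F_1 + F_2)`` is available behind a flag for strict
reproduction of the printed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import PosteriorDensity, PriorSpec

__all__ = ["ReductionResult", "reduce_sigma", "model_probabilities",
           "bmr_gaussian"]

_POINT_MASS_VAR = 1e-12


@dataclass(frozen=True)
class ReductionResult:
    f_full: float
    f_reduced: float
    log_bayes_factor: float       # F(sigma=0) - F(sigma!=0)
    prob_reduced: float
    prob_full: float
    reduced_posterior_sigma: tuple[float, float]  # (mean, variance)


def bmr_gaussian(mu_post: np.ndarray, cov_post: np.ndarray,
                 mu_prior: np.ndarray, cov_prior: np.ndarray,
                 mu_rprior: np.ndarray, cov_rprior: np.ndarray
                 ) -> tuple[float, np.ndarray, np.ndarray]:
    """Change in log evidence and reduced posterior under a new prior.

    Returns ``(delta_f, mu_reduced, cov_reduced)`` where ``delta_f`` is
    ``F_reduced - F_full``.  All densities are Gaussian; ``cov_prior`` and
    ``cov_rprior`` may be passed as 1-D variance vectors.
    """
    def as_prec(c):
        c = np.asarray(c, dtype=float)
        if c.ndim == 1:
            return np.diag(1.0 / c)
        return np.linalg.inv(c)

    pi_post = np.linalg.inv(cov_post)
    pi_0 = as_prec(cov_prior)
    pi_r0 = as_prec(cov_rprior)
    pi_red = pi_post + pi_r0 - pi_0
    w, _ = np.linalg.eigh(0.5 * (pi_red + pi_red.T))
    if w.min() <= 0:
        raise ValueError("numerically singular reduction: reduced precision "
                         f"has min eigenvalue {w.min():.3e}")
    cov_red = np.linalg.inv(pi_red)
    h = pi_post @ mu_post + pi_r0 @ mu_rprior - pi_0 @ mu_prior
    mu_red = cov_red @ h

    def logdet(m):
        sign, ld = np.linalg.slogdet(m)
        if sign <= 0:
            raise ValueError("numerically singular reduction (log-determinant)")
        return ld

    delta_f = 0.5 * (logdet(pi_post) - logdet(pi_red)
                     + logdet(pi_r0) - logdet(pi_0))
    delta_f += 0.5 * (mu_red @ pi_red @ mu_red
                      - mu_post @ pi_post @ mu_post
                      + mu_prior @ pi_0 @ mu_prior
                      - mu_rprior @ pi_r0 @ mu_rprior)
    return float(delta_f), mu_red, cov_red


def reduce_sigma(posterior: PosteriorDensity, priors: PriorSpec | None = None,
                 mode: str = "softmax") -> ReductionResult:
    """Score the reduced model with the diffusion coefficient pinned at zero.

    The reduced prior keeps every other parameter's prior untouched and
    replaces sigma's with a point mass at zero (variance ``1e-12``).
    Requires sigma to be a free parameter under the natural-scale
    parameterisation (sigma = 0 lies outside the log-scale space).
    """
    priors = priors or posterior.priors
    if priors.sigma_scale != "natural":
        raise ValueError("sigma = 0 reduction requires the natural-scale "
                         "parameterisation of sigma")
    k_sigma_all = priors.index_of("sigma")
    if priors.variance[k_sigma_all] <= 0:
        raise ValueError("sigma is not a free parameter; nothing to reduce")

    free = np.flatnonzero(priors.free)
    k_sigma = int(np.flatnonzero(free == k_sigma_all)[0])
    mu_post = posterior.mean[free]
    cov_post = posterior.covariance[np.ix_(free, free)]
    mu_prior = priors.mean[free]
    var_prior = priors.variance[free]
    mu_rprior = mu_prior.copy()
    mu_rprior[k_sigma] = 0.0
    var_rprior = var_prior.copy()
    var_rprior[k_sigma] = _POINT_MASS_VAR

    delta_f, mu_red, cov_red = bmr_gaussian(mu_post, cov_post, mu_prior,
                                            var_prior, mu_rprior, var_rprior)
    f_full = float(posterior.free_energy)
    f_reduced = f_full + delta_f
    probs = model_probabilities([f_reduced, f_full], mode=mode)
    return ReductionResult(
        f_full=f_full, f_reduced=f_reduced, log_bayes_factor=float(delta_f),
        prob_reduced=float(probs[0]), prob_full=float(probs[1]),
        reduced_posterior_sigma=(float(mu_red[k_sigma]),
                                 float(cov_red[k_sigma, k_sigma])))


def model_probabilities(f_values, mode: str = "softmax") -> np.ndarray:
    """Convert free energies (log evidences) to model probabilities.

    "softmax" exponentiates relative to the maximum and normalises —
    invariant to adding a constant to every F.  "ratio" divides each F by
    the sum, reproducing the printed normalisation; it is not
    shift-invariant and is provided for comparison only.
    """
    f = np.asarray(f_values, dtype=float)
    if f.size < 2:
        raise ValueError("need at least two free energies")
    if not np.all(np.isfinite(f)):
        raise ValueError("free energies must be finite")
    if mode == "softmax":
        e = np.exp(f - f.max())
        return e / e.sum()
    if mode == "ratio":
        return f / f.sum()
    raise ValueError("mode must be 'softmax' or 'ratio'")
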