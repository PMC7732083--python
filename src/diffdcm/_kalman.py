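"""Kalman filtering/smoothing for the discretised linear-Gaussian model.

State space:  x_{t+1} = A x_t + b_t + w_t,  w_t ~ N(0, Q)
Observation:  y_t = x_t + e_t,              e_t ~ N(0, r I)

``Q`` is a full covariance: the fluctuations enter the states through the
one-step input integral of the flow, so their discrete covariance is
spatially structured, not isotropic.

The observation map is the identity (the model observes the latent states
directly, up to additive noise), which keeps the filter compact.  The hot
loops are jitted with numba when available; the pure-numpy fallbacks have
identical semantics.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return wrap

_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _filter_loglik(a, b, q, r, y, m0, p0):
    n, t_steps = y.shape
    eye = np.eye(n)
    m = m0.copy()
    p = p0 * np.eye(n)
    ll = 0.0
    for t in range(t_steps):
        s = p + r * eye
        cf = np.linalg.cholesky(s)
        innov = y[:, t] - m
        sol = np.linalg.solve(s, innov)
        logdet = 0.0
        for i in range(n):
            logdet += 2.0 * np.log(cf[i, i])
        ll += -0.5 * (n * _LOG2PI + logdet + innov @ sol)
        gain = np.linalg.solve(s, p).T  # K = P S^{-1}
        m = m + gain @ innov
        p = p - gain @ p
        p = 0.5 * (p + p.T)
        if t < t_steps - 1:
            m = a @ m + b[:, t]
            p = a @ p @ a.T + q
            p = 0.5 * (p + p.T)
    return ll


@njit(cache=True)
def _filter_store(a, b, q, r, y, m0, p0):
    n, t_steps = y.shape
    eye = np.eye(n)
    mf = np.zeros((t_steps, n))
    pf = np.zeros((t_steps, n, n))
    mp = np.zeros((t_steps, n))
    pp = np.zeros((t_steps, n, n))
    m = m0.copy()
    p = p0 * np.eye(n)
    mp[0] = m
    pp[0] = p
    for t in range(t_steps):
        s = p + r * eye
        innov = y[:, t] - m
        gain = np.linalg.solve(s, p).T
        m = m + gain @ innov
        p = p - gain @ p
        p = 0.5 * (p + p.T)
        mf[t] = m
        pf[t] = p
        if t < t_steps - 1:
            m = a @ m + b[:, t]
            p = a @ p @ a.T + q
            p = 0.5 * (p + p.T)
            mp[t + 1] = m
            pp[t + 1] = p
    return mf, pf, mp, pp


@njit(cache=True)
def _rts_smooth(a, mf, pf, mp, pp):
    t_steps, n = mf.shape
    ms = np.zeros((t_steps, n))
    ms[t_steps - 1] = mf[t_steps - 1]
    for t in range(t_steps - 2, -1, -1):
        c = np.linalg.solve(pp[t + 1], a @ pf[t]).T  # P_f A^T P_pred^{-1}
        ms[t] = mf[t] + c @ (ms[t + 1] - mp[t + 1])
    return ms


def _as_cov(q, n: int) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if q.ndim == 0:
        return float(q) * np.eye(n)
    return np.ascontiguousarray(q)


def kalman_loglik(a: np.ndarray, b: np.ndarray, q, r: float,
                  y: np.ndarray, m0: np.ndarray | None = None,
                  p0: float = 1.0) -> float:
    """Exact marginal log likelihood of the observations under the model.

    ``q`` may be a scalar (isotropic process noise) or a full (N, N)
    covariance matrix.
    """
    n = y.shape[0]
    if m0 is None:
        m0 = np.zeros(n)
    return float(_filter_loglik(np.ascontiguousarray(a, dtype=np.float64),
                                np.ascontiguousarray(b, dtype=np.float64),
                                _as_cov(q, n), float(r),
                                np.ascontiguousarray(y, dtype=np.float64),
                                np.ascontiguousarray(m0, dtype=np.float64),
                                float(p0)))


def kalman_smooth(a: np.ndarray, b: np.ndarray, q, r: float,
                  y: np.ndarray, m0: np.ndarray | None = None,
                  p0: float = 1.0) -> np.ndarray:
    """Rauch--Tung--Striebel smoothed state means, shape (N, T)."""
    n = y.shape[0]
    if m0 is None:
        m0 = np.zeros(n)
    mf, pf, mp, pp = _filter_store(np.ascontiguousarray(a, dtype=np.float64),
                                   np.ascontiguousarray(b, dtype=np.float64),
                                   _as_cov(q, n), float(r),
                                   np.ascontiguousarray(y, dtype=np.float64),
                                   np.ascontiguousarray(m0, dtype=np.float64),
                                   float(p0))
    ms = _rts_smooth(np.ascontiguousarray(a, dtype=np.float64), mf, pf, mp, pp)
    return np.asarray(ms).T
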