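"""Jacobian stability analysis and the critical diffusion-scaling factor.

For the linear model the Jacobian is ``J = P + sigma L``; stability of the
flow is governed entirely by its eigenvalues and is independent of any
external driving input.  Scaling the diffusion coefficient ``sigma -> alpha
sigma`` gives ``J'(alpha) = P + alpha sigma L`` whose trace is affine in
alpha:

    tr J'(alpha) = tr P + alpha * sigma * sum_i d_i

Since the trace is the sum of the eigenvalues, a positive trace guarantees
at least one eigenvalue with positive real part (instability).  Solving
``tr J'(alpha) = 0`` gives the trace-critical scaling

    alpha_trace = -tr P / (sigma * sum_i d_i) = 1 - tr J / (sigma * sum_i d_i)

which is strictly below 1 whenever ``tr J > 0``: an initially
trace-positive (hence unstable) system can only be rendered trace-negative
by *reducing* the diffusion coefficient.  Trace negativity is necessary,
not sufficient, for stability, so a spectral critical scaling (root of the
leading eigenvalue's real part) is exposed alongside the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .dynamics import ModelParameters
from .graph import AdjacencyGraph

__all__ = ["JacobianSummary", "AlphaResult", "jacobian", "scaled_jacobian",
           "critical_alpha"]


@dataclass(frozen=True)
class JacobianSummary:
    j: np.ndarray
    eigenvalues: np.ndarray
    trace: float
    sum_real: float
    stable: bool

    @property
    def max_real(self) -> float:
        return float(self.eigenvalues.real.max())


@dataclass(frozen=True)
class AlphaResult:
    """Critical diffusion scalings.

    ``alpha_trace`` zeroes the trace of the scaled Jacobian (closed form);
    ``alpha_spectral`` zeroes the leading real part (root search), or None
    when no sign change is bracketed.  ``trace_positive_input`` records
    whether the unscaled system was trace-positive (the regime the
    ``alpha < 1`` theorem addresses).
    """

    alpha_trace: float
    alpha_spectral: float | None
    trace_positive_input: bool


def _summarize(j: np.ndarray) -> JacobianSummary:
    eig = np.linalg.eigvals(j)
    sum_real = float(eig.real.sum())
    return JacobianSummary(j=j, eigenvalues=eig, trace=float(np.trace(j)),
                           sum_real=sum_real,
                           stable=bool(eig.real.max() < 0.0))


def jacobian(params: ModelParameters, graph: AdjacencyGraph) -> JacobianSummary:
    """Jacobian ``J = P + sigma L`` with eigenvalues and stability flag.

    Entrywise: ``J_ii = p_ii + sigma d_i`` and ``J_ij = p_ij - sigma k_ij``
    for ``i != j``.  Driving inputs never enter J.
    """
    if params.n_regions != graph.n_regions:
        raise ValueError("parameter and graph dimensions disagree")
    return _summarize(params.p + params.sigma * graph.laplacian)


def scaled_jacobian(params: ModelParameters, graph: AdjacencyGraph,
                    alpha: float) -> JacobianSummary:
    """Jacobian with the diffusion coefficient scaled: ``J' = P + alpha sigma L``."""
    if params.n_regions != graph.n_regions:
        raise ValueError("parameter and graph dimensions disagree")
    return _summarize(params.p + alpha * params.sigma * graph.laplacian)


def critical_alpha(params: ModelParameters, graph: AdjacencyGraph,
                   alpha_lo: float = -10.0, tol: float = 1e-8) -> AlphaResult:
    """Critical diffusion-scaling factors of the scaled Jacobian.

    Requires ``sigma > 0`` and at least one edge; otherwise the diffusion
    channel does not exist and no scaling can act.  The spectral root is
    searched on ``[alpha_lo, 1]`` by Brent's method when a sign change of
    ``max Re eig J'(alpha)`` is bracketed.
    """
    total_degree = float(graph.d.sum())
    if params.sigma <= 0 or total_degree <= 0:
        raise ValueError("no diffusion channel: sigma = 0 or edgeless graph")
    tr_p = float(np.trace(params.p))
    denom = params.sigma * total_degree
    # affine identity: tr J'(alpha) = tr P + alpha * sigma * sum(d)
    alpha_trace = -tr_p / denom
    tr_j = tr_p + denom
    trace_positive = tr_j > 0

    def leading(alpha: float) -> float:
        return scaled_jacobian(params, graph, alpha).max_real

    alpha_spectral = None
    lo, hi = alpha_lo, 1.0
    f_lo, f_hi = leading(lo), leading(hi)
    if f_lo == 0.0:
        alpha_spectral = lo
    elif f_hi == 0.0:
        alpha_spectral = hi
    elif f_lo * f_hi < 0:
        alpha_spectral = float(brentq(leading, lo, hi, xtol=tol))
    return AlphaResult(alpha_trace=float(alpha_trace),
                       alpha_spectral=alpha_spectral,
                       trace_positive_input=trace_positive)
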