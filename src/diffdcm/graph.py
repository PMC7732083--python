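"""Structural connectivity: normalisation, thresholding and graph Laplacians.

A weighted connectome (e.g. streamline counts from diffusion tractography)
is first normalised relative to its maximum entry, then binarized at one or
more thresholds expressed as fractions of that maximum.  The binary
adjacency matrix ``K`` yields the degree vector ``d`` and the graph
Laplacian ``L = D - K``, the discrete Laplace operator that drives the
diffusion term of the generalised neuronal state equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WeightedConnectome",
    "AdjacencyGraph",
    "normalize_connectome",
    "binarize",
    "threshold_sweep",
    "read_matrix",
    "write_matrix",
    "to_graphml",
]

_SYM_TOL = 1e-9


def _default_labels(n: int) -> list[str]:
    return [f"region_{i}" for i in range(n)]


@dataclass(frozen=True)
class WeightedConnectome:
    """Symmetric nonnegative connectivity matrix normalised to max 1."""

    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not self.region_labels:
            object.__setattr__(self, "region_labels", _default_labels(w.shape[0]))
        if len(self.region_labels) != w.shape[0]:
            raise ValueError("region_labels length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Binary adjacency with degrees and graph Laplacian ``L = D - K``."""

    k: np.ndarray
    d: np.ndarray
    laplacian: np.ndarray
    threshold: float
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.region_labels:
            object.__setattr__(self, "region_labels", _default_labels(self.k.shape[0]))

    @property
    def n_regions(self) -> int:
        return self.k.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.k.sum()) // 2

    @property
    def total_degree(self) -> int:
        """Sum of node degrees (twice the edge count)."""
        return int(self.d.sum())


def normalize_connectome(raw: np.ndarray, region_labels: list[str] | None = None) -> WeightedConnectome:
    """Normalise a raw connectivity matrix relative to its maximum value.

    Symmetry is enforced by averaging with the transpose, the diagonal is
    zeroed (no self-loops) and all weights are divided by the maximum
    off-diagonal entry, so the strongest connection has weight 1.

    Raises
    ------
    ValueError
        If the matrix is asymmetric beyond ``1e-9``, has negative entries,
        or contains no positive off-diagonal entry ("empty connectome").
    """
    w = np.asarray(raw, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectome must be a square matrix")
    if not np.all(np.isfinite(w)):
        raise ValueError("connectome contains non-finite entries")
    if np.any(w < 0):
        raise ValueError("connectome entries must be nonnegative")
    scale = max(np.abs(w).max(), 1.0)
    if np.abs(w - w.T).max() > _SYM_TOL * scale:
        raise ValueError("connectome is asymmetric beyond tolerance")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax <= 0:
        raise ValueError("empty connectome")
    return WeightedConnectome(w / wmax, list(region_labels or []))


def binarize(w: WeightedConnectome, threshold: float) -> AdjacencyGraph:
    """Binarize a normalised connectome: ``k_ij = 1`` iff ``w_ij >= threshold``.

    The threshold is a fraction of the maximum weight (the matrix is
    normalised to max 1) and the comparison is inclusive.  The diagonal is
    always zero.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    k = (w.weights >= threshold).astype(np.int64)
    np.fill_diagonal(k, 0)
    d = k.sum(axis=1)
    lap = np.diag(d) - k
    return AdjacencyGraph(k=k, d=d, laplacian=lap, threshold=float(threshold),
                          region_labels=list(w.region_labels))


def threshold_sweep(w: WeightedConnectome, lo: float = 10.0, hi: float = 95.0,
                    step: float = 5.0) -> list[AdjacencyGraph]:
    """Binarize over a grid of thresholds given in percent.

    The default grid 10..95 % in 5 % steps yields 18 adjacency matrices.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    n = int(round((hi - lo) / step)) + 1
    thresholds = [lo + i * step for i in range(n) if lo + i * step <= hi + 1e-9]
    return [binarize(w, t / 100.0) for t in thresholds]


def laplacian_action(graph: AdjacencyGraph, x: np.ndarray) -> np.ndarray:
    """Diffusion term ``sum_j k_ij (x_i - x_j)`` computed as ``L @ x``."""
    return graph.laplacian @ np.asarray(x, dtype=float)


def pairwise_gradient_sum(graph: AdjacencyGraph, x: np.ndarray) -> np.ndarray:
    """Diffusion term computed edge-by-edge from the structural gradients.

    Identical to :func:`laplacian_action`; retained as the explicit,
    loop-based form of the same operator for cross-checking.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    k = graph.k
    n = k.shape[0]
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if k[i, j]:
                acc += x[i] - x[j]
        out[i] = acc
    return out


# ---------------------------------------------------------------------------
# I/O

def write_matrix(path, matrix: np.ndarray, labels: list[str], sep: str = "\t") -> None:
    """Write a square labelled matrix as TSV/CSV with a header row."""
    pd.DataFrame(np.asarray(matrix), index=labels, columns=labels).to_csv(path, sep=sep)


def read_matrix(path, sep: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Read a square labelled matrix written by :func:`write_matrix`."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def to_graphml(graph: AdjacencyGraph, path) -> None:
    """Export a binarized adjacency graph to GraphML."""
    g = nx.Graph()
    g.add_nodes_from(graph.region_labels)
    idx = np.argwhere(np.triu(graph.k, 1))
    for i, j in idx:
        g.add_edge(graph.region_labels[i], graph.region_labels[j])
    g.graph["threshold"] = graph.threshold
    nx.write_graphml(g, path)
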