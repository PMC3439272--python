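"""Biased random walk with restart and edge-flux scoring.

The walker moves on the directed-arc expansion of the network (an
undirected edge contributes both arcs).  Transition probabilities are
biased by per-node data weights w:

    p_ij = w_j / sum_{k in N_i} w_k

over the downstream neighbors N_i of node i.  The stationary distribution
g is the left eigenvector (eigenvalue 1) of the restart-modified matrix

    M = (1 - q) P + q 1 r^T,      r = w / sum(w)

with restart probability q (default 0.01): at every step the walker
teleports with probability q to a node drawn proportionally to its data
weight, which makes high-data nodes sources of walk mass.  Rows with no
outgoing arcs (dangling) are replaced by r (standard stochasticization).

The arc visitation probability is e_ij = g_i p_ij.  The Edge Flux score of
an interaction is the log-likelihood ratio of its visitation probability
under the data-biased walk versus the uniform-weight baseline walk on the
same topology:

    EF_ij = log( e_ij_w / e_ij_r )

For an undirected edge the two arc probabilities are summed in numerator
and denominator before the log (the interaction is one event).  The
baseline captures all bias due to topology alone, so EF isolates the data
signal; uniform weights give EF identically zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .network import InteractionNetwork

logger = logging.getLogger("edgeflux")

DEFAULT_Q = 0.01
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000

__all__ = [
    "TransitionMatrix",
    "WalkResult",
    "EdgeFluxResult",
    "ConvergenceError",
    "build_transition_matrix",
    "stationary_distribution",
    "edge_probabilities",
    "edge_flux",
]


class ConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float, tol: float):
        super().__init__(
            f"power iteration did not converge in {iterations} iterations "
            f"(final L1 change {residual:.3e}, tolerance {tol:.1e})")
        self.iterations = iterations
        self.residual = residual


@dataclass
class TransitionMatrix:
    """Row-stochastic sparse transition matrix over a fixed node order.

    Rows of dangling nodes (no outgoing arcs) are all-zero here and flagged
    in ``dangling``; the walk substitutes the restart distribution for them.
    """

    nodes: list[str]
    index: dict[str, int]
    P: sp.csr_matrix
    dangling: np.ndarray  # bool, per node

    @property
    def n(self) -> int:
        return len(self.nodes)

    def weight_array(self, weights: Mapping[str, float]) -> np.ndarray:
        w = np.empty(self.n)
        for i, node in enumerate(self.nodes):
            try:
                w[i] = weights[node]
            except KeyError:
                raise KeyError(f"no weight for network node {node!r}") from None
        if not (np.all(np.isfinite(w)) and np.all(w > 0)):
            bad = self.nodes[int(np.argmin(np.where(np.isfinite(w), w, -np.inf)))]
            raise ValueError(f"weights must be strictly positive and finite "
                             f"(offending node: {bad!r})")
        return w


@dataclass
class WalkResult:
    """Converged stationary distribution of one biased walk."""

    nodes: list[str]
    g: np.ndarray
    q: float
    iterations: int
    residual: float
    dangling_mass: float

    @property
    def g_map(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.g.tolist()))


def build_transition_matrix(network: InteractionNetwork,
                            weights: Mapping[str, float]) -> TransitionMatrix:
    """Build p_ij = w_j / sum of downstream-neighbor weights.

    Node order is sorted for determinism.  Undirected edges are expanded to
    two arcs; parallel typed edges between the same pair collapse to one arc.
    """
    nodes = sorted(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    arcs = sorted(network.arc_set())
    w = np.empty(n)
    for node, i in index.items():
        wi = weights[node] if node in weights else None
        if wi is None:
            raise KeyError(f"no weight for network node {node!r}")
        if not (math.isfinite(wi) and wi > 0):
            raise ValueError(
                f"node {node!r} has nonpositive or nonfinite weight {wi!r}")
        w[i] = wi
    rows = np.fromiter((index[a] for a, _ in arcs), dtype=np.int64, count=len(arcs))
    cols = np.fromiter((index[b] for _, b in arcs), dtype=np.int64, count=len(arcs))
    vals = w[cols]
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    row_sums = np.asarray(P.sum(axis=1)).ravel()
    dangling = row_sums == 0
    inv = np.ones(n)
    inv[~dangling] = 1.0 / row_sums[~dangling]
    P = sp.diags(inv) @ P
    return TransitionMatrix(nodes=nodes, index=index, P=P.tocsr(),
                            dangling=dangling)


def stationary_distribution(tm: TransitionMatrix,
                            weights: Mapping[str, float],
                            q: float = DEFAULT_Q,
                            tol: float = DEFAULT_TOL,
                            max_iter: int = DEFAULT_MAX_ITER) -> WalkResult:
    """Power iteration for g = g[(1-q)(P + d r^T) + q 1 r^T].

    Starts from the restart distribution r = w/sum(w); stops when the L1
    change drops below ``tol``.  Convergence is geometric at rate <= 1-q.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"restart probability q must be in (0, 1), got {q}")
    w = tm.weight_array(weights)
    r = w / w.sum()
    P = tm.P
    dangling = tm.dangling
    g = r.copy()
    residual = math.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        dangling_mass = float(g[dangling].sum()) if dangling.any() else 0.0
        g_new = (1.0 - q) * (g @ P + dangling_mass * r) + q * r
        residual = float(np.abs(g_new - g).sum())
        g = g_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(max_iter, residual, tol)
    g = g / g.sum()
    return WalkResult(nodes=tm.nodes, g=g, q=q, iterations=iterations,
                      residual=residual,
                      dangling_mass=float(g[dangling].sum()) if dangling.any() else 0.0)


def edge_probabilities(result: WalkResult,
                       tm: TransitionMatrix) -> dict[tuple[str, str], float]:
    """Arc visitation probabilities e_ij = g_i p_ij.

    Sums to 1 minus the stationary mass on dangling nodes (whose teleport
    steps traverse no network arc).
    """
    coo = tm.P.tocoo()
    g = result.g
    out: dict[tuple[str, str], float] = {}
    for i, j, p in zip(coo.row, coo.col, coo.data):
        out[(tm.nodes[i], tm.nodes[j])] = float(g[i] * p)
    return out


@dataclass
class EdgeFluxResult:
    """Edge Flux scores per canonical edge plus the underlying walks.

    ``ef`` maps (a, b, directed) -> score; NaN marks an edge the baseline
    walk never visits (undefined ratio).  ``per_arc`` carries the
    directional scores for undirected edges.
    """

    ef: dict[tuple, float]
    per_arc: dict[tuple[str, str], float]
    walk_weighted: WalkResult
    walk_baseline: WalkResult
    log_base: float = math.e
    n_undefined: int = 0
    edge_prob_weighted: dict[tuple[str, str], float] = field(default_factory=dict)
    edge_prob_baseline: dict[tuple[str, str], float] = field(default_factory=dict)


def baseline_walk(network: InteractionNetwork,
                  q: float = DEFAULT_Q,
                  tol: float = DEFAULT_TOL,
                  max_iter: int = DEFAULT_MAX_ITER
                  ) -> tuple[TransitionMatrix, WalkResult, dict]:
    """Uniform-weight walk on the network topology.

    Depends only on the topology, so it is computed once per network and
    reused across all data columns.
    """
    uniform = {node: 1.0 for node in network.nodes}
    tm = build_transition_matrix(network, uniform)
    res = stationary_distribution(tm, uniform, q=q, tol=tol, max_iter=max_iter)
    return tm, res, edge_probabilities(res, tm)


def edge_flux(network: InteractionNetwork,
              weights: Mapping[str, float],
              q: float = DEFAULT_Q,
              tol: float = DEFAULT_TOL,
              max_iter: int = DEFAULT_MAX_ITER,
              log_base: float = math.e,
              baseline: tuple[TransitionMatrix, WalkResult, dict] | None = None,
              ) -> EdgeFluxResult:
    """Edge Flux for every edge: log-ratio of weighted vs baseline arc
    visitation probability (undirected edges sum their two arcs first).

    ``baseline`` accepts a precomputed :func:`baseline_walk` triple so one
    baseline serves many conditions.  ``log_base`` defaults to the natural
    log; pass 2 for log2 scores.
    """
    tm = build_transition_matrix(network, weights)
    res_w = stationary_distribution(tm, weights, q=q, tol=tol, max_iter=max_iter)
    e_w = edge_probabilities(res_w, tm)
    if baseline is None:
        baseline = baseline_walk(network, q=q, tol=tol, max_iter=max_iter)
    tm_r, res_r, e_r = baseline
    scale = math.log(log_base)
    ef: dict[tuple, float] = {}
    per_arc: dict[tuple[str, str], float] = {}
    n_undefined = 0
    for arc, pw in e_w.items():
        pr = e_r.get(arc, 0.0)
        if pr > 0 and pw > 0:
            per_arc[arc] = math.log(pw / pr) / scale
        else:
            per_arc[arc] = math.nan
    for key in network.canonical_edge_keys():
        a, b, directed = key
        if directed:
            num = e_w.get((a, b), 0.0)
            den = e_r.get((a, b), 0.0)
        else:
            num = e_w.get((a, b), 0.0) + e_w.get((b, a), 0.0)
            den = e_r.get((a, b), 0.0) + e_r.get((b, a), 0.0)
        if den > 0 and num > 0:
            ef[key] = math.log(num / den) / scale
        else:
            ef[key] = math.nan
            n_undefined += 1
    if n_undefined:
        logger.warning(
            "edge_flux: %d edge(s) have zero baseline visitation "
            "probability; their scores are undefined", n_undefined)
    return EdgeFluxResult(ef=ef, per_arc=per_arc, walk_weighted=res_w,
                          walk_baseline=res_r, log_base=log_base,
                          n_undefined=n_undefined,
                          edge_prob_weighted=e_w, edge_prob_baseline=e_r)
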