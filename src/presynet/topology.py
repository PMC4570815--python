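"""Small-world / scale-free network generation and graph statistics.

Neurons sit at uniform random positions on a square plate (an MEA-like
surface with hard boundaries).  Each neuron's out-degree is drawn from a
generalized-Pareto (heavy-tailed) distribution whose scale is calibrated so
the mean out-degree matches the requested connectivity ratio.  Targets are
drawn by distance rank: candidates are sorted by Euclidean distance and
sampled without replacement with probability proportional to a binomial pmf
of the rank, giving preferentially local wiring with a nonzero chance of
long-range shortcuts.  Nonzero weights are lognormal, truncated at A_max,
and negated for inhibitory sources.

Graph statistics (global clustering coefficient, all-pairs shortest paths via
Floyd-Warshall, small-world index against an Erdos-Renyi ensemble) follow the
undirected convention: the directed graph is symmetrized before either
statistic is computed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import brentq
from scipy.sparse.csgraph import floyd_warshall
from scipy.spatial.distance import cdist

__all__ = [
    "NetworkTopology",
    "GraphMetrics",
    "place_neurons",
    "sample_degrees",
    "build_connectivity",
    "generate_topology",
    "shortest_paths",
    "clustering_coefficient",
    "mean_shortest_path",
    "small_world_index",
    "save_topology",
    "load_topology",
]


@dataclass
class NetworkTopology:
    """Positions, excitatory/inhibitory labels and signed weighted adjacency.

    ``adjacency[i, j]`` is the weight of the connection from presynaptic
    neuron j to postsynaptic neuron i (zero when unconnected); its sign
    follows the type of the *source* neuron j.
    """

    positions: np.ndarray          # (n, 2)
    is_inhibitory: np.ndarray      # (n,) bool
    adjacency: sp.csr_matrix       # (n, n), A[i, j] for j -> i

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    @property
    def connectivity_ratio_realized(self) -> float:
        n = self.n_neurons
        return self.n_edges / (n * (n - 1))

    def validate(self) -> None:
        a = self.adjacency.tocoo()
        if np.any(a.row == a.col):
            raise ValueError("self-connections present")
        if np.any(np.abs(a.data) > np.inf):
            raise ValueError("non-finite weights")
        inhib = self.is_inhibitory[a.col]
        if np.any((a.data < 0) != inhib):
            raise ValueError("weight sign inconsistent with source neuron type")


@dataclass
class GraphMetrics:
    mean_shortest_path: float
    clustering_coefficient: float
    normalized_clustering: float
    normalized_shortest_path: float
    small_world_index: float
    connectivity_ratio_realized: float
    mean_degree: float
    degenerate: bool = False


def place_neurons(n: int, dims: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform random positions on the square [0, dims]^2."""
    if n < 2:
        raise ValueError("need at least 2 neurons")
    if dims <= 0:
        raise ValueError("dims must be positive")
    return rng.uniform(0.0, dims, size=(n, 2))


def _expected_clipped_gpd_mean(scale: float, shape: float, upper: float) -> float:
    """E[clip(X, 1, upper)] for X ~ GPD(shape, scale) on [0, inf).

    Uses E[clip(X,1,M)] = 1 + integral_1^M S(x) dx with the closed-form
    survival integral of the generalized Pareto distribution.
    """
    dist = stats.genpareto(shape, loc=0.0, scale=scale)

    def survival_integral(a: float, b: float) -> float:
        # integral of (1 + c x / s)^(-1/c) dx
        c, s = shape, scale
        if abs(c) < 1e-12:
            return s * (np.exp(-a / s) - np.exp(-b / s))
        if c >= 1:
            raise ValueError("pareto_shape must be < 1 for a finite mean")
        anti = lambda x: -s / (1 - c) * (1 + c * x / s) ** (1 - 1 / c)
        return anti(b) - anti(a)

    return 1.0 + survival_integral(1.0, upper)


def sample_degrees(n: int, connectivity_ratio: float, rng: np.random.Generator,
                   pareto_shape: float = 0.25) -> np.ndarray:
    """Heavy-tailed integer out-degrees with mean ~ connectivity_ratio*(n-1).

    Degrees are generalized-Pareto draws, rounded and clipped to [1, n-1];
    the GPD scale is solved numerically so the expected clipped value equals
    the target mean.
    """
    if not 0 < connectivity_ratio < 1:
        raise ValueError("connectivity_ratio must be in (0, 1)")
    target = connectivity_ratio * (n - 1)
    if target > n - 1:
        raise ValueError("requested mean degree exceeds n-1")
    if target < 1:
        raise ValueError(
            "connectivity_ratio too small: mean degree below the minimum of 1")

    f = lambda s: _expected_clipped_gpd_mean(s, pareto_shape, n - 1) - target
    scale = brentq(f, 1e-9, 10.0 * target * max(1.0, 1 - pareto_shape))
    raw = stats.genpareto.rvs(pareto_shape, loc=0.0, scale=scale,
                              size=n, random_state=rng)
    return np.clip(np.rint(raw), 1, n - 1).astype(np.int64)


def _rank_kernel(n: int, kernel_trials: int | None, kernel_p: float) -> np.ndarray:
    """Binomial pmf over distance ranks 0..n-2, floored to keep every rank
    reachable (long-range shortcuts retain a small nonzero probability)."""
    trials = (n - 1) if kernel_trials is None else kernel_trials
    pmf = stats.binom.pmf(np.arange(n - 1), trials, kernel_p)
    pmf = pmf + 1e-12 * max(pmf.max(), 1e-300)
    return pmf / pmf.sum()


def build_connectivity(positions: np.ndarray, degrees: np.ndarray,
                       is_inhibitory: np.ndarray, rng: np.random.Generator, *,
                       weight_mu: float = -0.874, weight_sigma: float = 1.026,
                       weight_scale: float = 1.0, a_max: float = 10.0,
                       kernel_trials: int | None = None,
                       kernel_p: float = 0.05) -> NetworkTopology:
    """Wire each neuron to deg(j) distinct targets by distance rank.

    Weight magnitudes are ``weight_scale`` times lognormal(mu, sigma) draws,
    resampled until below ``a_max``.
    """
    n = positions.shape[0]
    degrees = np.asarray(degrees)
    if np.any(degrees > n - 1) or np.any(degrees < 0):
        raise ValueError("degrees must lie in [0, n-1]")
    dist = cdist(positions, positions)
    kernel = _rank_kernel(n, kernel_trials, kernel_p)

    rows, cols, data = [], [], []
    others_base = np.arange(n)
    for j in range(n):
        deg = int(degrees[j])
        if deg == 0:
            continue
        others = np.delete(others_base, j)
        # stable sort: ties in distance broken by neuron index
        order = others[np.argsort(dist[j, others], kind="stable")]
        if deg == n - 1:
            targets = order
        else:
            picked = rng.choice(n - 1, size=deg, replace=False, p=kernel)
            targets = order[picked]
        w = _truncated_lognormal(deg, weight_mu, weight_sigma, weight_scale,
                                 a_max, rng)
        if is_inhibitory[j]:
            w = -w
        rows.append(targets)
        cols.append(np.full(deg, j))
        data.append(w)

    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    data = np.concatenate(data) if data else np.array([], dtype=float)
    adjacency = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    topo = NetworkTopology(positions=positions,
                           is_inhibitory=np.asarray(is_inhibitory, dtype=bool),
                           adjacency=adjacency)
    topo.validate()
    return topo


def _truncated_lognormal(size: int, mu: float, sigma: float, scale: float,
                         a_max: float, rng: np.random.Generator) -> np.ndarray:
    """Scaled lognormal magnitudes resampled until all fall below a_max."""
    w = scale * rng.lognormal(mu, sigma, size=size)
    bad = w >= a_max
    while np.any(bad):
        w[bad] = scale * rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = w >= a_max
    return w


def generate_topology(config, rng: np.random.Generator) -> NetworkTopology:
    """Full pipeline: placement, inhibitory labels, degrees, wiring."""
    n = config.n_neurons
    positions = place_neurons(n, config.mea_dims, rng)
    n_inhib = int(round(config.inhibitory_neuron_ratio * n))
    is_inhibitory = np.zeros(n, dtype=bool)
    is_inhibitory[rng.choice(n, size=n_inhib, replace=False)] = True
    degrees = sample_degrees(n, config.connectivity_ratio, rng,
                             pareto_shape=config.pareto_shape)
    raw_mean = float(np.exp(config.weight_mu + 0.5 * config.weight_sigma ** 2))
    scale = (1.0 if config.weight_mean is None
             else config.weight_mean / raw_mean)
    return build_connectivity(
        positions, degrees, is_inhibitory, rng,
        weight_mu=config.weight_mu, weight_sigma=config.weight_sigma,
        weight_scale=scale, a_max=config.a_max,
        kernel_trials=config.kernel_trials, kernel_p=config.kernel_p)


# --------------------------------------------------------------------------
# graph statistics
# --------------------------------------------------------------------------

def _as_unweighted(adjacency) -> sp.csr_matrix:
    a = sp.csr_matrix(adjacency)
    a = (a != 0).astype(np.int8)
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def _symmetrized(adjacency) -> sp.csr_matrix:
    a = _as_unweighted(adjacency)
    return ((a + a.T) != 0).astype(np.int8)


def shortest_paths(adjacency) -> np.ndarray:
    """All-pairs hop counts of the directed unweighted graph (Floyd-Warshall).

    ``adjacency[i, j]`` encodes the edge j -> i, so the result is transposed
    back to the conventional orientation: ``D[src, dst]`` is the minimal hop
    count from src to dst.  Unreachable pairs are +inf; the diagonal is zero.
    """
    a = _as_unweighted(adjacency)
    return floyd_warshall(a.T.tocsr(), directed=True, unweighted=True)


def clustering_coefficient(adjacency) -> float:
    """Global clustering: 3*(#triangles) / (#paths of length 2).

    Computed on the symmetrized unweighted graph; returns 0.0 when the graph
    has no length-2 paths.
    """
    b = _symmetrized(adjacency).toarray().astype(np.float64)
    deg = b.sum(axis=1)
    wedges2 = float((deg * (deg - 1)).sum())       # 2 * number of wedges
    if wedges2 == 0:
        return 0.0
    closed = float((b * (b @ b)).sum())            # trace(B^3) = 6 * triangles
    return closed / wedges2


def mean_shortest_path(adjacency) -> float:
    """Mean hop count over reachable ordered pairs of the symmetrized graph."""
    d = floyd_warshall(_symmetrized(adjacency), directed=False, unweighted=True)
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return np.inf
    return float(d[finite].mean())


def _er_reference(n: int, m_directed: int, rng: np.random.Generator) -> sp.csr_matrix:
    """Directed Erdos-Renyi G(n, m) with the same node and edge counts."""
    pairs = n * (n - 1)
    idx = rng.choice(pairs, size=m_directed, replace=False)
    src, off = np.divmod(idx, n - 1)
    dst = np.where(off >= src, off + 1, off)
    return sp.csr_matrix((np.ones(m_directed, dtype=np.int8), (dst, src)),
                         shape=(n, n))


def small_world_index(topology: NetworkTopology, n_reference: int,
                      rng: np.random.Generator) -> GraphMetrics:
    """Clustering and path length normalized against an E-R ensemble.

    The reference ensemble has the same number of nodes and directed edges;
    the small-world index is normalized_clustering / normalized_shortest_path.
    A reference ensemble with zero clustering is flagged degenerate and the
    index is NaN.
    """
    adjacency = topology.adjacency
    n = topology.n_neurons
    m = topology.n_edges
    c_obs = clustering_coefficient(adjacency)
    l_obs = mean_shortest_path(adjacency)
    c_ref = np.empty(n_reference)
    l_ref = np.empty(n_reference)
    for r in range(n_reference):
        er = _er_reference(n, m, rng)
        c_ref[r] = clustering_coefficient(er)
        l_ref[r] = mean_shortest_path(er)
    c_ref_mean = float(c_ref.mean())
    l_ref_mean = float(l_ref.mean())
    degenerate = (c_ref_mean <= 0) or not np.isfinite(l_ref_mean) \
        or l_ref_mean <= 0 or not np.isfinite(l_obs)
    norm_c = c_obs / c_ref_mean if c_ref_mean > 0 else np.nan
    norm_l = l_obs / l_ref_mean if (np.isfinite(l_obs) and l_ref_mean > 0) else np.nan
    swi = norm_c / norm_l if not degenerate and norm_l > 0 else np.nan
    return GraphMetrics(
        mean_shortest_path=l_obs,
        clustering_coefficient=c_obs,
        normalized_clustering=norm_c,
        normalized_shortest_path=norm_l,
        small_world_index=swi,
        connectivity_ratio_realized=topology.connectivity_ratio_realized,
        mean_degree=m / n,
        degenerate=bool(degenerate),
    )


# --------------------------------------------------------------------------
# plain-text round trip
# --------------------------------------------------------------------------

def save_topology(topology: NetworkTopology, edges_path: str | Path,
                  nodes_path: str | Path) -> None:
    """Edge list (source_id, target_id, weight) plus a node sidecar table."""
    a = topology.adjacency.tocoo()
    edges = pd.DataFrame({"source_id": a.col, "target_id": a.row,
                          "weight": a.data})
    edges = edges.sort_values(["source_id", "target_id"], kind="stable")
    edges.to_csv(edges_path, index=False, float_format="%.17g")
    nodes = pd.DataFrame({
        "neuron_id": np.arange(topology.n_neurons),
        "x": topology.positions[:, 0],
        "y": topology.positions[:, 1],
        "is_inhibitory": topology.is_inhibitory.astype(int),
    })
    nodes.to_csv(nodes_path, index=False, float_format="%.17g")


def load_topology(edges_path: str | Path, nodes_path: str | Path) -> NetworkTopology:
    edges = pd.read_csv(edges_path, float_precision="round_trip")
    nodes = pd.read_csv(nodes_path,
                    float_precision="round_trip").sort_values("neuron_id")
    n = len(nodes)
    adjacency = sp.csr_matrix(
        (edges["weight"].to_numpy(),
         (edges["target_id"].to_numpy(), edges["source_id"].to_numpy())),
        shape=(n, n))
    return NetworkTopology(
        positions=nodes[["x", "y"]].to_numpy(),
        is_inhibitory=nodes["is_inhibitory"].to_numpy().astype(bool),
        adjacency=adjacency)
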