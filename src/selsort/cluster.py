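"""Super-paramagnetic clustering (SPC) and an OPTICS alternative.

SPC maps each waveform's feature vector to a q-state Potts spin on a
mutual K-nearest-neighbour graph with couplings

    J_ij = (1 / K_hat) * exp(-e_ij^2 / (2 a^2)),

where e_ij is the Euclidean distance, K_hat the average neighbour count
and a the average edge length.  Swendsen–Wang Monte Carlo at a grid of
temperatures yields the thermal average G_ij of the same-spin indicator
per edge.  At low temperature the system is ferromagnetic (G -> 1
everywhere); at high temperature paramagnetic (G -> 1/q); in between,
dense groups of points stay magnetised together while weak links melt —
clusters are the connected components of edges with G above a threshold
at a temperature chosen inside that super-paramagnetic plateau.  Small
components stay unassigned (label 0), collecting outliers and overlapped
waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import OPTICS, cluster_optics_dbscan
from sklearn.neighbors import NearestNeighbors


@dataclass
class SpcConfig:
    q_states: int = 20
    knn_K: int = 11
    temperatures: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 0.251, 0.01), 3)
    )
    sweeps: int = 500
    burn_in: int = 100
    correlation_threshold: float = 0.5
    #: None -> adaptive: 3% of the number of waveforms, floor 60
    min_cluster_size: int | None = None
    #: clusters smaller than this fraction of the largest are pooled as
    #: unassigned (small heterogeneous overlap/outlier groups)
    relative_min_fraction: float = 0.25
    #: clusters whose mean radius exceeds this multiple of the tightest
    #: cluster's radius are pooled: a spike class is noise-limited and
    #: compact, an overlapped-spike group is a wide mixture (0 disables)
    radius_demote_factor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=np.float64)
        if self.q_states < 2:
            raise ValueError("q_states must be at least 2")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")


@dataclass
class ClusterAssignment:
    """Per-waveform labels: 0 = unassigned/overlap, 1..C = clusters
    ordered by descending size."""

    labels: np.ndarray
    sizes: np.ndarray
    chosen_temperature: float
    method: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return self.sizes.size

    @property
    def n_unassigned(self) -> int:
        return int(np.count_nonzero(self.labels == 0))


@dataclass
class KnnGraph:
    """Mutual K-nearest-neighbour edge list with Euclidean distances."""

    n_points: int
    edges: np.ndarray  # (E, 2), i < j
    dists: np.ndarray  # (E,)

    @property
    def avg_neighbours(self) -> float:
        return 2.0 * self.edges.shape[0] / max(self.n_points, 1)

    @property
    def avg_dist(self) -> float:
        return float(self.dists.mean()) if self.dists.size else 0.0


def knn_distances(X: np.ndarray, K: int) -> KnnGraph:
    """Build the mutual K-nearest-neighbour graph (i and j are linked when
    each is among the other's K nearest)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    M = X.shape[0]
    K = min(K, M - 1)
    if M < 2 or K < 1:
        return KnnGraph(M, np.empty((0, 2), dtype=np.int64), np.empty(0))
    nn = NearestNeighbors(n_neighbors=min(K + 1, M)).fit(X)
    dist, ind = nn.kneighbors(X)
    # drop each point from its own neighbour list (duplicates make the
    # self entry land at an arbitrary position), keep the K nearest others
    neigh, ndist = [], []
    for i in range(M):
        keep = ind[i] != i
        neigh.append(ind[i][keep][:K])
        ndist.append(dist[i][keep][:K])
    nsets = [set(n.tolist()) for n in neigh]
    ii, jj, dd = [], [], []
    for i in range(M):
        for j, d in zip(neigh[i], ndist[i]):
            j = int(j)
            if j > i and i in nsets[j]:
                ii.append(i)
                jj.append(j)
                dd.append(d)
    edges = np.column_stack([ii, jj]).astype(np.int64) if ii else np.empty((0, 2), dtype=np.int64)
    return KnnGraph(M, edges, np.asarray(dd, dtype=np.float64))


def interaction_strengths(graph: KnnGraph) -> np.ndarray:
    """Potts couplings J_ij = (1/K_hat) exp(-e_ij^2 / (2 a^2)) per edge."""
    k_hat = max(graph.avg_neighbours, 1e-12)
    a = graph.avg_dist
    if a == 0:
        return np.full(graph.dists.shape, 1.0 / k_hat)
    return np.exp(-graph.dists**2 / (2.0 * a**2)) / k_hat


def _sw_correlations(graph: KnnGraph, J: np.ndarray, T: float,
                     cfg: SpcConfig, rng) -> np.ndarray:
    """Swendsen–Wang estimate of the same-spin correlation G_ij at one T."""
    M, E = graph.n_points, graph.edges.shape[0]
    if E == 0:
        return np.empty(0)
    src, dst = graph.edges[:, 0], graph.edges[:, 1]
    p_freeze = 1.0 - np.exp(-J / T) if T > 0 else np.ones(E)
    spins = rng.integers(cfg.q_states, size=M)
    G = np.zeros(E)
    counted = 0
    ones = np.ones(E)
    for sweep in range(cfg.sweeps):
        active = (spins[src] == spins[dst]) & (rng.random(E) < p_freeze)
        adj = coo_matrix(
            (ones[active], (src[active], dst[active])), shape=(M, M)
        )
        n_comp, comp = connected_components(adj, directed=False)
        spins = rng.integers(cfg.q_states, size=n_comp)[comp]
        if sweep >= cfg.burn_in:
            G += spins[src] == spins[dst]
            counted += 1
    return G / max(counted, 1)


def spc_sweep(graph: KnnGraph, J: np.ndarray, cfg: SpcConfig) -> dict:
    """Run Swendsen–Wang Potts dynamics over the temperature grid.

    Returns a map T -> per-edge thermal same-spin correlation G_ij in
    [0, 1].  Reproducible for a fixed ``cfg.seed`` (each temperature uses
    an independent child stream, so results per T do not depend on grid
    order or extent).
    """
    out = {}
    for i, T in enumerate(cfg.temperatures):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 101, int(round(T * 1e6))])
        )
        out[float(T)] = _sw_correlations(graph, J, float(T), cfg, rng)
    return out


def effective_min_size(cfg: SpcConfig, M: int) -> int:
    if cfg.min_cluster_size is not None:
        return cfg.min_cluster_size
    return max(60, int(round(0.03 * M)))


def extract_clusters(graph: KnnGraph, G: np.ndarray, cfg: SpcConfig,
                     chosen_temperature: float = float("nan"),
                     X: np.ndarray | None = None) -> ClusterAssignment:
    """Connected components of edges with G above the correlation
    threshold; components below the minimum cluster size stay unassigned
    (collecting outliers and overlapped spike shapes).

    When the feature matrix ``X`` is given, clusters much wider than the
    tightest one (``radius_demote_factor``) are also pooled — a genuine
    spike class is compact at the noise scale, while a group of
    overlapped waveforms is a wide mixture of collision shapes.
    """
    M = graph.n_points
    active = G > cfg.correlation_threshold
    adj = coo_matrix(
        (
            np.ones(int(np.count_nonzero(active))),
            (graph.edges[active, 0], graph.edges[active, 1]),
        ),
        shape=(M, M),
    )
    _, comp = connected_components(adj, directed=False)
    asg = _components_to_assignment(
        comp, effective_min_size(cfg, M), chosen_temperature, "spc",
        rel_min=cfg.relative_min_fraction,
    )
    if X is not None and cfg.radius_demote_factor > 0 and asg.n_clusters > 1:
        asg = _demote_wide_clusters(asg, np.atleast_2d(X), cfg.radius_demote_factor)
    return asg


def _demote_wide_clusters(asg: ClusterAssignment, X: np.ndarray,
                          factor: float) -> ClusterAssignment:
    radii = []
    for c in range(1, asg.n_clusters + 1):
        P = X[asg.labels == c]
        radii.append(float(np.mean(np.linalg.norm(P - P.mean(0), axis=1))))
    floor = min(radii)
    keep = [c for c, r in enumerate(radii, start=1)
            if floor == 0 or r <= factor * floor]
    labels = np.zeros_like(asg.labels)
    sizes = []
    order = sorted(keep, key=lambda c: -int(asg.sizes[c - 1]))
    for rank, c in enumerate(order, start=1):
        labels[asg.labels == c] = rank
        sizes.append(int(asg.sizes[c - 1]))
    return ClusterAssignment(
        labels=labels, sizes=np.asarray(sizes, dtype=np.int64),
        chosen_temperature=asg.chosen_temperature, method=asg.method,
    )


def _components_to_assignment(comp, min_size, chosen_T, method, rel_min=0.0):
    M = comp.size
    labels = np.zeros(M, dtype=np.int64)
    ids, counts = np.unique(comp, return_counts=True)
    if rel_min > 0 and np.any(counts >= min_size):
        min_size = max(min_size, int(np.ceil(rel_min * counts.max())))
    big = ids[counts >= min_size]
    big_counts = counts[counts >= min_size]
    order = np.argsort(-big_counts, kind="stable")
    sizes = []
    for rank, k in enumerate(order, start=1):
        labels[comp == big[k]] = rank
        sizes.append(int(big_counts[k]))
    return ClusterAssignment(
        labels=labels,
        sizes=np.asarray(sizes, dtype=np.int64),
        chosen_temperature=chosen_T,
        method=method,
    )


def select_temperature(temperatures, sizes_per_T) -> float:
    """Pick the temperature resolving the most cluster structure.

    Potts dynamics only ever split correlated domains as T rises, so the
    maximum number of non-trivial clusters over the grid marks the
    super-paramagnetic phase where all separable groups have come apart;
    among those temperatures the one assigning the most points to
    clusters wins (membership erodes with T), with remaining ties broken
    toward lower T.  Mutual-KNN graphs often disconnect well-separated
    groups outright, in which case the full structure is already present
    at the lowest grid temperature and that is what gets picked.
    Deterministic.
    """
    T = np.asarray(temperatures, dtype=np.float64)
    counts = np.array([len(s) for s in sizes_per_T])
    assigned = np.array([int(np.sum(s)) for s in sizes_per_T])
    if counts.max(initial=0) == 0:
        return float(T[0])
    cand = np.flatnonzero(counts == counts.max())
    best = cand[np.argmax(assigned[cand])]
    return float(T[best])


def spc_cluster(X: np.ndarray, cfg: SpcConfig | None = None):
    """Full SPC pass: graph, couplings, Monte Carlo, temperature choice,
    cluster extraction.  Returns ``(ClusterAssignment, diagnostics)``
    where diagnostics holds the per-temperature correlations and
    assignments."""
    cfg = cfg or SpcConfig()
    graph = knn_distances(X, cfg.knn_K)
    J = interaction_strengths(graph)
    corr = spc_sweep(graph, J, cfg)
    per_T = {}
    sizes_per_T = []
    for T in cfg.temperatures:
        asg = extract_clusters(graph, corr[float(T)], cfg, float(T), X=X)
        per_T[float(T)] = asg
        sizes_per_T.append(asg.sizes)
    T_star = select_temperature(cfg.temperatures, sizes_per_T)
    chosen = per_T[float(T_star)]
    diagnostics = {
        "graph": graph,
        "correlations": corr,
        "assignments": per_T,
        "sizes_per_T": sizes_per_T,
        "chosen_temperature": T_star,
    }
    return chosen, diagnostics


def optics_cluster(X: np.ndarray, min_samples: int = 11,
                   eps: float | None = None) -> ClusterAssignment:
    """Density-based alternative on raw aligned waveforms or features.

    OPTICS orders points by density reachability; the ordering is cut at
    ``eps`` (the 90th percentile of finite reachabilities when not given,
    which sits above within-cluster variation but below the jumps that
    separate density peaks).  Border points that are not density-reachable
    cores stay unassigned (label 0).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    M = X.shape[0]
    min_samples = max(2, min(min_samples, M))
    opt = OPTICS(min_samples=min_samples).fit(X)
    finite = opt.reachability_[np.isfinite(opt.reachability_)]
    if eps is None:
        eps = float(np.percentile(finite, 90)) if finite.size else 0.0
    if eps <= 0:
        labels01 = np.zeros(M, dtype=np.int64)
        return ClusterAssignment(
            labels=labels01, sizes=np.empty(0, dtype=np.int64),
            chosen_temperature=float("nan"), method="optics",
        )
    raw = cluster_optics_dbscan(
        reachability=opt.reachability_,
        core_distances=opt.core_distances_,
        ordering=opt.ordering_,
        eps=eps,
    )
    labels = np.zeros(M, dtype=np.int64)
    ids, counts = np.unique(raw[raw >= 0], return_counts=True)
    # a group smaller than the density count is not a valid cluster
    keep = counts >= min_samples
    ids, counts = ids[keep], counts[keep]
    order = np.argsort(-counts, kind="stable")
    sizes = []
    for rank, k in enumerate(order, start=1):
        labels[raw == ids[k]] = rank
        sizes.append(int(counts[k]))
    return ClusterAssignment(
        labels=labels,
        sizes=np.asarray(sizes, dtype=np.int64),
        chosen_temperature=float("nan"),
        method="optics",
    )
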