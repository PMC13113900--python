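"""Graph constructions for short transient waveforms.

The primary construction maps a quantized amplitude sequence to a weighted
undirected graph: nodes are the visited quantization levels and each
consecutive sample pair (q(t), q(t+1)) contributes the edge between its two
levels.  The edge weight is the inverse amplitude distance

    w(v_i, v_j) = 1 / (|l_i - l_j| + eps),    eps = 1/(Q-1),

so transitions between nearby levels are strongly connected while large
jumps yield weak edges; eps prevents division by zero on self-loops (weight
Q-1).  The weight is a function of the two levels alone; repeated
transitions increment an integer ``count`` edge attribute instead
(exposed for sensitivity analysis via ``use_count_weight``).

Five standard alternatives are provided for comparison: natural visibility
graph, recurrence network, k-nearest-neighbour graph, epsilon-ball graph on
quantization levels, and ordinal partition network.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.io
import scipy.linalg
import scipy.sparse

from .signal_io import QuantizedSignal, Waveform

__all__ = [
    "Construction",
    "SignalGraph",
    "SpectralSummary",
    "build_erg_graph",
    "build_visibility_graph",
    "build_recurrence_network",
    "build_knn_graph",
    "build_eball_graph",
    "build_opn",
    "build_graph",
    "spectral_summary",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "write_adjacency_mtx",
]


class Construction(str, enum.Enum):
    ERG_GRAPH = "erg"
    VG = "vg"
    RN = "rn"
    KNN = "knn"
    EBALL = "eball"
    OPN = "opn"


@dataclass
class SignalGraph:
    """A weighted undirected graph built from one waveform.

    Edge attributes: ``weight`` (positive real), ``count`` (number of
    temporal transitions realizing the edge; 1 for constructions without a
    transition notion).  Self-loops are kept on the graph but excluded from
    adjacency/Laplacian/density views by :func:`spectral_summary`.
    """

    graph: nx.Graph
    construction: Construction
    Q: int | None = None
    params: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_self_loops(self) -> int:
        return sum(1 for u, v in self.graph.edges if u == v)

    @property
    def n_edges(self) -> int:
        """Edge count excluding self-loops."""
        return self.graph.number_of_edges() - self.n_self_loops

    def simple(self) -> nx.Graph:
        """Self-loop-free view used by distance, clustering and spectral code."""
        g = self.graph.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
        return g

    def total_transition_count(self) -> int:
        return sum(d["count"] for _, _, d in self.graph.edges(data=True))


def _meta(source) -> dict:
    w = source.source if isinstance(source, QuantizedSignal) else source
    if isinstance(w, Waveform):
        return {
            "subject_id": w.subject_id,
            "group": w.group.value,
            "sex": w.sex.value,
            "eye": w.eye.value,
            "flash_td": w.flash_td,
            "recording_index": w.recording_index,
        }
    return {}


def build_erg_graph(q: QuantizedSignal) -> SignalGraph:
    """Amplitude-quantization transition graph (the primary construction).

    Nodes are the distinct visited level indices k (amplitude l = k/(Q-1),
    stored as the ``level`` node attribute).  A single-sample signal yields
    a single node and no edges.
    """
    eps = q.epsilon
    idx = q.indices
    g = nx.Graph()
    qm1 = q.Q - 1
    for k in np.unique(idx):
        g.add_node(int(k), level=k / qm1)
    for a, b in zip(idx[:-1], idx[1:]):
        u, v = (int(a), int(b)) if a <= b else (int(b), int(a))
        if g.has_edge(u, v):
            g[u][v]["count"] += 1
        else:
            dist = abs(u - v) / qm1
            g.add_edge(u, v, weight=1.0 / (dist + eps), count=1, length=dist + eps)
    return SignalGraph(graph=g, construction=Construction.ERG_GRAPH, Q=q.Q,
                       meta=_meta(q))


def build_visibility_graph(w: Waveform) -> SignalGraph:
    """Natural visibility graph on time samples.

    Samples a < b are connected iff every intermediate c satisfies
    x_c < x_a + (x_b - x_a)(c - a)/(b - a), i.e. the running maximum slope
    from a is exceeded at b (O(N^2) sweep).
    """
    x = np.asarray(w.samples, dtype=float)
    n = x.size
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a in range(n - 1):
        g.add_edge(a, a + 1, weight=1.0, count=1)
        max_slope = x[a + 1] - x[a]
        for b in range(a + 2, n):
            slope = (x[b] - x[a]) / (b - a)
            if slope > max_slope:
                g.add_edge(a, b, weight=1.0, count=1)
            max_slope = max(max_slope, slope)
    return SignalGraph(graph=g, construction=Construction.VG, meta=_meta(w))


def build_recurrence_network(w: Waveform, eps_r: float = 0.1) -> SignalGraph:
    """Recurrence network: samples i != j linked iff |x_i - x_j| < eps_r.

    Embedding dimension 1, delay 1, absolute-value norm on the normalized
    signal; the threshold is on normalized amplitude units.
    """
    if eps_r <= 0:
        raise ValueError("eps_r must be positive")
    x = np.asarray(w.samples, dtype=float)
    n = x.size
    g = nx.Graph()
    g.add_nodes_from(range(n))
    close = np.abs(x[:, None] - x[None, :]) < eps_r
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu[close[iu, ju]], ju[close[iu, ju]]):
        g.add_edge(int(i), int(j), weight=1.0, count=1)
    return SignalGraph(graph=g, construction=Construction.RN,
                       params={"eps_r": eps_r}, meta=_meta(w))


def build_knn_graph(w: Waveform, k: int = 3) -> SignalGraph:
    """k-nearest-neighbour graph in amplitude space (symmetrized union).

    Neighbours of sample i are the k samples minimizing |x_i - x_j|, ties
    broken by smaller time index.
    """
    x = np.asarray(w.samples, dtype=float)
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need at least k+1 = {k + 1} samples, got {n}")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    indices = np.arange(n)
    for i in range(n):
        d = np.abs(x - x[i])
        d[i] = np.inf
        order = np.lexsort((indices, d))  # distance, then time index
        for j in order[:k]:
            g.add_edge(i, int(j), weight=1.0, count=1)
    return SignalGraph(graph=g, construction=Construction.KNN,
                       params={"k": k}, meta=_meta(w))


def build_eball_graph(q: QuantizedSignal, eps_b: float | None = None) -> SignalGraph:
    """Epsilon-ball graph on visited quantization levels.

    Distinct levels l_i != l_j are linked iff |l_i - l_j| < eps_b.  The
    default eps_b = 2/(Q-1) connects adjacent and next-adjacent levels.
    """
    if eps_b is None:
        eps_b = 2.0 / (q.Q - 1)
    if eps_b <= 0:
        raise ValueError("eps_b must be positive")
    qm1 = q.Q - 1
    ks = np.unique(q.indices)
    g = nx.Graph()
    for k in ks:
        g.add_node(int(k), level=k / qm1)
    for i in range(ks.size):
        for j in range(i + 1, ks.size):
            if abs(ks[i] - ks[j]) / qm1 < eps_b:
                g.add_edge(int(ks[i]), int(ks[j]), weight=1.0, count=1)
    return SignalGraph(graph=g, construction=Construction.EBALL, Q=q.Q,
                       params={"eps_b": eps_b}, meta=_meta(q))


def _ordinal_pattern(window: np.ndarray) -> tuple:
    # Rank-order pattern; ties resolved earlier-index-smaller via stable sort.
    return tuple(int(i) for i in np.argsort(window, kind="stable"))


def build_opn(w: Waveform, m: int = 3) -> SignalGraph:
    """Ordinal partition network: nodes are rank-order patterns of m
    consecutive samples (delay 1); edges link patterns of consecutive
    windows, with ``count`` accumulating transitions (self-loops allowed)."""
    if m < 2:
        raise ValueError("m must be >= 2")
    x = np.asarray(w.samples, dtype=float)
    n = x.size
    if n <= m:
        raise ValueError(f"need at least m+1 = {m + 1} samples, got {n}")
    patterns = [_ordinal_pattern(x[i:i + m]) for i in range(n - m + 1)]
    g = nx.Graph()
    g.add_nodes_from(set(patterns))
    for a, b in zip(patterns[:-1], patterns[1:]):
        u, v = (a, b) if a <= b else (b, a)
        if g.has_edge(u, v):
            g[u][v]["count"] += 1
        else:
            g.add_edge(u, v, weight=1.0, count=1)
    return SignalGraph(graph=g, construction=Construction.OPN,
                       params={"m": m}, meta=_meta(w))


def build_graph(w: Waveform, method: Construction | str, Q: int = 50,
                eps_r: float = 0.1, k: int = 3, eps_b: float | None = None,
                m: int = 3) -> SignalGraph:
    """Dispatch on construction method; ``w`` must be normalized for all
    methods (quantization is applied internally where needed)."""
    from .signal_io import quantize

    method = Construction(method)
    if method is Construction.ERG_GRAPH:
        return build_erg_graph(quantize(w, Q))
    if method is Construction.VG:
        return build_visibility_graph(w)
    if method is Construction.RN:
        return build_recurrence_network(w, eps_r)
    if method is Construction.KNN:
        return build_knn_graph(w, k)
    if method is Construction.EBALL:
        return build_eball_graph(quantize(w, Q), eps_b)
    if method is Construction.OPN:
        return build_opn(w, m)
    raise ValueError(f"unknown construction {method}")


@dataclass
class SpectralSummary:
    """Dense adjacency/Laplacian views over the visited nodes.

    Self-loops are excluded from A (hence from D, L, density and degree):
    L = D - A is invariant to self-loops under the standard convention and
    the density denominator V(V-1) presumes a simple graph.
    """

    nodelist: list
    adjacency: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray
    eigenvalues: np.ndarray
    fiedler_vector: np.ndarray | None
    density: float
    n_components: int


def spectral_summary(g: SignalGraph, use_count_weight: bool = False) -> SpectralSummary:
    """Adjacency, degree, Laplacian, full eigendecomposition and density.

    Node counts are bounded by Q (or N), so a dense symmetric eigensolver
    is used.  ``use_count_weight`` multiplies each edge weight by its
    transition count before assembling A (sensitivity analysis).
    """
    simple = g.simple()
    nodelist = sorted(simple.nodes)
    n = len(nodelist)
    a = nx.to_numpy_array(simple, nodelist=nodelist, weight="weight")
    if use_count_weight:
        c = nx.to_numpy_array(simple, nodelist=nodelist, weight="count")
        a = a * c
    d = np.diag(a.sum(axis=1))
    lap = d - a
    eigvals, eigvecs = scipy.linalg.eigh(lap)
    fiedler = eigvecs[:, 1] if n >= 2 else None
    n_edges = simple.number_of_edges()
    density = 0.0 if n <= 1 else 2.0 * n_edges / (n * (n - 1))
    return SpectralSummary(
        nodelist=nodelist,
        adjacency=a,
        degree=d,
        laplacian=lap,
        eigenvalues=eigvals,
        fiedler_vector=fiedler,
        density=density,
        n_components=nx.number_connected_components(simple),
    )


# ---------------------------------------------------------------------------
# Export

def write_edgelist(sg: SignalGraph, path) -> None:
    """Weighted edge list, one ``u v weight count`` line per edge
    (self-loops included)."""
    with open(path, "w") as fh:
        for u, v, d in sg.graph.edges(data=True):
            fh.write(f"{u} {v} {d['weight']!r} {d['count']}\n")


def read_edgelist(path, construction: Construction | str = Construction.ERG_GRAPH,
                  Q: int | None = None) -> SignalGraph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            u, v, w, c = parts
            try:
                u, v = int(u), int(v)
            except ValueError:
                pass
            g.add_edge(u, v, weight=float(w), count=int(c))
    return SignalGraph(graph=g, construction=Construction(construction), Q=Q)


def write_graphml(sg: SignalGraph, path) -> None:
    g = sg.graph.copy()
    # GraphML cannot store tuple node ids (ordinal patterns); stringify.
    if any(not isinstance(n, (int, str)) for n in g.nodes):
        g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    nx.write_graphml(g, path)


def write_adjacency_mtx(sg: SignalGraph, path, use_count_weight: bool = False) -> None:
    """Adjacency matrix as MatrixMarket coordinate/symmetric."""
    summ = spectral_summary(sg, use_count_weight=use_count_weight)
    mat = scipy.sparse.coo_matrix(np.tril(summ.adjacency))
    scipy.io.mmwrite(str(path), mat, symmetry="symmetric")
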