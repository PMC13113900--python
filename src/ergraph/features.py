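"""Nine topological/spectral graph features for one waveform graph.

Feature set (in table column order): total load centrality (tlc), total
harmonic centrality (thc), number of maximal cliques (gnc), diameter,
radius, average clustering coefficient (cc), average path length (apl),
algebraic connectivity / Fiedler value (lambda2), and density.

Distances are hop counts on the self-loop-free graph by default; the
weighted mode (path length = |l_i - l_j| + eps) is available behind a flag
for the amplitude-level constructions.  Disconnected graphs follow a
"giant component" policy: diameter, radius, apl and lambda2 are computed on
the largest connected component with a logged warning (strict mode raises
instead).  tlc, thc, gnc, cc and density are well defined on disconnected
graphs and always use the full graph.

tlc is the unnormalized betweenness-style sum over unordered node pairs of
the fraction of shortest s-t paths through v; the field also uses the name
"load centrality" for a slightly different path-splitting measure, but the
sum-of-fractions form is what is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import Construction, SignalGraph, build_graph, spectral_summary
from .signal_io import Waveform, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureVector",
    "GRAPH_FEATURE_NAMES",
    "TD_FEATURE_NAMES",
    "all_pairs_distances",
    "total_load_centrality",
    "total_harmonic_centrality",
    "number_of_maximal_cliques",
    "graph_diameter",
    "graph_radius",
    "average_clustering",
    "average_path_length",
    "algebraic_connectivity",
    "extract_features",
    "time_domain_features",
    "feature_table",
    "write_feature_table",
    "read_feature_table",
]

GRAPH_FEATURE_NAMES = [
    "tlc", "thc", "gnc", "diameter", "radius", "cc", "apl", "lambda2", "density",
]

TD_FEATURE_NAMES = [
    "td_a_amp", "td_a_lat_ms", "td_b_amp", "td_b_lat_ms", "td_ba_ratio",
    "td_ptp", "td_energy", "td_op_rms",
]


@dataclass
class FeatureVector:
    tlc: float
    thc: float
    gnc: int
    diameter: float
    radius: float
    cc: float
    apl: float
    lambda2: float
    density: float
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "provenance"}


def _as_simple(g) -> nx.Graph:
    if isinstance(g, SignalGraph):
        return g.simple()
    g = g.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


_WEIGHT_KW = {False: None, True: "length"}


def all_pairs_distances(g, weighted: bool = False) -> tuple[list, np.ndarray]:
    """Shortest-path distance matrix (np.inf for disconnected pairs).

    Returns (nodelist, matrix); hop counts by default, edge ``length``
    attribute in weighted mode.
    """
    simple = _as_simple(g)
    nodes = sorted(simple.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    if weighted:
        it = nx.all_pairs_dijkstra_path_length(simple, weight="length")
    else:
        it = nx.all_pairs_shortest_path_length(simple)
    for u, dists in it:
        for v, duv in dists.items():
            d[pos[u], pos[v]] = duv
    return nodes, d


def total_load_centrality(g, weighted: bool = False) -> float:
    """Sum over nodes of the unnormalized shortest-path betweenness
    (fraction of s-t shortest paths through v, unordered pairs)."""
    simple = _as_simple(g)
    bc = nx.betweenness_centrality(simple, normalized=False, weight=_WEIGHT_KW[weighted])
    return float(sum(bc.values()))


def total_harmonic_centrality(g, weighted: bool = False) -> float:
    """Sum over ordered pairs u != v of 1/d(v, u); disconnected pairs
    contribute 0."""
    simple = _as_simple(g)
    hc = nx.harmonic_centrality(simple, distance=_WEIGHT_KW[weighted])
    return float(sum(hc.values()))


def number_of_maximal_cliques(g) -> int:
    simple = _as_simple(g)
    if simple.number_of_nodes() == 0:
        return 0
    return sum(1 for _ in nx.find_cliques(simple))


def _largest_component(simple: nx.Graph, strict: bool, what: str) -> nx.Graph:
    if nx.is_connected(simple):
        return simple
    if strict:
        raise ValueError(f"graph is disconnected; cannot compute {what} in strict mode")
    comp = max(nx.connected_components(simple), key=len)
    logger.warning("disconnected graph: %s computed on largest component (%d/%d nodes)",
                   what, len(comp), simple.number_of_nodes())
    return simple.subgraph(comp).copy()


def _ecc(simple: nx.Graph, weighted: bool) -> dict:
    if weighted:
        return nx.eccentricity(simple, weight="length")
    return nx.eccentricity(simple)


def graph_diameter(g, weighted: bool = False, strict: bool = False) -> float:
    simple = _largest_component(_as_simple(g), strict, "diameter")
    if simple.number_of_nodes() <= 1:
        return 0.0
    return float(max(_ecc(simple, weighted).values()))


def graph_radius(g, weighted: bool = False, strict: bool = False) -> float:
    simple = _largest_component(_as_simple(g), strict, "radius")
    if simple.number_of_nodes() <= 1:
        return 0.0
    return float(min(_ecc(simple, weighted).values()))


def average_clustering(g) -> float:
    """Mean local clustering coefficient over all nodes; nodes of degree
    < 2 contribute 0."""
    simple = _as_simple(g)
    if simple.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(simple, count_zeros=True))


def average_path_length(g, weighted: bool = False, strict: bool = False) -> float:
    """Mean shortest-path distance over ordered node pairs."""
    simple = _largest_component(_as_simple(g), strict, "average path length")
    if simple.number_of_nodes() <= 1:
        return 0.0
    return float(nx.average_shortest_path_length(simple, weight=_WEIGHT_KW[weighted]))


def algebraic_connectivity(g, use_count_weight: bool = False, strict: bool = False) -> float:
    """Second-smallest eigenvalue of the weighted combinatorial Laplacian
    (self-loops excluded); 0 by convention for a single node.

    On disconnected graphs lambda2 of the full Laplacian is 0, so the
    giant-component policy computes it on the largest component.
    """
    if isinstance(g, SignalGraph):
        sg = g
    else:
        sg = SignalGraph(graph=g, construction=Construction.ERG_GRAPH)
    simple = sg.simple()
    if simple.number_of_nodes() <= 1:
        return 0.0
    if not nx.is_connected(simple):
        comp_graph = _largest_component(simple, strict, "algebraic connectivity")
        sg = SignalGraph(graph=comp_graph, construction=sg.construction, Q=sg.Q)
        if comp_graph.number_of_nodes() <= 1:
            return 0.0
    summ = spectral_summary(sg, use_count_weight=use_count_weight)
    return float(summ.eigenvalues[1])


def extract_features(g: SignalGraph, weighted_paths: bool = False,
                     strict: bool = False, use_count_weight: bool = False) -> FeatureVector:
    """Compute the nine features, sharing one distance matrix and one
    spectral summary; deterministic for a given graph."""
    simple = _as_simple(g)
    n = simple.number_of_nodes()
    if n == 0:
        raise ValueError("cannot extract features from an empty graph")
    nodes, dmat = all_pairs_distances(simple, weighted=weighted_paths)
    finite = np.isfinite(dmat)
    connected = bool(finite.all())
    if connected:
        sub = dmat
    else:
        if strict:
            raise ValueError("graph is disconnected (strict mode)")
        comp = sorted(max(nx.connected_components(simple), key=len))
        sel = np.array([nodes.index(v) for v in comp])
        sub = dmat[np.ix_(sel, sel)]
        logger.warning("disconnected graph: diameter/radius/apl/lambda2 on "
                       "largest component (%d/%d nodes)", len(sel), n)
    m = sub.shape[0]
    if m <= 1:
        diam = rad = apl = 0.0
    else:
        ecc = sub.max(axis=1)
        diam = float(ecc.max())
        rad = float(ecc.min())
        apl = float(sub.sum() / (m * (m - 1)))
    with np.errstate(divide="ignore"):
        inv = np.where(finite & (dmat > 0), 1.0 / np.where(dmat > 0, dmat, 1.0), 0.0)
    thc = float(inv.sum())
    summ = spectral_summary(g if isinstance(g, SignalGraph)
                            else SignalGraph(graph=simple, construction=Construction.ERG_GRAPH),
                            use_count_weight=use_count_weight)
    lam2 = algebraic_connectivity(g, use_count_weight=use_count_weight, strict=strict)
    prov = dict(getattr(g, "meta", {}) or {})
    prov.update({"construction": getattr(g, "construction", None),
                 "Q": getattr(g, "Q", None)})
    return FeatureVector(
        tlc=total_load_centrality(simple, weighted=weighted_paths),
        thc=thc,
        gnc=number_of_maximal_cliques(simple),
        diameter=diam,
        radius=rad,
        cc=average_clustering(simple),
        apl=apl,
        lambda2=lam2,
        density=summ.density,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Time-domain morphology features (for feature-fusion configurations)

def time_domain_features(w: Waveform, a_window_ms: tuple = (5.0, 25.0),
                         b_window_ms: tuple = (15.0, 50.0),
                         op_band_hz: tuple = (75.0, 200.0)) -> dict:
    """Conventional morphology descriptors of the raw waveform.

    a-wave amplitude/latency (trough in the early window), b-wave
    amplitude/latency (peak), b/a ratio, peak-to-peak range, signal energy
    and RMS of the oscillatory band (default 75-200 Hz band-pass).
    """
    import scipy.signal

    x = np.asarray(w.samples, dtype=float)
    t = w.times_ms
    am = (t >= a_window_ms[0]) & (t <= a_window_ms[1])
    bm = (t >= b_window_ms[0]) & (t <= b_window_ms[1])
    ia = int(np.flatnonzero(am)[np.argmin(x[am])]) if am.any() else int(np.argmin(x))
    ib = int(np.flatnonzero(bm)[np.argmax(x[bm])]) if bm.any() else int(np.argmax(x))
    a_amp = float(-x[ia])
    b_amp = float(x[ib] - x[ia])
    sos = scipy.signal.butter(4, op_band_hz, btype="bandpass",
                              fs=w.sampling_rate, output="sos")
    try:
        op = scipy.signal.sosfiltfilt(sos, x)
    except ValueError:  # too few samples for zero-phase padding
        op = scipy.signal.sosfilt(sos, x)
    return {
        "td_a_amp": a_amp,
        "td_a_lat_ms": float(t[ia]),
        "td_b_amp": b_amp,
        "td_b_lat_ms": float(t[ib]),
        "td_ba_ratio": float(b_amp / a_amp) if a_amp != 0 else 0.0,
        "td_ptp": float(np.ptp(x)),
        "td_energy": float(np.sum(x ** 2)),
        "td_op_rms": float(np.sqrt(np.mean(op ** 2))),
    }


# ---------------------------------------------------------------------------
# Feature tables

_META_COLS = ["subject_id", "group", "sex", "eye", "flash_td",
              "recording_index", "construction", "Q"]


def feature_table(waveforms: Sequence[Waveform], Q: int = 50,
                  method: Construction | str = Construction.ERG_GRAPH,
                  include_td: bool = False, weighted_paths: bool = False,
                  strict: bool = False, **params) -> pd.DataFrame:
    """One row per waveform: metadata, the nine graph features and
    (optionally) the time-domain set.  Waveforms are normalized internally."""
    rows = []
    for w in waveforms:
        wn = w if w.normalized else normalize(w)
        sg = build_graph(wn, method, Q=Q, **params)
        fv = extract_features(sg, weighted_paths=weighted_paths, strict=strict)
        row = {
            "subject_id": w.subject_id,
            "group": w.group.value,
            "sex": w.sex.value,
            "eye": w.eye.value,
            "flash_td": w.flash_td,
            "recording_index": w.recording_index,
            "construction": Construction(method).value,
            "Q": Q,
        }
        row.update(fv.as_dict())
        if include_td:
            row.update(time_domain_features(w))
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GRAPH_FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {', '.join(missing)}")
    return df
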