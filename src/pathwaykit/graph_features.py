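"""The 88 graph features (groups 1-9) of a weighted pathway digraph.

All statistics use population variance and the even-length median
convention (mean of the two middle values).  Cutoff comparisons are
strict (">") throughout.  Self-loops, when present in the input, count in
the density denominator and make a vertex its own neighbor.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import ConfigurationError, PathwayGraph

#: Similarity cutoffs for the local-density-change group.
LOCAL_DENSITY_CUTOFFS = tuple(i / 10 for i in range(10))

PairSimilarity = Callable[[str, str], float]


def _neighborhoods(g: PathwayGraph) -> tuple[dict[str, set], dict[str, set]]:
    in_nb: dict[str, set] = {v: set() for v in g.vertices}
    out_nb: dict[str, set] = {v: set() for v in g.vertices}
    for tail, head in g.arcs:
        out_nb[tail].add(head)
        in_nb[head].add(tail)
    return in_nb, out_nb


def _stats3(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, population variance, max) with the all-zero convention for empty input."""
    if values.size == 0:
        return 0.0, 0.0, 0.0
    return float(values.mean()), float(values.var()), float(values.max())


def _arc_weights(g: PathwayGraph) -> np.ndarray:
    missing = [a for a in g.arcs if a not in g.weights]
    if missing:
        raise ConfigurationError(f"pathway {g.id}: arcs without weights, e.g. {missing[0]}")
    return np.array([g.weights[a] for a in g.arcs], dtype=float)


def size_density(g: PathwayGraph) -> tuple[float, float]:
    """Graph size |V| and density |E| / |V|^2 (self-loops admissible)."""
    n = g.n_vertices
    return float(n), g.n_arcs / n**2


def degree_stats(g: PathwayGraph) -> np.ndarray:
    """Mean, population variance, median and maximum of in- and out-degrees."""
    in_nb, out_nb = _neighborhoods(g)
    out = []
    for nb in (in_nb, out_nb):
        deg = np.array([len(nb[v]) for v in g.vertices], dtype=float)
        out += [deg.mean(), deg.var(), float(np.median(deg)), deg.max()]
    return np.array(out)


def edge_weight_stats(g: PathwayGraph) -> np.ndarray:
    """Mean/variance over all arc weights and over the nonzero arc weights."""
    w = _arc_weights(g)
    nz = w[w > 0]
    out = []
    for arr in (w, nz):
        if arr.size == 0:
            out += [0.0, 0.0]
        else:
            out += [float(arr.mean()), float(arr.var())]
    return np.array(out)


def topological_change(g: PathwayGraph) -> np.ndarray:
    """Relative arc loss T_i = (|E_i| - |E_{i+1}|) / |E_i| at weight cutoffs i/10.

    E_i keeps arcs with weight strictly greater than i/10; T_i = 0 when
    E_i is empty.  Seven features, i = 1..7.
    """
    w = _arc_weights(g)
    counts = [int((w > i / 10).sum()) for i in range(1, 9)]
    return np.array([
        (counts[i] - counts[i + 1]) / counts[i] if counts[i] > 0 else 0.0
        for i in range(7)
    ])


def _induced_arc_count(g: PathwayGraph, nodes: set) -> int:
    return sum(1 for tail, head in g.arcs if tail in nodes and head in nodes)


def degree_correlation(g: PathwayGraph) -> np.ndarray:
    """Per-vertex neighborhood arc density D' = |E'| / k over in- and out-neighbors.

    E' counts arcs of G among the k (in- or out-) neighbors of the vertex;
    features are the mean, population variance and max of the per-vertex
    values for each side.
    """
    in_nb, out_nb = _neighborhoods(g)
    out = []
    for nb in (in_nb, out_nb):
        vals = np.array([
            _induced_arc_count(g, nb[v]) / len(nb[v]) if nb[v] else 0.0
            for v in g.vertices
        ])
        out += list(_stats3(vals))
    return np.array(out)


def clustering(g: PathwayGraph) -> np.ndarray:
    """As :func:`degree_correlation` with squared denominators C' = |E'| / k^2."""
    in_nb, out_nb = _neighborhoods(g)
    out = []
    for nb in (in_nb, out_nb):
        vals = np.array([
            _induced_arc_count(g, nb[v]) / len(nb[v]) ** 2 if nb[v] else 0.0
            for v in g.vertices
        ])
        out += list(_stats3(vals))
    return np.array(out)


def shared_neighbor_topology(g: PathwayGraph) -> np.ndarray:
    """Shared-neighborhood overlap ratios for the four in/out combinations.

    For each ordered vertex pair (i, j), i != j, the overlap of i's in-(or
    out-)neighbors with j's in-(or out-)neighbors is divided by i's in-(or
    out-)degree (0 on zero denominator).  Each vertex gets the mean over
    j != i per combination; features are mean, population variance and max
    over vertices for each of the four combinations (12 in total).
    """
    n = g.n_vertices
    if n < 2:
        return np.zeros(12)
    in_nb, out_nb = _neighborhoods(g)
    per_vertex = {k: [] for k in range(4)}
    for vi in g.vertices:
        sums = [0.0, 0.0, 0.0, 0.0]
        din = len(in_nb[vi])
        dout = len(out_nb[vi])
        for vj in g.vertices:
            if vj == vi:
                continue
            if din:
                sums[0] += len(in_nb[vi] & in_nb[vj]) / din
                sums[1] += len(in_nb[vi] & out_nb[vj]) / din
            if dout:
                sums[2] += len(out_nb[vi] & in_nb[vj]) / dout
                sums[3] += len(out_nb[vi] & out_nb[vj]) / dout
        for k in range(4):
            per_vertex[k].append(sums[k] / (n - 1))
    out = []
    for k in range(4):
        out += list(_stats3(np.array(per_vertex[k])))
    return np.array(out)


def adjacency_matrix(g: PathwayGraph) -> np.ndarray:
    """0/1 adjacency matrix A over the pathway's vertex order."""
    idx = {v: i for i, v in enumerate(g.vertices)}
    a = np.zeros((g.n_vertices, g.n_vertices))
    for tail, head in g.arcs:
        a[idx[tail], idx[head]] = 1.0
    return a


def singular_values(g: PathwayGraph) -> np.ndarray:
    """Three largest singular values of the adjacency matrix, zero-padded."""
    s = np.linalg.svd(adjacency_matrix(g), compute_uv=False)
    out = np.zeros(3)
    out[: min(3, s.size)] = s[:3]
    return out


def local_density_change(g: PathwayGraph, pair_sim: PairSimilarity) -> np.ndarray:
    """Neighborhood similarity density across cutoffs 0.0 .. 0.9.

    For each vertex, the k in-(or out-)neighbors form a complete graph
    weighted by pairwise protein likelihood; L(w) is the fraction of the
    k(k-1)/2 unordered pairs whose likelihood strictly exceeds cutoff w
    (0 when k <= 1).  Features: per side and per cutoff, the mean and max
    of L(w) over vertices — 2 x 10 x 2 = 40 values.
    """
    in_nb, out_nb = _neighborhoods(g)
    out = []
    for nb in (in_nb, out_nb):
        # per-vertex L(w) profile across the 10 cutoffs
        profiles = np.zeros((g.n_vertices, len(LOCAL_DENSITY_CUTOFFS)))
        for row, v in enumerate(g.vertices):
            members = sorted(nb[v])
            k = len(members)
            if k <= 1:
                continue
            sims = np.array([
                pair_sim(members[i], members[j])
                for i in range(k) for j in range(i + 1, k)
            ])
            n_pairs = k * (k - 1) / 2
            for col, w in enumerate(LOCAL_DENSITY_CUTOFFS):
                profiles[row, col] = (sims > w).sum() / n_pairs
        for col in range(len(LOCAL_DENSITY_CUTOFFS)):
            out += [float(profiles[:, col].mean()), float(profiles[:, col].max())]
    return np.array(out)


def graph_feature_vector(g: PathwayGraph, pair_sim: PairSimilarity) -> np.ndarray:
    """All 88 graph features in registry order (groups 1-9 concatenated)."""
    parts = [
        np.array(size_density(g)),
        degree_stats(g),
        edge_weight_stats(g),
        topological_change(g),
        degree_correlation(g),
        clustering(g),
        shared_neighbor_topology(g),
        singular_values(g),
        local_density_change(g, pair_sim),
    ]
    vec = np.concatenate(parts)
    assert vec.size == 88
    return vec
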