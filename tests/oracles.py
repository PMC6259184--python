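"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively — explicit loops, itertools, direct
statistics — and deliberately shares no code with the package's
featurizer or classifier.
"""

from __future__ import annotations

import itertools

import numpy as np


def _mean(xs):
    xs = list(xs)
    return sum(xs) / len(xs) if xs else 0.0


def _popvar(xs):
    xs = list(xs)
    if not xs:
        return 0.0
    m = _mean(xs)
    return sum((x - m) ** 2 for x in xs) / len(xs)


def _median(xs):
    xs = sorted(xs)
    n = len(xs)
    if n == 0:
        return 0.0
    if n % 2:
        return float(xs[n // 2])
    return (xs[n // 2 - 1] + xs[n // 2]) / 2


def _max(xs):
    xs = list(xs)
    return max(xs) if xs else 0.0


def brute_graph_features(vertices, arcs, weights, sim):
    """All 88 graph features by direct enumeration.

    ``vertices``: list of ids; ``arcs``: list of (tail, head); ``weights``:
    dict arc -> w; ``sim``: callable (u, v) -> pair similarity.
    """
    n = len(vertices)
    arcs = list(dict.fromkeys(arcs))
    out = []

    # group 1: size, density
    out += [float(n), len(arcs) / n**2]

    # group 2: degree statistics
    in_deg = {v: sum(1 for (a, b) in arcs if b == v) for v in vertices}
    out_deg = {v: sum(1 for (a, b) in arcs if a == v) for v in vertices}
    for deg in (in_deg, out_deg):
        vals = [deg[v] for v in vertices]
        out += [_mean(vals), _popvar(vals), _median(vals), float(_max(vals))]

    # group 3: edge weight statistics
    ws = [weights[a] for a in arcs]
    nz = [w for w in ws if w > 0]
    for lst in (ws, nz):
        out += [_mean(lst), _popvar(lst)]

    # group 4: topological change
    sizes = [sum(1 for w in ws if w > i / 10) for i in range(1, 9)]
    for i in range(7):
        out.append((sizes[i] - sizes[i + 1]) / sizes[i] if sizes[i] else 0.0)

    # groups 5 and 6: neighborhood density
    in_nbrs = {v: {a for (a, b) in arcs if b == v} for v in vertices}
    out_nbrs = {v: {b for (a, b) in arcs if a == v} for v in vertices}

    def induced(nodes):
        return sum(1 for (a, b) in arcs if a in nodes and b in nodes)

    for power in (1, 2):
        for nbrs in (in_nbrs, out_nbrs):
            vals = [
                induced(nbrs[v]) / len(nbrs[v]) ** power if nbrs[v] else 0.0
                for v in vertices
            ]
            out += [_mean(vals), _popvar(vals), _max(vals)]

    # group 7: shared-neighbor overlap ratios
    if n < 2:
        out += [0.0] * 12
    else:
        per_k = {1: [], 2: [], 3: [], 4: []}
        for vi in vertices:
            accum = {1: [], 2: [], 3: [], 4: []}
            for vj in vertices:
                if vj == vi:
                    continue
                n1 = len(in_nbrs[vi] & in_nbrs[vj])
                n2 = len(in_nbrs[vi] & out_nbrs[vj])
                n3 = len(out_nbrs[vi] & in_nbrs[vj])
                n4 = len(out_nbrs[vi] & out_nbrs[vj])
                di = len(in_nbrs[vi])
                do = len(out_nbrs[vi])
                accum[1].append(n1 / di if di else 0.0)
                accum[2].append(n2 / di if di else 0.0)
                accum[3].append(n3 / do if do else 0.0)
                accum[4].append(n4 / do if do else 0.0)
            for k in (1, 2, 3, 4):
                per_k[k].append(_mean(accum[k]))
        for k in (1, 2, 3, 4):
            out += [_mean(per_k[k]), _popvar(per_k[k]), _max(per_k[k])]

    # group 8: singular values
    a_mat = np.zeros((n, n))
    for (t, h) in arcs:
        a_mat[vertices.index(t), vertices.index(h)] = 1.0
    svals = sorted(np.linalg.svd(a_mat, compute_uv=False), reverse=True)
    svals = (svals + [0.0, 0.0, 0.0])[:3]
    out += [float(s) for s in svals]

    # group 9: local density change
    for nbrs in (in_nbrs, out_nbrs):
        per_cutoff = {w: [] for w in [i / 10 for i in range(10)]}
        for v in vertices:
            members = sorted(nbrs[v])
            k = len(members)
            for w in per_cutoff:
                if k <= 1:
                    per_cutoff[w].append(0.0)
                else:
                    cnt = sum(
                        1
                        for x, y in itertools.combinations(members, 2)
                        if sim(x, y) > w
                    )
                    per_cutoff[w].append(2 * cnt / (k * (k - 1)))
        for w in sorted(per_cutoff):
            out += [_mean(per_cutoff[w]), _max(per_cutoff[w])]

    return np.array(out)


def brute_loocv_nn(x, y, metric_fn):
    """O(m^2) leave-one-out nearest-neighbor, scanning distances directly."""
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    m = len(y)
    preds = []
    for i in range(m):
        best_d, best_j = None, None
        for j in range(m):
            if j == i:
                continue
            d = metric_fn(x[i], x[j])
            if best_d is None or d < best_d:
                best_d, best_j = d, j
        preds.append(y[best_j])
    preds = np.array(preds)
    pos = y == 1
    return (
        float((preds[pos] == 1).mean()),
        float((preds[~pos] == 0).mean()),
        float((preds == y).mean()),
    )


def random_digraph(rng, max_n=6):
    """A random weighted digraph plus a random symmetric similarity table."""
    n = int(rng.integers(1, max_n + 1))
    vertices = [f"v{i}" for i in range(n)]
    arcs = []
    for t in vertices:
        for h in vertices:
            if t != h and rng.random() < 0.4:
                arcs.append((t, h))
    weights = {a: float(rng.random()) for a in arcs}
    table = {}
    for i in range(n):
        for j in range(i + 1, n):
            table[frozenset((vertices[i], vertices[j]))] = float(rng.random())

    def sim(u, v):
        return table[frozenset((u, v))]

    return vertices, arcs, weights, sim
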