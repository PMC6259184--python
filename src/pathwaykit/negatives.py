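"""Negative-pathway construction: the two randomization routes.

Route 1 builds fully random digraphs whose (vertex count, arc count)
pairs are drawn from the positives' joint empirical size distribution.
Route 2 keeps a positive's arc structure but replaces ⌈n/2⌉ of its
proteins with uniformly chosen outsiders.  The negative set is ``ratio``
times as large as the positive set (default 100:1), split evenly between
routes, and deduplicated against the positives and itself.
"""

from __future__ import annotations

import math

import numpy as np

from .core import ConfigurationError, PathwayGraph, Protein

_MAX_RETRIES = 100


def _sample_route1(
    universe_ids: list[str],
    templates: list[tuple[int, int]],
    rng: np.random.Generator,
    neg_id: str,
) -> PathwayGraph:
    # joint (|V|, |E|) template; resample if |E| infeasible without self-loops
    for _ in range(_MAX_RETRIES):
        nv, ne = templates[int(rng.integers(len(templates)))]
        if ne <= nv * (nv - 1):
            break
    else:
        raise ConfigurationError("no feasible (|V|, |E|) template without self-loops")
    vertices = [universe_ids[i] for i in rng.choice(len(universe_ids), size=nv, replace=False)]
    pairs = [(a, b) for a in vertices for b in vertices if a != b]
    chosen = rng.choice(len(pairs), size=ne, replace=False)
    arcs = [pairs[c] for c in sorted(chosen)]
    return PathwayGraph(id=neg_id, vertices=vertices, arcs=arcs, label="negative")


def route1_random(
    universe: list[Protein],
    positives: list[PathwayGraph],
    ratio_half: int,
    seed: int,
) -> list[PathwayGraph]:
    """``ratio_half`` × |positives| random digraphs sized like the positives."""
    if not positives:
        raise ConfigurationError("route 1 requires at least one positive pathway")
    rng = np.random.default_rng(seed)
    universe_ids = [p.id for p in universe]
    templates = [(g.n_vertices, g.n_arcs) for g in positives]
    return [
        _sample_route1(universe_ids, templates, rng, f"neg1_{k:05d}")
        for k in range(ratio_half * len(positives))
    ]


def _sample_route2(
    universe_ids: list[str],
    positives: list[PathwayGraph],
    rng: np.random.Generator,
    neg_id: str,
) -> PathwayGraph:
    source = positives[int(rng.integers(len(positives)))]
    n = source.n_vertices
    n_replace = math.ceil(n / 2)
    outside = [pid for pid in universe_ids if pid not in set(source.vertices)]
    if len(outside) < n_replace:
        raise ConfigurationError(
            f"universe too small to replace {n_replace} proteins of {source.id}"
        )
    replace_pos = rng.choice(n, size=n_replace, replace=False)
    replacements = [outside[i] for i in rng.choice(len(outside), size=n_replace, replace=False)]
    new_vertices = list(source.vertices)
    for pos, new in zip(replace_pos, replacements):
        new_vertices[pos] = new
    # arcs carried over as position-indexed pairs
    index = {v: i for i, v in enumerate(source.vertices)}
    arcs = [(new_vertices[index[t]], new_vertices[index[h]]) for t, h in source.arcs]
    return PathwayGraph(
        id=neg_id, vertices=new_vertices, arcs=arcs, label="negative", source_id=source.id
    )


def route2_replace(
    universe: list[Protein],
    positives: list[PathwayGraph],
    ratio_half: int,
    seed: int,
) -> list[PathwayGraph]:
    """``ratio_half`` × |positives| half-substituted copies of the positives."""
    if not positives:
        raise ConfigurationError("route 2 requires at least one positive pathway")
    rng = np.random.default_rng(seed)
    universe_ids = [p.id for p in universe]
    return [
        _sample_route2(universe_ids, positives, rng, f"neg2_{k:05d}")
        for k in range(ratio_half * len(positives))
    ]


def generate_negatives(
    universe: list[Protein],
    positives: list[PathwayGraph],
    ratio: int = 100,
    seed: int = 0,
) -> list[PathwayGraph]:
    """Exactly ``ratio`` × |positives| deduplicated negatives.

    The total is split evenly between the two routes (odd remainder to
    route 1).  A candidate whose (vertex set, arc set) collides with a
    positive or an earlier negative is discarded and regenerated, up to
    100 attempts each.
    """
    if ratio < 1:
        raise ConfigurationError("ratio must be >= 1")
    n_total = ratio * len(positives)
    n_route2 = n_total // 2
    n_route1 = n_total - n_route2
    rng = np.random.default_rng(seed)
    universe_ids = [p.id for p in universe]
    templates = [(g.n_vertices, g.n_arcs) for g in positives]

    seen = {g.canonical_form() for g in positives}
    negatives: list[PathwayGraph] = []
    for route, count, sampler in (
        (1, n_route1, lambda nid: _sample_route1(universe_ids, templates, rng, nid)),
        (2, n_route2, lambda nid: _sample_route2(universe_ids, positives, rng, nid)),
    ):
        for k in range(count):
            neg_id = f"neg{route}_{k:05d}"
            for _ in range(_MAX_RETRIES):
                candidate = sampler(neg_id)
                form = candidate.canonical_form()
                if form not in seen:
                    seen.add(form)
                    negatives.append(candidate)
                    break
            else:
                raise ConfigurationError(
                    f"could not generate a unique route-{route} negative after {_MAX_RETRIES} tries"
                )
    return negatives
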