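"""Annotation-vector similarity: the arc-weight ("likelihood") function.

Each protein is a binary vector over D annotation terms (GO-style flat
hits, no DAG semantics).  The likelihood that two proteins interact is the
cosine of their annotation vectors; it weights every arc of a pathway
graph and every pair inside the neighborhood complete graphs used by the
local-density features.  When either vector is all-zero the similarity is
defined as 0 ("no evidence of relatedness").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, PathwayGraph, Protein


def likelihood(pi: Protein, pj: Protein) -> float:
    """Cosine similarity of two proteins' binary annotation vectors.

    Returns dot(Pi, Pj) / (||Pi|| * ||Pj||), or 0.0 when either vector is
    all-zero.  Raises on dimension mismatch.
    """
    a = pi.annotation
    b = pj.annotation
    if a.shape != b.shape:
        raise ConfigurationError(
            f"annotation dimension mismatch: {pi.id} has {a.size}, {pj.id} has {b.size}"
        )
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 or nb == 0:
        return 0.0
    dot = int((a & b).sum())
    return dot / (np.sqrt(na) * np.sqrt(nb))


def similarity_matrix(proteins: list[Protein]) -> np.ndarray:
    """Pairwise cosine-similarity matrix for a list of proteins.

    Vectorised equivalent of :func:`likelihood` over all pairs; rows with
    all-zero annotations yield 0 similarity to everything (including
    themselves).
    """
    if not proteins:
        return np.zeros((0, 0))
    mat = np.stack([p.annotation for p in proteins]).astype(float)
    norms = np.sqrt(mat.sum(axis=1))
    dots = mat @ mat.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = dots / np.outer(norms, norms)
    sims[~np.isfinite(sims)] = 0.0
    return np.clip(sims, 0.0, 1.0)


@dataclass
class SimilarityCache:
    """Symmetric cache of pairwise likelihoods, keyed by unordered id pair."""

    proteins: dict[str, Protein]
    _cache: dict[frozenset, float] = field(default_factory=dict)

    def __call__(self, id_a: str, id_b: str) -> float:
        key = frozenset((id_a, id_b))
        if key not in self._cache:
            try:
                pa = self.proteins[id_a]
                pb = self.proteins[id_b]
            except KeyError as exc:
                raise ConfigurationError(f"unknown protein id {exc.args[0]!r}") from exc
            self._cache[key] = likelihood(pa, pb)
        return self._cache[key]


def weight_graph(g: PathwayGraph, proteins: dict[str, Protein]) -> PathwayGraph:
    """Set every arc weight of ``g`` to the likelihood of its endpoints.

    Returns ``g`` (mutated in place) with weights in [0, 1]; raises naming
    the offending vertex if one cannot be resolved to a protein.
    """
    for v in g.vertices:
        if v not in proteins:
            raise ConfigurationError(f"pathway {g.id}: vertex {v!r} has no protein record")
    cache = SimilarityCache(proteins)
    g.weights = {(t, h): cache(t, h) for t, h in g.arcs}
    return g


def read_annotation_tsv(path, dim: int) -> dict[str, np.ndarray]:
    """Read sparse annotation hits: ``protein_id<TAB>i,j,k`` (term indices).

    A protein with no hits has an empty second column.  Returns dense 0/1
    vectors of length ``dim``.
    """
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            pid = parts[0]
            vec = np.zeros(dim, dtype=np.uint8)
            if len(parts) > 1 and parts[1]:
                idx = [int(tok) for tok in parts[1].split(",")]
                if idx and (min(idx) < 0 or max(idx) >= dim):
                    raise ConfigurationError(f"{pid}: annotation index outside [0, {dim})")
                vec[idx] = 1
            out[pid] = vec
    return out


def write_annotation_tsv(path, proteins: list[Protein]) -> None:
    """Inverse of :func:`read_annotation_tsv`."""
    with open(path, "w") as fh:
        for p in proteins:
            hits = ",".join(str(i) for i in p.annotation_hits)
            fh.write(f"{p.id}\t{hits}\n")
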