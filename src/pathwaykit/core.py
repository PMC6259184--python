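"""Domain types shared by all pipeline stages, and the canonical feature registry.

A *protein-forming system* is a directed graph over proteins, each arc
weighted by the annotation similarity of its endpoints.  Every pathway is
summarised by a fixed, ordered vector of 352 features: 88 computed from the
weighted digraph and 264 aggregated from per-protein biochemical and
physicochemical descriptors.  The registry built here fixes the name and
order of every slot once, so that feature matrices, rankings and reports
are comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical 20-residue amino-acid alphabet, in fixed order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Secondary-structure class labels (helix, strand, coil).
SS_CLASSES = ("H", "E", "C")

#: Solvent-accessibility class labels (hidden, exposed).
ACC_CLASSES = ("H", "E")

#: Three-class labels used for the physicochemical property pseudo-sequences
#: (polar, neutral, hydrophobic — reused as generic class tags for volume,
#: polarity and polarizability as well).
PNH_CLASSES = ("P", "N", "H")

#: Group-10 physicochemical properties, in registry order.
PHYSCHEM_PROPERTIES = (
    "hydrophobicity",
    "normalized_vdw_volume",
    "polarity",
    "polarizability",
)

#: Quantile labels for the CTD distribution descriptor (the "first"
#: occurrence is labelled 0.0; the last 1.0).
DISTRIBUTION_QUANTILES = ("0.0", "0.25", "0.5", "0.75", "1.0")

#: Expected feature count per group id 1..13.
GROUP_SIZES = {
    1: 2, 2: 8, 3: 4, 4: 7, 5: 6, 6: 6, 7: 12, 8: 3, 9: 40,
    10: 168, 11: 14, 12: 42, 13: 40,
}

N_GRAPH_FEATURES = 88
N_BIO_FEATURES = 264
N_FEATURES = N_GRAPH_FEATURES + N_BIO_FEATURES  # 352

#: Per-protein biological descriptor count (4x21 physicochemical CTD
#: + 7 accessibility + 21 secondary structure + 20 amino-acid composition).
N_PROTEIN_DESCRIPTORS = 132


class ConfigurationError(ValueError):
    """Raised when a configuration or input violates a documented contract."""


@dataclass
class Protein:
    """One protein: identifier, sparse binary annotation vector, sequence,
    and same-length secondary-structure and solvent-accessibility strings.

    ``annotation`` is a dense 0/1 ``uint8`` vector over ``D`` annotation
    terms; all proteins in one dataset share the same ``D``.
    """

    id: str
    annotation: np.ndarray
    sequence: str
    ss_string: str
    acc_string: str

    def __post_init__(self) -> None:
        self.annotation = np.asarray(self.annotation, dtype=np.uint8)
        if self.annotation.ndim != 1 or self.annotation.size < 1:
            raise ConfigurationError(f"{self.id}: annotation must be a nonempty 1-D vector")
        if not np.isin(self.annotation, (0, 1)).all():
            raise ConfigurationError(f"{self.id}: annotation entries must be 0/1")
        if len(self.sequence) < 1:
            raise ConfigurationError(f"{self.id}: empty sequence")
        if len(self.ss_string) != len(self.sequence) or len(self.acc_string) != len(self.sequence):
            raise ConfigurationError(
                f"{self.id}: ss/acc strings must match sequence length {len(self.sequence)}"
            )

    @property
    def annotation_hits(self) -> np.ndarray:
        """Indices of annotation terms this protein hits."""
        return np.flatnonzero(self.annotation)


@dataclass
class PathwayGraph:
    """A directed pathway graph over protein identifiers.

    ``arcs`` are ordered (tail, head) pairs; duplicates are collapsed on
    construction, self-loops are retained.  ``weights`` maps each arc to a
    real in [0, 1] (annotation-similarity of its endpoints once weighted).
    """

    id: str
    vertices: list[str]
    arcs: list[tuple[str, str]]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    label: str = "positive"
    #: id of the positive this graph was derived from (route-2 negatives)
    source_id: str | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for arc in self.arcs:
            arc = (str(arc[0]), str(arc[1]))
            if arc not in seen:
                seen.add(arc)
                deduped.append(arc)
        self.arcs = deduped
        vset = set(self.vertices)
        if len(vset) != len(self.vertices):
            raise ConfigurationError(f"{self.id}: duplicate vertices")
        for tail, head in self.arcs:
            if tail not in vset or head not in vset:
                raise ConfigurationError(f"{self.id}: arc ({tail},{head}) endpoint not a vertex")
        for arc, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise ConfigurationError(f"{self.id}: weight {w} for arc {arc} outside [0,1]")
        if self.label not in ("positive", "negative"):
            raise ConfigurationError(f"{self.id}: label must be positive/negative")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def validate_dataset_admissible(self) -> None:
        """Pathways with fewer than three proteins are excluded from datasets."""
        if self.n_vertices < 3:
            raise ConfigurationError(
                f"{self.id}: pathways with fewer than 3 proteins are excluded"
            )

    def canonical_form(self) -> tuple:
        """Hashable (vertex set, arc set) signature used for deduplication."""
        return (frozenset(self.vertices), frozenset(self.arcs))


def _ctd3_descriptor_names(classes: tuple[str, str, str]) -> list[str]:
    """21 CTD descriptor names for a three-class property."""
    c1, c2, c3 = classes
    names = [f"composition_{c}" for c in classes]
    names += [f"transition_{c1}{c2}", f"transition_{c1}{c3}", f"transition_{c2}{c3}"]
    for c in classes:
        names += [f"distribution_{c}-{q}" for q in DISTRIBUTION_QUANTILES]
    return names


def _ctd2_descriptor_names(classes: tuple[str, str]) -> list[str]:
    """7 CTD descriptor names for a two-class property (first class only)."""
    c1, c2 = classes
    names = [f"composition_{c1}", f"transition_{c1}{c2}"]
    names += [f"distribution_{c1}-{q}" for q in DISTRIBUTION_QUANTILES]
    return names


def protein_descriptor_names() -> list[str]:
    """The 132 per-protein biological descriptor names, in canonical order."""
    names: list[str] = []
    for prop in PHYSCHEM_PROPERTIES:
        names += [f"{prop}_{d}" for d in _ctd3_descriptor_names(PNH_CLASSES)]
    names += [f"solvent_accessibility_{d}" for d in _ctd2_descriptor_names(ACC_CLASSES)]
    names += [f"secondary_structure_{d}" for d in _ctd3_descriptor_names(SS_CLASSES)]
    names += [f"AA_composition_{aa}" for aa in AMINO_ACIDS]
    assert len(names) == N_PROTEIN_DESCRIPTORS
    return names


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered list of (feature name, group id) fixing the 352-slot layout."""

    entries: tuple[tuple[str, int], ...]

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def groups(self) -> list[int]:
        return [gid for _, gid in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def group_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for _, gid in self.entries:
            sizes[gid] = sizes.get(gid, 0) + 1
        return sizes

    def index(self, name: str) -> int:
        return self.names.index(name)


def build_registry() -> FeatureRegistry:
    """Build the canonical 352-entry feature registry.

    Order: graph groups 1–9 (88 features) followed by biological groups
    10–13 (264 features, one mean and one max per per-protein descriptor).
    """
    entries: list[tuple[str, int]] = []

    entries += [("graph_size", 1), ("graph_density", 1)]
    for side in ("in", "out"):
        entries += [(f"{side}_degree_{s}", 2) for s in ("mean", "variance", "median", "max")]
    for subset in ("all", "nonzero"):
        entries += [(f"edge_weight_{subset}_{s}", 3) for s in ("mean", "variance")]
    entries += [(f"topological_change_0.{i}", 4) for i in range(1, 8)]
    for side in ("in", "out"):
        entries += [(f"{side}_degree_correlation_{s}", 5) for s in ("mean", "variance", "max")]
    for side in ("in", "out"):
        entries += [(f"{side}_clustering_{s}", 6) for s in ("mean", "variance", "max")]
    for kind in ("in_in", "in_out", "out_in", "out_out"):
        entries += [(f"topological_{kind}_{s}", 7) for s in ("mean", "variance", "max")]
    entries += [(f"singular_value_{i}", 8) for i in (1, 2, 3)]
    for side in ("in", "out"):
        for w in range(10):
            for agg in ("mean", "max"):
                entries.append((f"{side}_local_density_0.{w}_{agg}", 9))

    bio_groups = [10] * 84 + [11] * 7 + [12] * 21 + [13] * 20
    for desc, gid in zip(protein_descriptor_names(), bio_groups):
        for agg in ("mean", "max"):
            entries.append((f"{desc}_{agg}", gid))

    registry = FeatureRegistry(tuple(entries))
    assert len(registry) == N_FEATURES
    assert registry.group_sizes() == GROUP_SIZES
    assert len(set(registry.names)) == N_FEATURES
    return registry


@dataclass
class FeatureVector:
    """A named, registry-aligned 352-slot real vector for one pathway."""

    values: np.ndarray
    registry: FeatureRegistry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.registry),):
            raise ConfigurationError(
                f"feature vector length {self.values.size} != registry length {len(self.registry)}"
            )
        if not np.isfinite(self.values).all():
            raise ConfigurationError("feature vector contains non-finite values")

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.registry.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.registry.index(name)])
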