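"""The 264 biological features (groups 10-13).

Per protein, 132 descriptors are computed (Composition-Transition-
Distribution encodings of four physicochemical property pseudo-sequences,
of the solvent-accessibility string and of the secondary-structure string,
plus the 20 amino-acid composition percentages).  Descriptors are z-score
standardized against a declared reference population of proteins, then
each pathway contributes the mean and max of its member proteins' values
— 132 x 2 = 264 features.

The three-class residue groupings for hydrophobicity, normalized van der
Waals volume, polarity and polarizability follow the standard CTD scheme
(polar / neutral / hydrophobic and the analogous low / medium / high
classes), shipped as module constants and overridable via a YAML file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .core import (
    ACC_CLASSES,
    AMINO_ACIDS,
    ConfigurationError,
    PNH_CLASSES,
    PathwayGraph,
    Protein,
    SS_CLASSES,
    protein_descriptor_names,
)


@dataclass(frozen=True)
class PropertyAlphabet:
    """A property's class labels and (optionally) its residue→class map.

    ``residue_map`` covers all 20 residues for sequence-derived properties;
    it is ``None`` for properties whose pseudo-sequence is supplied
    directly (secondary structure, solvent accessibility).
    """

    name: str
    classes: tuple[str, ...]
    residue_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ConfigurationError(f"{self.name}: class labels must be distinct")
        if self.residue_map is not None:
            missing = set(AMINO_ACIDS) - set(self.residue_map)
            if missing:
                raise ConfigurationError(f"{self.name}: residue_map misses {sorted(missing)}")
            bad = set(self.residue_map.values()) - set(self.classes)
            if bad:
                raise ConfigurationError(f"{self.name}: unknown classes {sorted(bad)}")


def _alphabet_from_groups(name: str, groups: dict[str, str]) -> PropertyAlphabet:
    """Build an alphabet from {class label: residue string} groups."""
    rmap = {res: cls for cls, residues in groups.items() for res in residues}
    return PropertyAlphabet(name, tuple(groups.keys()), rmap)


# Standard three-class CTD residue groupings (P = polar/low, N = neutral/
# medium, H = hydrophobic/high for the respective physical scale).
DEFAULT_PROPERTY_GROUPS: dict[str, dict[str, str]] = {
    "hydrophobicity": {"P": "RKEDQN", "N": "GASTPHY", "H": "CLVIMFW"},
    "normalized_vdw_volume": {"P": "GASCTPD", "N": "NVEQIL", "H": "MHKFRYW"},
    "polarity": {"P": "LIFWCMVY", "N": "PATGS", "H": "HQRKNED"},
    "polarizability": {"P": "GASDT", "N": "CPNVEQIL", "H": "KMHFRYW"},
}


def default_alphabets() -> dict[str, PropertyAlphabet]:
    """The four physicochemical property alphabets with default groupings."""
    return {
        name: _alphabet_from_groups(name, groups)
        for name, groups in DEFAULT_PROPERTY_GROUPS.items()
    }


def load_alphabets(path) -> dict[str, PropertyAlphabet]:
    """Load property groupings from a YAML file of {property: {class: residues}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: _alphabet_from_groups(name, groups) for name, groups in raw.items()}


SS_ALPHABET = PropertyAlphabet("secondary_structure", SS_CLASSES)
ACC_ALPHABET = PropertyAlphabet("solvent_accessibility", ACC_CLASSES)


def pseudo_sequence(seq: str, alphabet: PropertyAlphabet, *, skip_unknown: bool = False) -> str:
    """Substitute each residue of ``seq`` by its property class label."""
    if alphabet.residue_map is None:
        raise ConfigurationError(f"{alphabet.name}: no residue map; pseudo-sequence is an input")
    out = []
    for res in seq:
        cls = alphabet.residue_map.get(res)
        if cls is None:
            if skip_unknown:
                continue
            raise ConfigurationError(f"unknown residue {res!r} for {alphabet.name}")
        out.append(cls)
    return "".join(out)


def ctd(class_string: str, classes: tuple[str, ...]) -> np.ndarray:
    """Composition-Transition-Distribution descriptors of a class string.

    Composition: percentage of each class.  Transition: per unordered class
    pair, 100 x (adjacent positions forming that pair) / (L - 1), 0 when
    L = 1.  Distribution: per class with m occurrences, the 1-based
    position of the ceil(q*m)-th occurrence as a percentage of L, for the
    first occurrence and q = 0.25, 0.5, 0.75, 1.0 (all five 0 when m = 0).

    For two-class properties only the first class's composition and
    distribution are reported (1 + 1 + 5 = 7 descriptors); three-class
    properties yield 3 + 3 + 15 = 21.
    """
    length = len(class_string)
    if length == 0:
        raise ConfigurationError("CTD requires a nonempty class string")
    unknown = set(class_string) - set(classes)
    if unknown:
        raise ConfigurationError(f"class string contains unknown labels {sorted(unknown)}")

    counts = {c: class_string.count(c) for c in classes}
    two_class = len(classes) == 2

    comp_classes = classes[:1] if two_class else classes
    comp = [100.0 * counts[c] / length for c in comp_classes]

    pairs = (
        [(classes[0], classes[1])]
        if two_class
        else [(classes[0], classes[1]), (classes[0], classes[2]), (classes[1], classes[2])]
    )
    trans = []
    for a, b in pairs:
        if length == 1:
            trans.append(0.0)
            continue
        hits = sum(
            1
            for x, y in zip(class_string, class_string[1:])
            if (x, y) in ((a, b), (b, a))
        )
        trans.append(100.0 * hits / (length - 1))

    dist = []
    for c in comp_classes:
        m = counts[c]
        if m == 0:
            dist += [0.0] * 5
            continue
        positions = [i + 1 for i, ch in enumerate(class_string) if ch == c]
        for q in (1 / m, 0.25, 0.5, 0.75, 1.0):
            k = max(1, math.ceil(q * m))
            dist.append(100.0 * positions[k - 1] / length)

    return np.array(comp + trans + dist)


def aa_composition(seq: str) -> np.ndarray:
    """Percentage of each of the 20 amino acids in the sequence."""
    if not seq:
        raise ConfigurationError("empty sequence")
    return np.array([100.0 * seq.count(aa) / len(seq) for aa in AMINO_ACIDS])


DESCRIPTOR_NAMES = protein_descriptor_names()


def protein_descriptors(
    protein: Protein, alphabets: dict[str, PropertyAlphabet] | None = None
) -> np.ndarray:
    """The 132 raw per-protein biological descriptors in canonical order."""
    alphabets = alphabets or default_alphabets()
    parts = []
    for name in DEFAULT_PROPERTY_GROUPS:
        alpha = alphabets[name]
        parts.append(ctd(pseudo_sequence(protein.sequence, alpha), alpha.classes))
    parts.append(ctd(protein.acc_string, ACC_ALPHABET.classes))
    parts.append(ctd(protein.ss_string, SS_ALPHABET.classes))
    parts.append(aa_composition(protein.sequence))
    vec = np.concatenate(parts)
    assert vec.size == len(DESCRIPTOR_NAMES)
    return vec


@dataclass
class StandardizationStats:
    """Per-descriptor mean and population standard deviation of a
    declared reference protein population."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if (self.std < 0).any():
            raise ConfigurationError("negative standard deviation")


def compute_standardization(matrix: np.ndarray) -> StandardizationStats:
    """Fit standardization stats on a (proteins x descriptors) matrix."""
    return StandardizationStats(mean=matrix.mean(axis=0), std=matrix.std(axis=0))


def standardize(matrix: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """Z-score each column; constant columns (zero sd) map to 0."""
    std = np.where(stats.std == 0, 1.0, stats.std)
    out = (matrix - stats.mean) / std
    out[:, stats.std == 0] = 0.0
    return out


def aggregate_pathway(g: PathwayGraph, protein_rows: dict[str, np.ndarray]) -> np.ndarray:
    """Mean and max over the pathway's proteins, per descriptor.

    ``protein_rows`` maps protein id to its (standardized) 132-descriptor
    row.  Output has 264 entries: for each descriptor, its mean then its
    max, in registry order.
    """
    try:
        stack = np.stack([protein_rows[v] for v in g.vertices])
    except KeyError as exc:
        raise ConfigurationError(f"pathway {g.id}: missing protein {exc.args[0]!r}") from exc
    if stack.shape[1] != len(DESCRIPTOR_NAMES):
        raise ConfigurationError(
            f"expected {len(DESCRIPTOR_NAMES)} descriptors per protein, got {stack.shape[1]}"
        )
    means = stack.mean(axis=0)
    maxes = stack.max(axis=0)
    out = np.empty(2 * means.size)
    out[0::2] = means
    out[1::2] = maxes
    return out
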