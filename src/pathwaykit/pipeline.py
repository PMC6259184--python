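"""End-to-end orchestration: generate → weight → featurize → rank → IFS.

Also houses the file formats the pipeline reads and writes (edge-list
TSV, dataset manifest, FASTA + structure-string TSV, feature matrix,
ranking and IFS tables) and a minimal KGML-subset reader (entry/relation
elements only).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from lxml import etree

from .classify import IFSResult, ifs
from .core import (
    ConfigurationError,
    FeatureRegistry,
    PathwayGraph,
    Protein,
    build_registry,
)
from .negatives import generate_negatives
from .protein_features import (
    aggregate_pathway,
    compute_standardization,
    protein_descriptors,
    standardize,
)
from .graph_features import graph_feature_vector
from .selection import FeatureRanking, discretize, maxrel_slice, mrmr_rank
from .similarity import SimilarityCache, weight_graph, write_annotation_tsv
from .synthetic import UniverseConfig, generate_positive_pathways, generate_universe

logger = logging.getLogger("pathwaykit")


# ---------------------------------------------------------------------------
# file formats

def write_pathway_tsv(g: PathwayGraph, path) -> None:
    """Edge-list TSV: one ``# vertex:`` header line per vertex (so isolated
    vertices survive a round-trip), then one ``tail<TAB>head`` line per arc."""
    with open(path, "w") as fh:
        for v in g.vertices:
            fh.write(f"# vertex: {v}\n")
        for tail, head in g.arcs:
            fh.write(f"{tail}\t{head}\n")


def read_pathway_tsv(path, pathway_id: str | None = None, label: str = "positive") -> PathwayGraph:
    vertices: list[str] = []
    arcs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# vertex:"):
                vertices.append(line.split(":", 1)[1].strip())
            elif line.startswith("#"):
                continue
            else:
                tail, head = line.split("\t")
                arcs.append((tail, head))
    if not vertices:
        vertices = sorted({v for arc in arcs for v in arc})
    gid = pathway_id or Path(path).stem
    return PathwayGraph(id=gid, vertices=vertices, arcs=arcs, label=label)


def write_manifest(pathways: list[PathwayGraph], path) -> None:
    pd.DataFrame(
        [
            {"id": g.id, "label": g.label, "n_vertices": g.n_vertices, "n_arcs": g.n_arcs}
            for g in pathways
        ]
    ).to_csv(path, sep="\t", index=False)


def write_universe(proteins: list[Protein], outdir: Path) -> None:
    """FASTA for sequences; TSVs for annotations and ss/acc strings."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(records, str(outdir / "universe.fasta"), "fasta")
    write_annotation_tsv(outdir / "annotations.tsv", proteins)
    pd.DataFrame(
        [{"id": p.id, "ss": p.ss_string, "acc": p.acc_string} for p in proteins]
    ).to_csv(outdir / "structures.tsv", sep="\t", index=False)


def read_kgml_subset(path, label: str = "positive") -> PathwayGraph:
    """Parse a minimal KGML dialect into a pathway graph.

    Entries of type ``protein`` or ``gene`` become vertices (keyed by
    their entry id); ``relation`` elements become directed arcs
    entry1 → entry2.  Other entry types (group, compound, map, ...) are
    skipped with a logged warning, as are relations touching them.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ConfigurationError(f"malformed KGML {path}: {exc}") from exc
    root = tree.getroot()
    vertices: list[str] = []
    for entry in root.iter("entry"):
        etype = entry.get("type")
        eid = entry.get("id")
        if etype in ("protein", "gene"):
            vertices.append(eid)
        else:
            logger.warning("KGML %s: skipping entry %s of type %r", path, eid, etype)
    vset = set(vertices)
    arcs = []
    for rel in root.iter("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 in vset and e2 in vset:
            arcs.append((e1, e2))
        else:
            logger.warning("KGML %s: skipping relation %s->%s (non-protein endpoint)", path, e1, e2)
    name = root.get("name") or Path(path).stem
    return PathwayGraph(id=name, vertices=vertices, arcs=arcs, label=label)


def write_ranking_tsv(ranking: FeatureRanking, registry: FeatureRegistry, path, which: str) -> None:
    """Ranking TSV: rank, feature name, group id, score."""
    if which == "maxrel":
        order = ranking.maxrel_order
        scores = [float(ranking.relevance[i]) for i in order]
    elif which == "mrmr":
        order = ranking.mrmr_order
        scores = ranking.mrmr_scores
    else:
        raise ConfigurationError(f"unknown ranking {which!r}")
    groups = registry.groups
    pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "feature": [ranking.feature_names[i] for i in order],
            "group_id": [groups[i] for i in order],
            "score": scores,
        }
    ).to_csv(path, sep="\t", index=False)


def write_ifs(result: IFSResult, tsv_path, png_path=None) -> None:
    result.to_frame().to_csv(tsv_path, sep="\t", index=False, float_format="%.6f")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(result.prefix_sizes, result.positive_accuracy, label="positive accuracy")
        ax.plot(result.prefix_sizes, result.total_accuracy, label="total accuracy", alpha=0.6)
        ax.axvline(result.optimal_size, color="gray", ls="--", lw=0.8)
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("jackknife accuracy")
        ax.legend()
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# featurization

def featurize_dataset(
    pathways: list[PathwayGraph],
    proteins: dict[str, Protein],
    registry: FeatureRegistry | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Full 352-column feature matrix for a weighted dataset.

    Weights every pathway's arcs by annotation similarity, computes the 88
    graph features, and aggregates per-protein biological descriptors
    (standardized against the proteins appearing anywhere in the dataset).
    Returns (matrix, pathway ids, labels with 1 = positive).
    """
    registry = registry or build_registry()
    for g in pathways:
        g.validate_dataset_admissible()

    used_ids = sorted({v for g in pathways for v in g.vertices})
    missing = [pid for pid in used_ids if pid not in proteins]
    if missing:
        raise ConfigurationError(f"proteins missing from universe: {missing[:5]}")

    raw = np.stack([protein_descriptors(proteins[pid]) for pid in used_ids])
    stats = compute_standardization(raw)
    std_rows = dict(zip(used_ids, standardize(raw, stats)))

    cache = SimilarityCache(proteins)
    rows = []
    for g in pathways:
        weight_graph(g, proteins)
        graph_part = graph_feature_vector(g, cache)
        bio_part = aggregate_pathway(g, std_rows)
        rows.append(np.concatenate([graph_part, bio_part]))
    matrix = np.stack(rows)
    labels = np.array([1 if g.label == "positive" else 0 for g in pathways])
    return matrix, [g.id for g in pathways], labels


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """Full pipeline configuration (synthesis + analysis parameters)."""

    universe: UniverseConfig = field(default_factory=UniverseConfig)
    negative_ratio: int = 100
    max_prefix: int = 50
    mrmr_criterion: str = "difference"
    metric: str = "cosine"
    maxrel_fraction: float = 0.10
    write_pathway_files: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        u = raw.pop("universe", {})
        for key in ("seq_len_range", "pathway_size_range"):
            if key in u:
                u[key] = tuple(u[key])   # YAML serializes tuples as lists
        ucfg = UniverseConfig(**u)
        return cls(universe=ucfg, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["universe"]["seq_len_range"] = list(self.universe.seq_len_range)
        d["universe"]["pathway_size_range"] = list(self.universe.pathway_size_range)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    registry: FeatureRegistry
    universe: list[Protein]
    pathways: list[PathwayGraph]
    feature_matrix: np.ndarray
    pathway_ids: list[str]
    labels: np.ndarray
    ranking: FeatureRanking
    ifs_result: IFSResult
    summary: dict


def _group_distribution(names: list[str], registry: FeatureRegistry) -> dict:
    idx = {name: gid for name, gid in registry.entries}
    per_group: dict[int, int] = {}
    for name in names:
        per_group[idx[name]] = per_group.get(idx[name], 0) + 1
    n_graph = sum(c for g, c in per_group.items() if g <= 9)
    return {
        "per_group": {int(k): v for k, v in sorted(per_group.items())},
        "n_graph": n_graph,
        "n_biological": len(names) - n_graph,
    }


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute the full analysis and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = build_registry()

    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        logger.info("stage %s (t=%.1fs)", name, time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        stage("synthesize universe")
        universe = generate_universe(config.universe)
        proteins = {p.id: p for p in universe}
        write_universe(universe, outdir)

        stage("generate positive pathways")
        positives = generate_positive_pathways(universe, config.universe)

        stage("generate negatives")
        negatives = generate_negatives(
            universe, positives, ratio=config.negative_ratio, seed=config.universe.seed + 1
        )
        # negatives first: under the lowest-index NN tie rule, fully tied
        # distances resolve to the majority class
        pathways = negatives + positives
        write_manifest(pathways, outdir / "manifest.tsv")
        if config.write_pathway_files:
            pdir = outdir / "pathways"
            pdir.mkdir(exist_ok=True)
            for g in pathways:
                write_pathway_tsv(g, pdir / f"{g.id}.tsv")

        stage("featurize")
        matrix, ids, labels = featurize_dataset(pathways, proteins, registry)
        frame = pd.DataFrame(matrix, columns=registry.names)
        frame.insert(0, "pathway_id", ids)
        frame.insert(1, "label", ["positive" if y else "negative" for y in labels])
        frame.to_csv(outdir / "features.tsv", sep="\t", index=False, float_format="%.6g")

        stage("rank features")
        table = discretize(matrix, registry.names, labels)
        ranking = mrmr_rank(table, criterion=config.mrmr_criterion)
        write_ranking_tsv(ranking, registry, outdir / "maxrel.tsv", "maxrel")
        write_ranking_tsv(ranking, registry, outdir / "mrmr.tsv", "mrmr")

        stage("incremental feature selection")
        result = ifs(
            matrix,
            labels,
            ranking.mrmr_order,
            max_prefix=config.max_prefix,
            metric=config.metric,
            feature_names=registry.names,
        )
        write_ifs(result, outdir / "ifs.tsv", outdir / "ifs.png")
    except Exception as exc:   # annotate which stage died
        raise RuntimeError(f"pipeline failed at stage {current['stage']!r}: {exc}") from exc

    top_slice = maxrel_slice(ranking, config.maxrel_fraction)
    pos_acc, neg_acc, tot_acc = result.optimal_metrics
    summary = {
        "config": config.to_dict(),
        "n_positive": len(positives),
        "n_negative": len(negatives),
        "n_total": len(pathways),
        "n_features": len(registry),
        "maxrel_top_slice": {
            "size": len(top_slice),
            "features": top_slice,
            "distribution": _group_distribution(top_slice, registry),
        },
        "ifs": {
            "optimal_size": result.optimal_size,
            "positive_accuracy": pos_acc,
            "negative_accuracy": neg_acc,
            "total_accuracy": tot_acc,
            "optimal_features": result.optimal_features,
            "distribution": _group_distribution(result.optimal_features, registry),
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    stage("done")
    return PipelineResult(
        config=config,
        registry=registry,
        universe=universe,
        pathways=pathways,
        feature_matrix=matrix,
        pathway_ids=ids,
        labels=labels,
        ranking=ranking,
        ifs_result=result,
        summary=summary,
    )
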