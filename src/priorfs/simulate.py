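"""Synthetic fixtures with planted structure for offline, end-to-end testing.

The generator emulates a normalized (log-like) expression study: Gaussian
per-gene noise with unit within-class standard deviation, a small set of
*informative* genes whose class means are shifted by a configurable effect
size, optional uniform missingness, an association knowledge base that
scores the planted genes high and a covered subset of null genes low, and
random pathway graphs with designated hub nodes plus one "signal" pathway
built from the planted genes.  Everything derives deterministically from the
spec seed, and `write_workspace` materializes the exact file dialects the
loaders read.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .knowledge import AssociationKB, NetworkKB, write_gmt

SIGNAL_PATHWAY = "pathway_signal"
DEFAULT_TERM = "condition"


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic fixtures.

    effect_size is the class-mean shift of informative genes in units of the
    within-class standard deviation (which is 1 by construction).
    """

    n_samples: int = 100
    n_genes: int = 1000
    n_classes: int = 2
    n_informative: int = 10
    effect_size: float = 2.0
    missing_rate: float = 0.0
    kb_signal_score: float = 0.9
    kb_noise_score: float = 0.1
    kb_coverage: float = 0.3  # fraction of null genes with a KB record
    n_pathways: int = 10
    pathway_size: int = 20
    hub_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        for name in ("missing_rate", "kb_coverage", "hub_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("kb_signal_score", "kb_noise_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_samples < 2 * self.n_classes or self.n_classes < 2:
            raise ValueError("need at least two classes with two samples each")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: which genes carry signal and how."""

    spec: SimulationSpec
    informative_genes: list[str]
    class_means: pd.DataFrame  # informative genes x class labels
    class_labels: list[str]


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _gene_ids(spec: SimulationSpec) -> list[str]:
    width = len(str(spec.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]


def _sample_ids(spec: SimulationSpec) -> list[str]:
    width = len(str(spec.n_samples))
    return [f"S{i:0{width}d}" for i in range(1, spec.n_samples + 1)]


def _balanced_labels(spec: SimulationSpec) -> pd.Series:
    classes = [f"class{c}" for c in range(spec.n_classes)]
    labels = [classes[i % spec.n_classes] for i in range(spec.n_samples)]
    return pd.Series(labels, index=_sample_ids(spec), name="condition")


def generate_expression(
    spec: SimulationSpec,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Class-structured Gaussian expression with planted informative genes.

    Each informative gene's class-c mean is ``sign * effect_size * c`` for a
    random per-gene sign, so adjacent classes differ by one effect size;
    null genes are pure N(0, 1) noise.  Missing entries are placed uniformly
    at ``missing_rate``.
    """
    rng = _rng(spec, 0)
    genes = _gene_ids(spec)
    labels = _balanced_labels(spec)
    classes = [f"class{c}" for c in range(spec.n_classes)]

    informative = sorted(rng.choice(spec.n_genes, spec.n_informative, replace=False))
    informative_genes = [genes[i] for i in informative]
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    class_means = pd.DataFrame(
        np.outer(signs * spec.effect_size, np.arange(spec.n_classes)),
        index=informative_genes,
        columns=classes,
    )

    X = rng.standard_normal((spec.n_genes, spec.n_samples))
    class_idx = labels.map({c: i for i, c in enumerate(classes)}).to_numpy()
    for row, gene in zip(informative, informative_genes):
        X[row] += class_means.loc[gene].to_numpy()[class_idx]

    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = np.where(mask, np.nan, X)

    values = pd.DataFrame(X, index=pd.Index(genes, name="gene_id"), columns=labels.index)
    truth = GroundTruth(spec, informative_genes, class_means, classes)
    return ExpressionDataset(values, labels), truth


def generate_association_kb(
    truth: GroundTruth, spec: SimulationSpec | None = None, term: str = DEFAULT_TERM
) -> AssociationKB:
    """Association KB scoring planted genes high and covered null genes low.

    All informative genes get a record near ``kb_signal_score``; a
    ``kb_coverage`` fraction of null genes gets one near ``kb_noise_score``.
    Jitter is uniform +/-0.05, clipped so scores stay in [0, 1].
    """
    spec = spec or truth.spec
    rng = _rng(spec, 1)
    genes = _gene_ids(spec)
    informative = set(truth.informative_genes)
    null_genes = [g for g in genes if g not in informative]
    n_cov = int(round(spec.kb_coverage * len(null_genes)))
    covered_null = sorted(
        np.array(null_genes)[rng.choice(len(null_genes), n_cov, replace=False)]
    ) if n_cov else []

    records = []
    for g in sorted(informative):
        s = spec.kb_signal_score + rng.uniform(-0.05, 0.05)
        records.append((term, g, float(np.clip(s, 0.0, 1.0))))
    for g in covered_null:
        s = spec.kb_noise_score + rng.uniform(-0.05, 0.05)
        records.append((term, g, float(np.clip(s, 0.0, 1.0))))
    df = pd.DataFrame(records, columns=["term", "gene", "score"])
    return AssociationKB(df, name="synthetic_kb")


def _pathway_graph(
    members: list[str], hub_fraction: float, rng: np.random.Generator
) -> nx.Graph:
    """Random graph with designated hubs wired to every other member."""
    g = nx.Graph()
    g.add_nodes_from(members)
    n = len(members)
    n_hubs = max(1, int(round(hub_fraction * n))) if n > 1 else 0
    hubs = list(rng.choice(members, size=n_hubs, replace=False)) if n_hubs else []
    for h in hubs:
        for other in members:
            if other != h:
                g.add_edge(h, other)
    # sparse random background so non-hub degrees vary
    non_hubs = [m for m in members if m not in set(hubs)]
    for i, a in enumerate(non_hubs):
        for b in non_hubs[i + 1 :]:
            if rng.random() < 2.0 / max(n, 2):
                g.add_edge(a, b)
    return g


def generate_network_kb(
    truth: GroundTruth, spec: SimulationSpec | None = None
) -> NetworkKB:
    """Random pathway graphs plus one signal pathway of planted genes.

    The signal pathway contains every informative gene topped up with random
    null genes to ``pathway_size``; the remaining ``n_pathways - 1`` pathways
    are random draws from the null genes.  Each pathway gets hub nodes wired
    to all other members (hub_fraction of the membership).
    """
    spec = spec or truth.spec
    rng = _rng(spec, 2)
    genes = _gene_ids(spec)
    informative = list(truth.informative_genes)
    null_genes = [g for g in genes if g not in set(informative)]

    pathways: dict[str, nx.Graph] = {}
    signal_members = list(informative)
    if len(signal_members) < spec.pathway_size:
        extra = rng.choice(
            len(null_genes), spec.pathway_size - len(signal_members), replace=False
        )
        signal_members += [null_genes[i] for i in sorted(extra)]
    pathways[SIGNAL_PATHWAY] = _pathway_graph(
        signal_members[: spec.pathway_size], spec.hub_fraction, rng
    )
    for k in range(spec.n_pathways - 1):
        idx = rng.choice(len(null_genes), spec.pathway_size, replace=False)
        members = [null_genes[i] for i in sorted(idx)]
        pathways[f"pathway_{k:02d}"] = _pathway_graph(members, spec.hub_fraction, rng)
    return NetworkKB(pathways, {p: "synthetic pathway" for p in pathways})


def generate_paired_dataset(
    ds_a: ExpressionDataset,
    truth: GroundTruth,
    shift: float = 0.0,
    seed_stream: int = 3,
) -> ExpressionDataset:
    """Second cohort: same planted structure, fresh noise, optional global shift.

    The gene set, class structure and informative-gene means match the first
    dataset; noise is redrawn and ``shift`` is added to every entry to
    emulate an un-harmonized cohort effect.
    """
    spec = truth.spec
    rng = _rng(spec, seed_stream)
    labels = _balanced_labels(spec)
    labels.index = [f"T{s[1:]}" for s in labels.index]
    classes = truth.class_labels
    class_idx = labels.map({c: i for i, c in enumerate(classes)}).to_numpy()

    genes = list(ds_a.gene_ids)
    X = rng.standard_normal((len(genes), spec.n_samples)) + shift
    gene_pos = {g: i for i, g in enumerate(genes)}
    for gene in truth.informative_genes:
        if gene in gene_pos:
            X[gene_pos[gene]] += truth.class_means.loc[gene].to_numpy()[class_idx]
    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = np.where(mask, np.nan, X)
    values = pd.DataFrame(X, index=pd.Index(genes, name="gene_id"), columns=labels.index)
    return ExpressionDataset(values, labels)


def write_workspace(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a complete runnable workspace of fixture files.

    Writes the expression matrix, sample metadata, association TSV, pathway
    GMT + edge list, an identity-style mapping table, a paired second
    cohort, and the ground-truth record; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = generate_expression(spec)
    kb = generate_association_kb(truth)
    net = generate_network_kb(truth)
    ds_b = generate_paired_dataset(ds, truth)

    paths = {
        "expression": out / "expression.tsv",
        "expression_b": out / "expression_b.tsv",
        "metadata": out / "metadata.tsv",
        "metadata_b": out / "metadata_b.tsv",
        "associations": out / "associations.tsv",
        "gmt": out / "pathways.gmt",
        "edges": out / "edges.tsv",
        "mapping": out / "mapping.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    ds.values.to_csv(paths["expression"], sep="\t")
    ds_b.values.to_csv(paths["expression_b"], sep="\t")
    for key, d in (("metadata", ds), ("metadata_b", ds_b)):
        pd.DataFrame(
            {"sample_id": d.sample_ids, "condition": d.labels.to_numpy()}
        ).to_csv(paths[key], sep="\t", index=False)
    kb.records.to_csv(paths["associations"], sep="\t", index=False)
    write_gmt(
        {name: sorted(net.member_genes(name)) for name in net.pathway_names},
        paths["gmt"],
    )
    edge_rows = [
        {"pathway": name, "gene_a": a, "gene_b": b}
        for name in net.pathway_names
        for a, b in sorted(tuple(sorted(e)) for e in net.pathways[name].edges)
    ]
    pd.DataFrame(edge_rows, columns=["pathway", "gene_a", "gene_b"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    pd.DataFrame(
        {"source_id": ds.gene_ids, "target_id": [f"SYM_{g}" for g in ds.gene_ids]}
    ).to_csv(paths["mapping"], sep="\t", index=False)
    record = {
        "spec": asdict(spec),
        "informative_genes": truth.informative_genes,
        "class_labels": truth.class_labels,
        "class_means": truth.class_means.to_dict(),
    }
    paths["ground_truth"].write_text(json.dumps(record, indent=1, sort_keys=True))
    return paths
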