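"""Local prior-knowledge backends: gene--term association scores and pathway networks.

Association knowledge bases hold `(term, gene, score)` records with scores in
[0, 1], the shape of gene--disease evidence exported by resources such as
OpenTargets or DisGeNET.  Network knowledge bases hold one undirected graph
per pathway (membership from a GMT file, edges from a per-pathway edge list),
the shape of KEGG / PathwayCommons exports.

The pathway-topology gene score implemented here rewards hub genes: a gene's
score is the mean, over the pathways containing it, of its fractional
percentile rank by degree within each pathway,

    s_i = ( sum_p pr_{p,i} ) / |P_i| ,

so a gene that is highly connected in every pathway it belongs to scores
close to 1 and a peripheral gene scores close to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationKB:
    """Gene--term association records with evidence scores in [0, 1]."""

    records: pd.DataFrame  # columns: term, gene, score
    name: str = "associations"

    def __post_init__(self) -> None:
        df = self.records
        required = ["term", "gene", "score"]
        if list(df.columns[:3]) != required:
            raise ValueError(f"association records need columns {required}")
        if df.empty:
            raise ValueError("association KB is empty")
        scores = df["score"].astype(float)
        if (scores < 0).any() or (scores > 1).any():
            bad = df.loc[(scores < 0) | (scores > 1)]
            raise ValueError(
                f"association scores outside [0, 1]: {bad.head(3).to_dict('records')}"
            )
        if df.duplicated(subset=["term", "gene"]).any():
            raise ValueError("duplicate (term, gene) pairs in association KB")

    @property
    def terms(self) -> list[str]:
        return sorted(self.records["term"].unique())

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"])


@dataclass(frozen=True)
class NetworkKB:
    """Named pathway graphs: node sets of gene ids with undirected edges."""

    pathways: dict[str, nx.Graph]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, g in self.pathways.items():
            if any(u == v for u, v in g.edges):
                raise ValueError(f"self-loop in pathway {name!r}")

    @property
    def pathway_names(self) -> list[str]:
        return sorted(self.pathways)

    def member_genes(self, pathway: str) -> set[str]:
        return set(self.pathways[pathway].nodes)


@dataclass(frozen=True)
class CoverageReport:
    """Per-term gene counts and score distribution summaries."""

    table: pd.DataFrame  # index: term; columns: gene_count, min, q25, median, q75, max, mean

    def __post_init__(self) -> None:
        if (self.table["gene_count"] < 0).any():
            raise ValueError("negative gene count")


def load_association_kb(path: str | Path, name: str | None = None) -> AssociationKB:
    """Read a three-column TSV (term, gene, score) with a header line."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path.name}: expected 3 columns (term, gene, score)")
    df = df.iloc[:, :3]
    df.columns = ["term", "gene", "score"]
    df["term"] = df["term"].astype(str)
    df["gene"] = df["gene"].astype(str)
    df["score"] = df["score"].astype(float)
    return AssociationKB(df, name=name or path.stem)


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT gene-set library: name, description, tab-separated genes."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        sets[name] = (desc, genes)
    if not sets:
        raise ValueError(f"empty GMT file: {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_network_kb(gmt_path: str | Path, edges_path: str | Path) -> NetworkKB:
    """Build per-pathway graphs from a GMT membership file and an edge list.

    The edge list is a headered TSV (pathway, gene_a, gene_b).  Edges naming
    genes outside the pathway's membership are dropped and counted; self
    loops are dropped; duplicate and reversed duplicates collapse (graphs are
    undirected, so directed inputs are symmetrized implicitly).  An edge-list
    pathway missing from the GMT is an error.
    """
    memberships = read_gmt(gmt_path)
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    if edges.shape[1] < 3:
        raise ValueError("edge list needs columns (pathway, gene_a, gene_b)")
    edges = edges.iloc[:, :3]
    edges.columns = ["pathway", "gene_a", "gene_b"]

    unknown = set(edges["pathway"]) - set(memberships)
    if unknown:
        raise ValueError(f"edge-list pathways absent from GMT: {sorted(unknown)[:5]}")

    pathways: dict[str, nx.Graph] = {}
    annotations: dict[str, str] = {}
    for name, (desc, genes) in memberships.items():
        g = nx.Graph()
        g.add_nodes_from(genes)
        pathways[name] = g
        annotations[name] = desc

    n_dropped = 0
    for pw, a, b in edges.itertuples(index=False):
        g = pathways[pw]
        if a == b:
            n_dropped += 1
            continue
        if a not in g.nodes or b not in g.nodes:
            n_dropped += 1
            continue
        g.add_edge(a, b)
    if n_dropped:
        logger.info("load_network_kb: dropped %d invalid edges", n_dropped)
    return NetworkKB(pathways, annotations)


def get_relevant_genes(
    kb: AssociationKB, terms: list[str], min_score: float = 0.0
) -> set[str]:
    """Union over the search terms of genes with association score >= min_score."""
    if not terms:
        raise ValueError("terms must be nonempty")
    known = set(kb.records["term"])
    missing = [t for t in terms if t not in known]
    if missing:
        logger.info("get_relevant_genes: unknown terms %s", missing)
    df = kb.records
    hit = df[(df["term"].isin(terms)) & (df["score"] >= min_score)]
    return set(hit["gene"])


def get_gene_scores(
    kb: AssociationKB, terms: list[str], aggregation: str = "max"
) -> dict[str, float]:
    """Aggregate each gene's association scores over the search terms.

    Genes with no record for any of the terms are absent from the result;
    callers decide what a missing gene is worth.
    """
    if not terms:
        raise ValueError("terms must be nonempty")
    if aggregation not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    df = kb.records[kb.records["term"].isin(terms)]
    if df.empty:
        return {}
    agg = df.groupby("gene")["score"].agg(aggregation)
    return agg.to_dict()


def connectedness_gene_scores(net: NetworkKB) -> dict[str, float]:
    """Pathway-topology gene score: mean per-pathway percentile degree rank.

    Within each pathway the member genes are ranked by degree (ties receive
    the average rank, isolated members included) and the rank is divided by
    the pathway size, giving a fractional percentile in (0, 1].  A gene's
    score averages these percentiles over all pathways containing it, so
    hub genes -- especially recurrent hubs -- score highest.
    """
    if not net.pathways:
        raise ValueError("network KB has no pathways")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name, g in net.pathways.items():
        nodes = sorted(g.nodes)
        if not nodes:
            continue
        degrees = np.array([g.degree(n) for n in nodes], dtype=float)
        pr = rankdata(degrees, method="average") / len(nodes)
        for node, r in zip(nodes, pr):
            sums[node] = sums.get(node, 0.0) + float(r)
            counts[node] = counts.get(node, 0) + 1
    return {gene: sums[gene] / counts[gene] for gene in sums}


def coverage_report(kb: AssociationKB, terms: list[str]) -> CoverageReport:
    """Summary statistics of the prior knowledge available per search term."""
    if not terms:
        raise ValueError("terms must be nonempty")
    rows = []
    for term in terms:
        scores = kb.records.loc[kb.records["term"] == term, "score"].to_numpy()
        if scores.size == 0:
            rows.append(
                dict(term=term, gene_count=0, min=np.nan, q25=np.nan,
                     median=np.nan, q75=np.nan, max=np.nan, mean=np.nan)
            )
        else:
            q25, med, q75 = np.percentile(scores, [25, 50, 75])
            rows.append(
                dict(term=term, gene_count=int(scores.size), min=float(scores.min()),
                     q25=float(q25), median=float(med), q75=float(q75),
                     max=float(scores.max()), mean=float(scores.mean()))
            )
    table = pd.DataFrame(rows).set_index("term")
    return CoverageReport(table)
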