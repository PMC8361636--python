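"""Expression matrix and metadata IO, identifier harmonization, missing-value filtering.

The canonical in-memory layout is genes x samples; every loader normalizes to
it and every downstream module assumes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Orientation = Literal["auto", "genes_in_rows", "samples_in_rows"]


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x samples matrix of normalized expression levels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. NaN marks a
        missing measurement.
    labels
        Optional Series mapping sample id -> class label, covering every
        sample exactly once when present.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.labels is not None:
            missing = set(self.values.columns) - set(self.labels.index)
            if missing:
                raise ValueError(f"samples without labels: {sorted(missing)[:5]}")
            # keep label order aligned with the matrix
            object.__setattr__(self, "labels", self.labels.loc[self.values.columns])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        """Restrict to the given genes, preserving their given order."""
        present = [g for g in genes if g in self.values.index]
        if not present:
            raise ValueError("no requested genes present in dataset")
        return replace(self, values=self.values.loc[present])

    def equals(self, other: "ExpressionDataset") -> bool:
        same_values = self.values.equals(other.values)
        if self.labels is None or other.labels is None:
            return same_values and (self.labels is None) == (other.labels is None)
        return same_values and self.labels.equals(other.labels)


@dataclass(frozen=True)
class MappingTable:
    """Identifier translation pairs between two namespaces.

    A source id may map to several targets; empty identifiers are rejected.
    """

    records: pd.DataFrame  # columns: source_id, target_id
    source_namespace: str = "source"
    target_namespace: str = "target"

    def __post_init__(self) -> None:
        df = self.records
        if list(df.columns) != ["source_id", "target_id"]:
            df = df.copy()
            df.columns = ["source_id", "target_id"]
            object.__setattr__(self, "records", df)
        if df.empty:
            raise ValueError("mapping table is empty")
        if (df["source_id"].astype(str).str.len() == 0).any() or (
            df["target_id"].astype(str).str.len() == 0
        ).any():
            raise ValueError("mapping table contains empty identifiers")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        *,
        header: bool = True,
        source_namespace: str = "source",
        target_namespace: str = "target",
    ) -> "MappingTable":
        df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
        df = df.iloc[:, :2]
        df.columns = ["source_id", "target_id"]
        return cls(df, source_namespace, target_namespace)


def load_expression_matrix(
    path: str | Path,
    orientation: Orientation = "auto",
    known_sample_ids: set[str] | None = None,
    delimiter: str = "\t",
) -> ExpressionDataset:
    """Read a delimited expression table and return it genes x samples.

    The file must have a header line and row ids in the first column; both
    layouts (genes in rows or samples in rows) are accepted.  With
    ``orientation='auto'`` the samples axis is the one whose header labels
    overlap ``known_sample_ids``; if no id set is given, the longer axis is
    taken as samples (expression matrices almost always have more genes than
    samples, so the shorter axis is the sample axis only when genes are in
    columns -- the heuristic picks the axis with MORE entries as genes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if orientation == "genes_in_rows":
        mat = df
    elif orientation == "samples_in_rows":
        mat = df.T
    else:
        mat = _auto_orient(df, known_sample_ids, path)

    if mat.index.has_duplicates:
        dupes = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path.name}: {dupes[:5]}")
    if mat.columns.has_duplicates:
        dupes = mat.columns[mat.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path.name}: {dupes[:5]}")
    return ExpressionDataset(mat.astype(float))


def _auto_orient(
    df: pd.DataFrame, known_sample_ids: set[str] | None, path: Path
) -> pd.DataFrame:
    if known_sample_ids:
        col_overlap = len(set(df.columns) & known_sample_ids)
        row_overlap = len(set(df.index) & known_sample_ids)
        if col_overlap == 0 and row_overlap == 0:
            raise ValueError(
                f"cannot orient {path.name}: neither axis overlaps the known sample ids"
            )
        return df if col_overlap >= row_overlap else df.T
    if df.shape[0] == df.shape[1]:
        raise ValueError(
            f"cannot orient square matrix {path.name} without known_sample_ids"
        )
    # more rows than columns -> rows are genes
    return df if df.shape[0] > df.shape[1] else df.T


def attach_labels(
    ds: ExpressionDataset,
    metadata: pd.DataFrame | str | Path,
    sample_id_column: str,
    label_attribute: str,
) -> ExpressionDataset:
    """Attach class labels from a metadata table.

    Samples absent from the metadata are dropped (the count is logged);
    an empty intersection is an error.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t", dtype=str)
    for col in (sample_id_column, label_attribute):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks column {col!r}")
    meta = metadata.drop_duplicates(subset=sample_id_column).set_index(sample_id_column)
    keep = [s for s in ds.sample_ids if s in meta.index]
    if not keep:
        raise ValueError("no dataset sample appears in the metadata table")
    dropped = ds.n_samples - len(keep)
    if dropped:
        logger.info("attach_labels: dropped %d samples absent from metadata", dropped)
    labels = meta.loc[keep, label_attribute].astype(str)
    labels.name = label_attribute
    return ExpressionDataset(ds.values[keep], labels)


def filter_missing(
    ds: ExpressionDataset,
    max_missing_fraction_per_feature: float = 0.5,
    max_missing_fraction_per_sample: float = 0.5,
) -> ExpressionDataset:
    """Drop samples, then genes, whose missing fraction exceeds its threshold.

    The samples-then-features pass is repeated until nothing more is
    removed: dropping genes changes per-sample missing fractions (and vice
    versa), so a single pass would not be idempotent.  Retained entries are
    untouched.
    """
    for t in (max_missing_fraction_per_feature, max_missing_fraction_per_sample):
        if not 0.0 <= t <= 1.0:
            raise ValueError("missing-fraction thresholds must lie in [0, 1]")
    vals = ds.values
    while True:
        before = vals.shape
        sample_frac = vals.isna().mean(axis=0)
        keep_samples = sample_frac[sample_frac <= max_missing_fraction_per_sample].index
        if len(keep_samples) == 0:
            raise ValueError("missing-value filter removed every sample")
        vals = vals[keep_samples]
        gene_frac = vals.isna().mean(axis=1)
        keep_genes = gene_frac[gene_frac <= max_missing_fraction_per_feature].index
        if len(keep_genes) == 0:
            raise ValueError("missing-value filter removed every gene")
        vals = vals.loc[keep_genes]
        if vals.shape == before:
            break
    n_s, n_g = ds.n_samples - vals.shape[1], ds.n_genes - vals.shape[0]
    if n_s or n_g:
        logger.info("filter_missing: dropped %d samples, %d genes", n_s, n_g)
    labels = ds.labels.loc[vals.columns] if ds.labels is not None else None
    return ExpressionDataset(vals, labels)


def map_identifiers(
    ds: ExpressionDataset,
    table: MappingTable,
    collision_policy: Literal["first", "drop"] = "first",
) -> ExpressionDataset:
    """Rename genes through a mapping table.

    Unmapped genes are dropped (logged).  When several source genes map to
    one target, ``first`` keeps the first source gene's row (in table order)
    under the target id and ``drop`` removes all colliding genes.
    """
    if collision_policy not in ("first", "drop"):
        raise ValueError(f"unknown collision policy {collision_policy!r}")
    rec = table.records.drop_duplicates(subset="source_id", keep="first")
    mapping = dict(zip(rec["source_id"], rec["target_id"]))
    rows: list[tuple[str, str]] = []  # (target, source) in table order
    seen_sources = set()
    present = set(ds.gene_ids)
    for src, tgt in zip(rec["source_id"], rec["target_id"]):
        if src in present and src not in seen_sources:
            rows.append((tgt, src))
            seen_sources.add(src)
    if not rows:
        raise ValueError("no dataset gene could be mapped")
    unmapped = ds.n_genes - len(rows)
    if unmapped:
        logger.info("map_identifiers: dropped %d unmapped genes", unmapped)

    by_target: dict[str, list[str]] = {}
    for tgt, src in rows:
        by_target.setdefault(tgt, []).append(src)
    kept: list[tuple[str, str]] = []
    n_collide = 0
    for tgt, sources in by_target.items():
        if len(sources) == 1:
            kept.append((tgt, sources[0]))
        elif collision_policy == "first":
            kept.append((tgt, sources[0]))
            n_collide += len(sources) - 1
        else:
            n_collide += len(sources)
    if n_collide:
        logger.info(
            "map_identifiers: %d colliding genes handled with policy=%s",
            n_collide,
            collision_policy,
        )
    if not kept:
        raise ValueError("identifier collisions removed every mapped gene")
    new_values = ds.values.loc[[src for _, src in kept]].copy()
    new_values.index = pd.Index([tgt for tgt, _ in kept], name=ds.values.index.name)
    return ExpressionDataset(new_values, ds.labels)
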