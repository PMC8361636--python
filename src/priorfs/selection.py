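"""Feature selectors: statistical rankers, prior-knowledge adaptations, pathway features.

Statistical rankers score genes by variance or one-way ANOVA F.  Prior
knowledge enters in three ways:

* *modifying* -- restrict the gene universe to knowledge-base-relevant genes
  before (`prefilter_select`) or after (`postfilter_select`) ranking, or
  extend a statistical top list with KB genes (`extension_select`);
* *combining* -- multiply the statistical score by the association score,
  s_i = s_i^trad * s_i^kb (`weighted_combine`), or shrink the Lasso penalty
  of well-supported genes (`kb_penalized_lasso`);
* *network* -- swap gene features for pathway-activity features after
  picking class-relevant pathways (`select_relevant_pathways`,
  `pathway_activity_matrix`).

All rankings are deterministic: ties break by gene id ascending.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .datasets import ExpressionDataset
from .knowledge import AssociationKB, NetworkKB, get_gene_scores, get_relevant_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureRanking:
    """Genes ordered by relevance score, descending (ties by gene id)."""

    table: pd.DataFrame  # columns: gene_id, score
    method_name: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.table
        if list(df.columns[:2]) != ["gene_id", "score"]:
            raise ValueError("ranking table needs columns (gene_id, score)")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate genes in ranking")
        if not np.isfinite(df["score"].to_numpy()).all():
            raise ValueError("non-finite ranking scores")
        diffs = np.diff(df["score"].to_numpy())
        if (diffs > 0).any():
            raise ValueError("ranking not sorted by score descending")

    @classmethod
    def from_scores(
        cls, scores: dict[str, float] | pd.Series, method_name: str, **metadata
    ) -> "FeatureRanking":
        s = pd.Series(scores, dtype=float)
        df = pd.DataFrame({"gene_id": s.index.astype(str), "score": s.to_numpy()})
        df = df.sort_values(
            ["score", "gene_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        return cls(df, method_name, metadata)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def __len__(self) -> int:
        return len(self.table)

    def score_of(self, gene: str) -> float:
        row = self.table.loc[self.table["gene_id"] == gene, "score"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])

    def rank_of(self, gene: str) -> int:
        """1-based position of a gene in the ranking."""
        pos = self.table.index[self.table["gene_id"] == gene]
        if len(pos) == 0:
            raise KeyError(gene)
        return int(pos[0]) + 1

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out["method_name"] = self.method_name
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PathwayFeatureSet:
    """Selected pathways with relevance scores and, optionally, activity features."""

    scores: pd.DataFrame  # columns: pathway, relevance[, p_value]
    activity: pd.DataFrame | None = None  # pathways x samples

    def __post_init__(self) -> None:
        if self.activity is not None:
            if list(self.activity.index) != list(self.scores["pathway"]):
                raise ValueError("activity rows must match selected pathways")

    @property
    def pathway_names(self) -> list[str]:
        return list(self.scores["pathway"])


def rank_by_variance(ds: ExpressionDataset) -> FeatureRanking:
    """Rank genes by sample variance (ddof=1), ignoring missing entries per gene."""
    if ds.n_samples < 2:
        raise ValueError("variance ranking needs at least 2 samples")
    var = ds.values.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    return FeatureRanking.from_scores(var, "variance")


def _anova_f_scores(values: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Vectorized nan-aware one-way ANOVA F per gene (row) across label classes."""
    classes = labels.unique()
    X = values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n_tot = np.zeros(X.shape[0])
    grand_sum = np.zeros(X.shape[0])
    per_class = []
    for c in classes:
        cols = (labels == c).to_numpy()
        Xc = X[:, cols]
        oc = obs[:, cols]
        n_c = oc.sum(axis=1).astype(float)
        s_c = np.nansum(Xc, axis=1)
        per_class.append((Xc, oc, n_c, s_c))
        n_tot += n_c
        grand_sum += s_c
    with np.errstate(invalid="ignore", divide="ignore"):
        grand_mean = grand_sum / n_tot
        ssb = np.zeros(X.shape[0])
        ssw = np.zeros(X.shape[0])
        for Xc, oc, n_c, s_c in per_class:
            mean_c = np.where(n_c > 0, s_c / np.maximum(n_c, 1), 0.0)
            ssb += n_c * (mean_c - grand_mean) ** 2
            dev = Xc - mean_c[:, None]
            ssw += np.nansum(dev**2, axis=1)
        df_b = len(classes) - 1
        df_w = n_tot - len(classes)
        f = (ssb / df_b) / (ssw / np.maximum(df_w, 1))
    # zero within-class variance with real between-class signal: effectively
    # infinite separation; cap at a large finite value so rankings stay valid
    f = np.where(np.isinf(f), 1e12, f)
    f = np.where(np.isnan(f) | (df_w <= 0), 0.0, f)
    return pd.Series(f, index=values.index)


def rank_by_anova_f(ds: ExpressionDataset) -> FeatureRanking:
    """Rank genes by the one-way ANOVA F statistic across class labels."""
    if ds.labels is None:
        raise ValueError("ANOVA ranking needs a labeled dataset")
    counts = ds.labels.value_counts()
    if len(counts) < 2:
        raise ValueError("ANOVA ranking needs at least 2 classes")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    return FeatureRanking.from_scores(
        _anova_f_scores(ds.values, ds.labels), "anova_f"
    )


def prefilter_select(
    ds: ExpressionDataset,
    kb: AssociationKB,
    terms: list[str],
    min_score: float,
    base_ranker: Callable[[ExpressionDataset], FeatureRanking],
) -> FeatureRanking:
    """Restrict the dataset to KB-relevant genes, then run the base ranker."""
    relevant = get_relevant_genes(kb, terms, min_score)
    keep = [g for g in ds.gene_ids if g in relevant]
    if not keep:
        raise ValueError("no KB-relevant gene is present in the dataset")
    base = base_ranker(ds.subset_genes(keep))
    return FeatureRanking(
        base.table, f"prefilter_{base.method_name}", {**base.metadata, "kb": kb.name}
    )


def postfilter_select(
    base_ranking: FeatureRanking,
    kb: AssociationKB,
    terms: list[str],
    min_score: float,
) -> FeatureRanking:
    """Drop ranked genes that are not KB-relevant, preserving the order."""
    relevant = get_relevant_genes(kb, terms, min_score)
    df = base_ranking.table[base_ranking.table["gene_id"].isin(relevant)]
    if df.empty:
        raise ValueError("post-filter removed every ranked gene")
    return FeatureRanking(
        df.reset_index(drop=True),
        f"postfilter_{base_ranking.method_name}",
        {**base_ranking.metadata, "kb": kb.name},
    )


def extension_select(
    base_ranking: FeatureRanking,
    kb: AssociationKB,
    terms: list[str],
    min_score: float,
    k_stat: int,
    k_kb: int,
) -> FeatureRanking:
    """Top statistical genes extended with top KB-associated genes.

    Takes the first ``k_stat`` genes of the base ranking, then appends up to
    ``k_kb`` KB-relevant genes (association score >= min_score) that are not
    already present, in descending association-score order.  The reported
    scores are ordinal (length - position) because the two halves live on
    incommensurable scales; the original scores are kept in extra columns.
    """
    if k_stat < 0 or k_kb < 0:
        raise ValueError("k_stat and k_kb must be non-negative")
    stat_part = base_ranking.table.head(k_stat)
    chosen = list(stat_part["gene_id"])
    kb_scores = get_gene_scores(kb, terms, aggregation="max")
    candidates = sorted(
        ((g, s) for g, s in kb_scores.items() if s >= min_score and g not in set(chosen)),
        key=lambda gs: (-gs[1], gs[0]),
    )
    ext = candidates[:k_kb]
    genes = chosen + [g for g, _ in ext]
    source_scores = list(stat_part["score"]) + [s for _, s in ext]
    n = len(genes)
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "score": np.arange(n, 0, -1, dtype=float),
            "source_score": source_scores,
            "source": ["statistical"] * len(chosen) + ["kb"] * len(ext),
        }
    )
    return FeatureRanking(
        df,
        f"extension_{base_ranking.method_name}",
        {"kb": kb.name, "score_scale": "ordinal"},
    )


def weighted_combine(
    base_ranking: FeatureRanking,
    kb_scores: dict[str, float],
    missing_policy: str = "epsilon",
    epsilon: float = 0.001,
) -> FeatureRanking:
    """Combine statistical and association evidence: s_i = s_i^trad * s_i^kb.

    Genes absent from the knowledge base receive an association score of 0
    (``missing_policy='zero'``) or ``epsilon``; with the epsilon policy a
    strong statistical signal can still surface a KB-unknown gene.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if missing_policy not in ("zero", "epsilon"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if len(base_ranking) == 0:
        raise ValueError("empty base ranking")
    fill = 0.0 if missing_policy == "zero" else epsilon
    df = base_ranking.table.copy()
    kb = df["gene_id"].map(kb_scores).fillna(fill)
    df["score"] = df["score"] * kb
    df = df.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return FeatureRanking(
        df[["gene_id", "score"]],
        f"weighted_{base_ranking.method_name}",
        {"missing_policy": missing_policy, "epsilon": epsilon},
    )


def _impute_and_scale(values: pd.DataFrame) -> np.ndarray:
    """Per-gene mean imputation then z-scaling; constant genes become zeros."""
    X = values.to_numpy(dtype=float)
    means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
    means = np.where(np.isnan(means), 0.0, means)
    X = np.where(np.isnan(X), means[:, None], X)
    sd = X.std(axis=1, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=1)[:, None]) / sd[:, None]


def kb_penalized_lasso(
    ds: ExpressionDataset,
    kb_scores: dict[str, float],
    lam: float = 1.0,
    missing_policy: str = "zero",
    epsilon: float = 0.001,
    max_iter: int = 5000,
) -> FeatureRanking:
    """L1 logistic regression with knowledge-shrunk per-feature penalties.

    Each gene's L1 penalty factor is w_i = 1 - s_i^kb, clipped to
    [epsilon, 1], so well-supported genes are cheaper to keep in the model.
    The per-feature weighting is realized by rescaling each feature column by
    1/w_i before the fit (which turns the uniform penalty lam * |b'_i| into
    lam * w_i * |b_i| on the original scale).  Multi-class labels are handled
    one-vs-rest; the ranking score is the maximum absolute original-scale
    coefficient across the binary problems.  Genes with all-zero coefficients
    rank below every selected gene, ordered by ascending penalty (encoded as
    score -w_i).
    """
    if ds.labels is None:
        raise ValueError("penalized Lasso needs a labeled dataset")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if missing_policy not in ("zero", "epsilon"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    fill = 0.0 if missing_policy == "zero" else epsilon
    s_kb = np.array([kb_scores.get(g, fill) for g in ds.gene_ids])
    w = np.clip(1.0 - s_kb, epsilon, 1.0)

    X = _impute_and_scale(ds.values).T  # samples x genes
    X_scaled = X / w[None, :]
    y = ds.labels.to_numpy()
    model = LogisticRegression(
        l1_ratio=1, C=1.0 / lam, solver="liblinear", max_iter=max_iter,
        tol=1e-6, random_state=0,
    )
    model.fit(X_scaled, y)
    if np.max(model.n_iter_) >= max_iter:
        raise RuntimeError(f"Lasso did not converge within {max_iter} iterations")
    coef = np.atleast_2d(model.coef_) / w[None, :]  # back to original scale
    strength = np.abs(coef).max(axis=0)
    score = np.where(strength > 0, strength, -w)
    return FeatureRanking.from_scores(
        pd.Series(score, index=ds.gene_ids),
        "kb_lasso",
        lam=lam,
        n_selected=int((strength > 0).sum()),
    )


def select_relevant_pathways(
    ds: ExpressionDataset,
    net: NetworkKB,
    n_pathways: int = 10,
    n_permutations: int = 100,
    seed: int = 0,
) -> PathwayFeatureSet:
    """Pick pathways whose member genes separate the classes.

    Relevance of a pathway is the mean absolute ANOVA F over its measured
    member genes; an empirical p-value comes from a label-permutation null
    (same permutation stream for every pathway, so pathway comparisons are
    paired).  Pathways with no measured member are excluded and logged.
    """
    if ds.labels is None:
        raise ValueError("pathway selection needs a labeled dataset")
    members: dict[str, list[str]] = {}
    gene_set = set(ds.gene_ids)
    for name in net.pathway_names:
        measured = sorted(net.member_genes(name) & gene_set)
        if measured:
            members[name] = measured
        else:
            logger.info("select_relevant_pathways: %r has no measured member", name)
    if not members:
        raise ValueError("no pathway shares a gene with the dataset")

    f_obs = _anova_f_scores(ds.values, ds.labels)
    relevance = {p: float(f_obs.loc[g].abs().mean()) for p, g in members.items()}

    rng = np.random.default_rng(seed)
    exceed = {p: 0 for p in members}
    label_values = ds.labels.to_numpy()
    for _ in range(n_permutations):
        perm = pd.Series(
            rng.permutation(label_values), index=ds.labels.index
        )
        f_perm = _anova_f_scores(ds.values, perm)
        for p, genes in members.items():
            if float(f_perm.loc[genes].abs().mean()) >= relevance[p]:
                exceed[p] += 1
    pvals = {p: (1 + exceed[p]) / (n_permutations + 1) for p in members}

    order = sorted(members, key=lambda p: (-relevance[p], p))[:n_pathways]
    scores = pd.DataFrame(
        {
            "pathway": order,
            "relevance": [relevance[p] for p in order],
            "p_value": [pvals[p] for p in order],
        }
    )
    return PathwayFeatureSet(scores)


def pathway_activity_matrix(
    ds: ExpressionDataset,
    selected_pathways: PathwayFeatureSet | list[str],
    net: NetworkKB,
) -> PathwayFeatureSet:
    """Per-sample pathway activity: mean z-scored expression of member genes.

    Each gene is z-scored over the provided samples (missing entries are
    ignored; constant genes contribute 0) and a pathway's activity in a
    sample is the mean over its measured members.  This is a deliberate
    simplification of condition-responsive-subset activity scoring: all
    measured members contribute, no subset search is performed.
    """
    if isinstance(selected_pathways, PathwayFeatureSet):
        names = selected_pathways.pathway_names
        scores = selected_pathways.scores
    else:
        names = list(selected_pathways)
        scores = pd.DataFrame({"pathway": names, "relevance": np.nan})
    if not names:
        raise ValueError("no pathways selected")

    vals = ds.values
    mean = vals.mean(axis=1, skipna=True)
    sd = vals.std(axis=1, ddof=0, skipna=True).replace(0.0, np.nan)
    z = vals.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)

    gene_set = set(ds.gene_ids)
    rows = []
    for name in names:
        measured = sorted(net.member_genes(name) & gene_set)
        if not measured:
            raise ValueError(f"pathway {name!r} has no measured member gene")
        rows.append(z.loc[measured].mean(axis=0))
    activity = pd.DataFrame(rows, index=pd.Index(names, name="pathway"))
    return PathwayFeatureSet(scores.reset_index(drop=True), activity)


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First k genes of a ranking, in ranking order."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range [1, {len(ranking)}]")
    return ranking.gene_ids[:k]
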