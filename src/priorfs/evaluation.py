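"""Feature-set evaluation: cross-validation, concordance, overlaps, enrichment.

Classification performance is measured by stratified k-fold cross-validation
over a panel of standard classifiers (Gaussian naive Bayes, logistic
regression, SVM, random forest, 3-nearest-neighbours), with per-gene mean
imputation and z-scaling fit on the training folds only.  Feature sets are
further compared by Kendall's coefficient of concordance W, upset-style
exclusive set overlaps, and a local Fisher-exact gene-set enrichment with
Benjamini--Hochberg control and an Enrichr-style combined score.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset
from .selection import FeatureRanking, select_top_k

logger = logging.getLogger(__name__)

# hyperparameters are fixed so that a (config, seed) pair pins the run
CLASSIFIER_FACTORIES: dict[str, Callable[[], object]] = {
    "naive_bayes": lambda: GaussianNB(),
    "logistic_regression": lambda: LogisticRegression(max_iter=2000, random_state=0),
    "svm": lambda: SVC(kernel="rbf", C=1.0, random_state=0),
    "random_forest": lambda: RandomForestClassifier(
        n_estimators=100, random_state=0, n_jobs=1
    ),
    "knn3": lambda: KNeighborsClassifier(n_neighbors=3),
}

DEFAULT_CLASSIFIERS = list(CLASSIFIER_FACTORIES)


@dataclass(frozen=True)
class MetricsTable:
    """Long-format CV results: one row per (selector, classifier, size, fold, metric)."""

    records: pd.DataFrame

    COLUMNS = ["selector", "classifier", "feature_set_size", "fold", "metric_name", "value"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"metrics table lacks columns {missing}")
        vals = self.records.loc[
            self.records["metric_name"].isin(["accuracy", "f1_macro"]), "value"
        ]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("accuracy/F1 outside [0, 1]")

    def averaged(self) -> pd.DataFrame:
        """Mean over folds, then over classifiers, per (selector, size, metric)."""
        per_clf = (
            self.records.groupby(
                ["selector", "classifier", "feature_set_size", "metric_name"],
                as_index=False,
            )["value"].mean()
        )
        return per_clf.groupby(
            ["selector", "feature_set_size", "metric_name"], as_index=False
        )["value"].mean()

    @staticmethod
    def concat(tables: Iterable["MetricsTable"]) -> "MetricsTable":
        frames = [t.records for t in tables]
        return MetricsTable(pd.concat(frames, ignore_index=True))


def _make_classifier(name: str):
    try:
        return CLASSIFIER_FACTORIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; available: {sorted(CLASSIFIER_FACTORIES)}"
        ) from None


def kfold_cv(
    ds: ExpressionDataset,
    feature_set: Sequence[str],
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    k: int = 10,
    seed: int = 0,
    selector_name: str = "unnamed",
) -> MetricsTable:
    """Stratified k-fold cross-validation of one feature set.

    Imputation (per-gene training mean) and z-scaling are part of the fold
    pipeline, so no test-fold statistic leaks into the fit.  Folds depend
    only on (labels, k, seed); runs with the same seed are bit-identical.
    """
    if ds.labels is None:
        raise ValueError("cross-validation needs a labeled dataset")
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = ds.labels.value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(f"classes with fewer than k={k} samples: {small}")
    missing = [g for g in feature_set if g not in set(ds.gene_ids)]
    if missing:
        raise ValueError(f"feature set genes absent from dataset: {missing[:5]}")

    # canonical sample order: fold assignment depends on (labels, k, seed)
    # only, never on the column order of the input matrix
    order = np.argsort(np.asarray(ds.sample_ids))
    X = ds.values.loc[list(feature_set)].T.to_numpy(dtype=float)[order]  # samples x genes
    y = ds.labels.to_numpy()[order]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    rows = []
    for clf_name in classifiers:
        _make_classifier(clf_name)  # fail fast on unknown names
        for fold_idx, (train, test) in enumerate(folds):
            pipe = Pipeline(
                [
                    ("impute", SimpleImputer(strategy="mean")),
                    ("scale", StandardScaler()),
                    ("clf", _make_classifier(clf_name)),
                ]
            )
            pipe.fit(X[train], y[train])
            pred = pipe.predict(X[test])
            for metric, value in (
                ("accuracy", accuracy_score(y[test], pred)),
                ("f1_macro", f1_score(y[test], pred, average="macro")),
            ):
                rows.append(
                    dict(
                        selector=selector_name,
                        classifier=clf_name,
                        feature_set_size=len(feature_set),
                        fold=fold_idx,
                        metric_name=metric,
                        value=float(value),
                    )
                )
    return MetricsTable(pd.DataFrame(rows))


def sweep_feature_sizes(
    ranking: FeatureRanking,
    ds: ExpressionDataset,
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    k: int = 10,
    sizes: Sequence[int] = tuple(range(1, 21)),
    seed: int = 0,
) -> MetricsTable:
    """Cross-validate nested top-k feature sets of increasing size.

    Fold assignment is identical across sizes (it depends only on labels and
    seed), so performance curves differ only in the features used.
    """
    if max(sizes) > len(ranking):
        raise ValueError(f"max size {max(sizes)} exceeds ranking length {len(ranking)}")
    tables = []
    for size in sizes:
        features = select_top_k(ranking, size)
        tables.append(
            kfold_cv(ds, features, classifiers, k, seed, selector_name=ranking.method_name)
        )
    return MetricsTable.concat(tables)


def cross_dataset_validation(
    feature_set: Sequence[str],
    ds_b: ExpressionDataset,
    classifiers: Sequence[str] = DEFAULT_CLASSIFIERS,
    k: int = 10,
    seed: int = 0,
    selector_name: str = "unnamed",
) -> MetricsTable:
    """Robustness check: cross-validate features selected elsewhere on dataset B.

    Features missing from B are dropped with a logged count; an empty
    intersection is an error.
    """
    present = set(ds_b.gene_ids)
    surviving = [g for g in feature_set if g in present]
    if not surviving:
        raise ValueError("no selected feature is measured in the second dataset")
    dropped = len(feature_set) - len(surviving)
    if dropped:
        logger.info("cross_dataset_validation: dropped %d unmeasured features", dropped)
    return MetricsTable(
        kfold_cv(ds_b, surviving, classifiers, k, seed, selector_name).records.assign(
            feature_set_size=len(feature_set)
        )
    )


def _rank_matrix(rankings: Sequence[FeatureRanking | Sequence[str]]) -> np.ndarray:
    """m x n matrix of (tie-averaged) ranks over a shared item set."""
    item_sets = []
    rank_rows = []
    for r in rankings:
        if isinstance(r, FeatureRanking):
            items = r.gene_ids
            # equal scores share an average rank
            ranks = rankdata(-r.table["score"].to_numpy(), method="average")
            row = dict(zip(items, ranks))
        else:
            items = list(r)
            row = {g: i + 1 for i, g in enumerate(items)}
        item_sets.append(set(items))
        rank_rows.append(row)
    universe = item_sets[0]
    if any(s != universe for s in item_sets[1:]):
        raise ValueError("rankings do not cover identical item sets")
    order = sorted(universe)
    return np.array([[row[g] for g in order] for row in rank_rows], dtype=float)


def kendalls_w(rankings: Sequence[FeatureRanking | Sequence[str]]) -> float:
    """Kendall's coefficient of concordance W with tie correction.

    W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j) where S is the sum of squared
    deviations of the per-item rank sums from their mean and
    T_j = sum over tie groups of (t^3 - t) within ranking j.  W is 1 for
    identical rankings and 0 for two mutually reversed rankings.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    R = _rank_matrix(rankings)
    m, n = R.shape
    if n < 2:
        raise ValueError("need at least two items")
    rank_sums = R.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_term = 0.0
    for row in R:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom == 0:
        return 1.0  # every ranking is one big tie group: vacuous concordance
    return 12.0 * s / denom


@dataclass(frozen=True)
class OverlapSummary:
    """Upset-style exclusive intersection counts over named sets."""

    counts: dict[frozenset, int]  # nonempty subsets of set names -> exclusive count
    set_names: tuple[str, ...]

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "&".join(sorted(key)), "exclusive_count": c}
            for key, c in sorted(self.counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def feature_overlap(named_sets: Mapping[str, set[str]]) -> OverlapSummary:
    """Exclusive (upset-style) intersection counts for every nonempty subset.

    An element is counted exactly once, in the cell of the subset of sets
    that contain it, so the exclusive counts sum to the union size.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets to overlap")
    names = tuple(named_sets)
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            counts[frozenset(combo)] = 0
    union = set().union(*named_sets.values())
    for element in union:
        membership = frozenset(n for n in names if element in named_sets[n])
        counts[membership] += 1
    return OverlapSummary(counts, names)


def annotation_overlap(enrichment_results: Mapping[str, set[str]]) -> OverlapSummary:
    """Exclusive overlaps of enriched-term sets; empty result sets are allowed."""
    return feature_overlap({k: set(v) for k, v in enrichment_results.items()})


@dataclass(frozen=True)
class EnrichedTerm:
    """One significantly enriched gene-set term."""

    term: str
    overlap_count: int
    p_value: float
    adjusted_p: float
    combined_score: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1 or not 0 <= self.adjusted_p <= 1:
            raise ValueError("p-values must lie in [0, 1]")
        if self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p below raw p")


def enrich(
    query: set[str],
    library: Mapping[str, Sequence[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichedTerm]:
    """Fisher-exact over-representation of a gene set against a GMT library.

    For each term the one-sided Fisher exact p-value (hypergeometric upper
    tail) of the query/term overlap against the background universe is
    computed, Benjamini--Hochberg adjusted across terms, and terms with
    adjusted p > ``alpha`` are removed.  Survivors are sorted by the
    combined score  -ln(p) * z,  where z is the overlap's deviation from
    its hypergeometric expectation in null standard-deviation units.
    """
    if not query:
        raise ValueError("empty query gene set")
    if not background:
        raise ValueError("empty background universe")
    extra = query - background
    if extra:
        raise ValueError(f"query genes outside background: {sorted(extra)[:5]}")

    N = len(background)
    n_query = len(query)
    rows = []
    for term, genes in library.items():
        term_genes = set(genes) & background
        if not term_genes:
            continue
        K = len(term_genes)
        overlap = len(query & term_genes)
        # P(X >= overlap) for X ~ Hypergeom(N, K, n_query)
        p = float(hypergeom.sf(overlap - 1, N, K, n_query))
        expected = n_query * K / N
        var = (
            n_query * (K / N) * (1 - K / N) * (N - n_query) / (N - 1)
            if N > 1
            else 0.0
        )
        z = (overlap - expected) / np.sqrt(var) if var > 0 else 0.0
        combined = -np.log(max(p, 1e-300)) * z
        rows.append((term, overlap, p, z, combined))
    if not rows:
        return []
    pvals = [r[2] for r in rows]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichedTerm(term, overlap, p, float(adj), float(combined))
        for (term, overlap, p, z, combined), adj in zip(rows, p_adj)
        if adj <= alpha and overlap > 0
    ]
    results.sort(key=lambda t: (-t.combined_score, t.term))
    return results


def runtime_profile(invocation: Callable[[], object]) -> tuple[object, float]:
    """Run a selector invocation and return (result, wall-clock seconds)."""
    t0 = time.perf_counter()
    result = invocation()
    return result, time.perf_counter() - t0
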