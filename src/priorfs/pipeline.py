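"""Benchmark orchestration: preprocessing, selectors, evaluation, reporting.

`run_benchmark` drives one configured run end to end: it preprocesses the
expression data, summarizes knowledge-base coverage, executes every
configured selector (timed, failures isolated), sweeps feature-set sizes
through cross-validation, optionally validates on a second cohort, and
compares selectors by Kendall's W, feature overlaps and enrichment.  All
analytic outputs are deterministic given (config, seed, inputs); only the
runtime ledger varies between identical runs.

Selectors and classifiers live in registries so user code can plug in new
components; a registered selector receives the preprocessed dataset plus a
context of knowledge bases and parameters and must return a FeatureRanking
(optionally with a transformed feature dataset, as the pathway-activity
selector does).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from . import evaluation as ev
from . import selection as sel
from .config import BenchmarkConfig
from .datasets import (
    ExpressionDataset,
    MappingTable,
    attach_labels,
    filter_missing,
    load_expression_matrix,
    map_identifiers,
)
from .knowledge import (
    AssociationKB,
    NetworkKB,
    coverage_report,
    get_gene_scores,
    load_association_kb,
    load_network_kb,
    read_gmt,
)

logger = logging.getLogger(__name__)


@dataclass
class SelectorContext:
    """Everything a selector may draw on besides the dataset itself."""

    kb: AssociationKB | None
    net: NetworkKB | None
    terms: list[str]
    cfg: BenchmarkConfig
    seed: int


@dataclass
class SelectorResult:
    ranking: sel.FeatureRanking
    # network selectors replace genes with pathway features; the CV stage
    # then runs on this dataset instead of the preprocessed gene matrix
    transformed: ExpressionDataset | None = None


SelectorFn = Callable[[ExpressionDataset, SelectorContext], SelectorResult]

_SELECTORS: dict[str, SelectorFn] = {}


def register_selector(name: str, factory: SelectorFn) -> None:
    if name in _SELECTORS:
        raise ValueError(f"selector {name!r} already registered")
    _SELECTORS[name] = factory


def register_classifier(name: str, factory: Callable[[], object]) -> None:
    if name in ev.CLASSIFIER_FACTORIES:
        raise ValueError(f"classifier {name!r} already registered")
    ev.CLASSIFIER_FACTORIES[name] = factory


def registered_selectors() -> set[str]:
    return set(_SELECTORS)


def registered_classifiers() -> set[str]:
    return set(ev.CLASSIFIER_FACTORIES)


def _need_kb(ctx: SelectorContext) -> AssociationKB:
    if ctx.kb is None:
        raise ValueError("selector needs an association knowledge base")
    return ctx.kb


def _sel_variance(ds, ctx):
    return SelectorResult(sel.rank_by_variance(ds))


def _sel_anova(ds, ctx):
    return SelectorResult(sel.rank_by_anova_f(ds))


def _sel_prefilter_anova(ds, ctx):
    kb = _need_kb(ctx)
    min_score = ctx.cfg.get("knowledge", "min_score")
    return SelectorResult(
        sel.prefilter_select(ds, kb, ctx.terms, min_score, sel.rank_by_anova_f)
    )


def _sel_postfilter_anova(ds, ctx):
    kb = _need_kb(ctx)
    min_score = ctx.cfg.get("knowledge", "min_score")
    base = sel.rank_by_anova_f(ds)
    return SelectorResult(sel.postfilter_select(base, kb, ctx.terms, min_score))


def _sel_extension_anova(ds, ctx):
    kb = _need_kb(ctx)
    cfg = ctx.cfg
    base = sel.rank_by_anova_f(ds)
    return SelectorResult(
        sel.extension_select(
            base,
            kb,
            ctx.terms,
            cfg.get("knowledge", "min_score"),
            cfg.get("selection", "extension_k_stat"),
            cfg.get("selection", "extension_k_kb"),
        )
    )


def _sel_weighted_anova(ds, ctx):
    kb = _need_kb(ctx)
    cfg = ctx.cfg
    base = sel.rank_by_anova_f(ds)
    scores = get_gene_scores(kb, ctx.terms, cfg.get("knowledge", "aggregation"))
    return SelectorResult(
        sel.weighted_combine(
            base,
            scores,
            cfg.get("selection", "missing_policy"),
            cfg.get("selection", "epsilon"),
        )
    )


def _sel_kb_lasso(ds, ctx):
    kb = _need_kb(ctx)
    cfg = ctx.cfg
    scores = get_gene_scores(kb, ctx.terms, cfg.get("knowledge", "aggregation"))
    return SelectorResult(
        sel.kb_penalized_lasso(
            ds,
            scores,
            lam=cfg.get("selection", "lasso_lambda"),
            missing_policy=cfg.get("selection", "missing_policy"),
            epsilon=cfg.get("selection", "epsilon"),
        )
    )


def _sel_pathway_activity(ds, ctx):
    if ctx.net is None:
        raise ValueError("pathway selector needs a network knowledge base")
    cfg = ctx.cfg
    chosen = sel.select_relevant_pathways(
        ds,
        ctx.net,
        n_pathways=cfg.get("selection", "n_pathways"),
        n_permutations=cfg.get("selection", "n_permutations"),
        seed=ctx.seed,
    )
    feats = sel.pathway_activity_matrix(ds, chosen, ctx.net)
    ranking = sel.FeatureRanking.from_scores(
        dict(zip(feats.scores["pathway"], feats.scores["relevance"])),
        "pathway_activity",
    )
    transformed = ExpressionDataset(feats.activity, ds.labels)
    return SelectorResult(ranking, transformed)


for _name, _fn in [
    ("variance", _sel_variance),
    ("anova", _sel_anova),
    ("prefilter_anova", _sel_prefilter_anova),
    ("postfilter_anova", _sel_postfilter_anova),
    ("extension_anova", _sel_extension_anova),
    ("weighted_anova", _sel_weighted_anova),
    ("kb_lasso", _sel_kb_lasso),
    ("pathway_activity", _sel_pathway_activity),
]:
    register_selector(_name, _fn)


def _preprocess(cfg: BenchmarkConfig, expression_key: str, metadata_key: str) -> ExpressionDataset:
    ds = load_expression_matrix(
        cfg.get("data", expression_key), delimiter=cfg.get("data", "delimiter")
    )
    meta_path = cfg.get("data", metadata_key)
    if meta_path:
        ds = attach_labels(
            ds,
            meta_path,
            cfg.get("data", "sample_id_column"),
            cfg.get("data", "label_attribute"),
        )
    ds = filter_missing(
        ds,
        cfg.get("preprocessing", "max_missing_fraction_per_feature"),
        cfg.get("preprocessing", "max_missing_fraction_per_sample"),
    )
    mapping_path = cfg.get("preprocessing", "mapping_table")
    if mapping_path:
        table = MappingTable.from_tsv(mapping_path)
        ds = map_identifiers(ds, table, cfg.get("preprocessing", "collision_policy"))
    return ds


def run_benchmark(cfg: BenchmarkConfig, out_dir: str | Path | None = None) -> dict:
    """Execute a configured benchmark; returns a summary dict.

    Preprocessing failures abort the run; a failing selector is logged and
    skipped while the others continue.  The summary's ``failed`` list is
    empty exactly when every configured selector completed.
    """
    cfg.validate(registered_selectors(), registered_classifiers())
    out = Path(out_dir or cfg.get("run", "output_dir"))
    for sub in ("preprocessing", "coverage", "rankings", "metrics",
                "enrichment", "overlaps", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    log_path = out / "logs" / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("priorfs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    seed = cfg.get("run", "seed")
    try:
        cfg.snapshot(out / "config_snapshot.ini")
        ds = _preprocess(cfg, "expression", "metadata")
        ds.values.to_csv(out / "preprocessing" / "expression_clean.tsv", sep="\t")
        if ds.labels is not None:
            ds.labels.to_csv(out / "preprocessing" / "labels.tsv", sep="\t")

        terms = cfg.getlist("knowledge", "search_terms")
        kb = net = None
        if cfg.get("knowledge", "associations"):
            kb = load_association_kb(cfg.get("knowledge", "associations"))
            coverage_report(kb, terms).table.to_csv(
                out / "coverage" / "association_coverage.tsv", sep="\t"
            )
        if cfg.get("knowledge", "gmt") and cfg.get("knowledge", "edges"):
            net = load_network_kb(
                cfg.get("knowledge", "gmt"), cfg.get("knowledge", "edges")
            )

        ctx = SelectorContext(kb, net, terms, cfg, seed)
        classifiers = cfg.getlist("evaluation", "classifiers")
        cv_k = cfg.get("evaluation", "cv_k")
        max_size = cfg.get("evaluation", "max_size")

        results: dict[str, SelectorResult] = {}
        runtimes = []
        failed = []
        for name in cfg.getlist("selection", "selectors"):
            try:
                res, seconds = ev.runtime_profile(lambda: _SELECTORS[name](ds, ctx))
                results[name] = res
                runtimes.append({"selector": name, "seconds": seconds})
                res.ranking.to_tsv(out / "rankings" / f"{name}.tsv")
            except Exception:
                logger.exception("selector %r failed; continuing", name)
                failed.append(name)
        pd.DataFrame(runtimes, columns=["selector", "seconds"]).to_csv(
            out / "metrics" / "runtimes.tsv", sep="\t", index=False
        )

        metric_tables = []
        cross_tables = []
        ds_b = None
        if cfg.get("evaluation", "cross_dataset") and cfg.get("data", "second_expression"):
            ds_b = _preprocess(cfg, "second_expression", "second_metadata")
        for name, res in results.items():
            eval_ds = res.transformed if res.transformed is not None else ds
            sizes = list(range(1, min(max_size, len(res.ranking)) + 1))
            table = ev.sweep_feature_sizes(
                res.ranking, eval_ds, classifiers, cv_k, sizes, seed
            )
            metric_tables.append(
                ev.MetricsTable(table.records.assign(selector=name))
            )
            if ds_b is not None and res.transformed is None:
                top = sel.select_top_k(res.ranking, min(max_size, len(res.ranking)))
                try:
                    cross_tables.append(
                        ev.cross_dataset_validation(
                            top, ds_b, classifiers, cv_k, seed, selector_name=name
                        )
                    )
                except ValueError:
                    logger.exception("cross-dataset validation failed for %r", name)
        if metric_tables:
            merged = ev.MetricsTable.concat(metric_tables)
            merged.records.to_csv(out / "metrics" / "cv_metrics.csv", index=False)
            merged.averaged().to_csv(out / "metrics" / "cv_metrics_averaged.csv", index=False)
        if cross_tables:
            ev.MetricsTable.concat(cross_tables).records.to_csv(
                out / "metrics" / "cross_dataset.csv", index=False
            )

        # selector comparisons run on gene-level rankings only
        gene_rankings = {
            n: r.ranking for n, r in results.items() if r.transformed is None
        }
        concordance = None
        if len(gene_rankings) >= 2:
            common = set.intersection(
                *(set(r.gene_ids) for r in gene_rankings.values())
            )
            if len(common) >= 2:
                ordered = [
                    [g for g in r.gene_ids if g in common]
                    for r in gene_rankings.values()
                ]
                concordance = ev.kendalls_w(ordered)
                pd.DataFrame(
                    [{"n_rankings": len(ordered), "n_common_genes": len(common),
                      "kendalls_w": concordance}]
                ).to_csv(out / "metrics" / "kendalls_w.tsv", sep="\t", index=False)

        top_sets = {
            n: set(sel.select_top_k(r, min(max_size, len(r))))
            for n, r in gene_rankings.items()
        }
        if len(top_sets) >= 2:
            ev.feature_overlap(top_sets).to_frame().to_csv(
                out / "overlaps" / "feature_overlap.tsv", sep="\t", index=False
            )

        lib_path = cfg.get("evaluation", "enrichment_library")
        if lib_path:
            library = {name: genes for name, (_, genes) in read_gmt(lib_path).items()}
            background = set(ds.gene_ids)
            alpha = cfg.get("evaluation", "enrichment_alpha")
            term_sets = {}
            for name, genes in top_sets.items():
                hits = ev.enrich(genes & background, library, background, alpha)
                pd.DataFrame(
                    [vars(h) for h in hits],
                    columns=["term", "overlap_count", "p_value", "adjusted_p",
                             "combined_score"],
                ).to_csv(out / "enrichment" / f"{name}.tsv", sep="\t", index=False)
                term_sets[name] = {h.term for h in hits}
            if len(term_sets) >= 2:
                ev.annotation_overlap(term_sets).to_frame().to_csv(
                    out / "overlaps" / "annotation_overlap.tsv", sep="\t", index=False
                )

        return {
            "output_dir": str(out),
            "selectors_run": sorted(results),
            "failed": failed,
            "kendalls_w": concordance,
        }
    finally:
        root.removeHandler(handler)
        handler.close()
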