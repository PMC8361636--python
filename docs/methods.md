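# Methods

This note documents the models, scores and procedures implemented in
`priorfs`, the parameters that matter, what the synthetic fixtures do and
do not emulate, and the design choices made where the design was open.

## Data model and preprocessing

The canonical container is a genes × samples matrix of normalized
expression values (`ExpressionDataset`), with optional per-sample class
labels. Input tables in either orientation are accepted: with
`orientation="auto"` the samples axis is the one whose header overlaps a
user-supplied sample-id set, and absent such a set, the axis with more
entries is taken as genes (expression studies essentially always measure
more genes than samples). A square matrix with no sample-id hint is
rejected rather than guessed.

Missing values are representable (`NaN`) and filtered by per-sample and
per-feature missing-fraction thresholds (both in [0, 1], interpreted as
fractions, not absolute counts). The samples-then-features pass repeats
until a fixed point, because removing genes changes per-sample fractions;
the iterated filter is idempotent by construction. Identifier mapping uses
local two-column tables; many-to-one collisions either keep the first
source row (`first`) or remove all colliding genes (`drop`), and the
mapper never synthesizes values — every output row is an input row.

Imputation is deliberately *not* part of preprocessing: selectors that
need complete data impute per-gene means internally, and cross-validation
fits imputation/scaling on training folds only (see Evaluation).

## Knowledge bases

Associations are `(term, gene, score)` records with scores in [0, 1],
matching the evidence-score exports of gene–disease resources. Multi-term
queries aggregate per gene by `max` (default: strong evidence for any
search term makes a gene relevant) or `mean`. Genes without a record are
*absent* from score maps rather than scored 0 — the consumer chooses the
missing-gene policy, because the right default differs between weighting
(where 0 annihilates the statistical score) and penalization.

Pathway knowledge is a GMT membership file plus a per-pathway edge list;
graphs are undirected (directed inputs symmetrize on load), self-loops and
edges naming non-members are dropped with logged counts.

### Pathway-topology gene score

For gene *i* in pathway *p* with $n_p$ members, $pr_{p,i}$ is the
fractional percentile rank of *i*'s **degree** among all member genes —
average rank for ties, isolated members included, values in (0, 1] — and

$$ s_i = \frac{\sum_p pr_{p,i}}{|P_i|} $$

averages over the $|P_i|$ pathways containing *i*. Degree was chosen as
the connectedness statistic because it is the simplest one under which hub
genes with many interactions outscore peripheral genes; centrality
variants are not implemented. Including degree-0 members means an isolated
gene in a sparse pathway still gets a (low) score rather than none.

## Feature selectors

- **Variance / ANOVA F**: per-gene sample variance (ddof = 1) and the
  one-way ANOVA F across classes, both NaN-aware and vectorized. A gene
  with zero within-class variance but real between-class separation has an
  unbounded F; it is capped at 1e12 so rankings keep finite scores.
- **Prefilter / postfilter**: restrict to KB-relevant genes (association
  score ≥ `min_score`) before or after ranking. For subset-independent
  scores such as variance or per-gene F the two commute and produce the
  same ordering; they differ for subset-dependent rankers.
- **Extension**: top `k_stat` statistical genes followed by up to `k_kb`
  KB genes not already chosen, in descending association-score order. The
  two halves live on incommensurable scales, so the reported scores are
  ordinal (length − position); original scores are kept in extra columns.
- **Weighted combination**: $s_i = s_i^{trad} \cdot s_i^{kb}$. Missing
  genes get 0 (`zero`) or a small $\varepsilon$ (`epsilon`, default
  0.001); the default is `epsilon` so that a very strong statistical
  signal can still surface a KB-unknown gene instead of being erased. The
  policy is recorded in the ranking metadata.
- **KB-penalized Lasso**: L1 logistic regression (liblinear, one-vs-rest
  for multiclass) with per-feature penalty factor
  $w_i = \mathrm{clip}(1 - s_i^{kb}, \varepsilon, 1)$ — a monotone
  decreasing map from evidence to penalty. Per-feature weights are
  realized by dividing feature columns by $w_i$ before the fit, which
  turns the uniform penalty $\lambda \lVert \beta' \rVert_1$ into
  $\lambda \sum_i w_i \lvert \beta_i \rvert$ on the original scale;
  coefficients are mapped back for ranking. The ranking score is the
  maximum absolute coefficient across the one-vs-rest problems;
  zero-coefficient genes are placed below every selected gene in
  ascending-penalty order (encoded as score $-w_i$, which realizes that
  order under the ranking's single descending sort key). With all
  $s^{kb}=0$ the selector reduces exactly to plain Lasso.
- **Pathway selection and activity**: a pathway's relevance is the mean
  |F| of its measured member genes — this reuses the ANOVA machinery,
  handles more than two classes, and rises when member expression
  co-varies with the classes. Empirical p-values come from a
  label-permutation null with a shared permutation stream across pathways
  (paired comparisons); the estimator is the add-one form
  $(1 + \#\{\text{null} \ge \text{obs}\})/(B + 1)$. Selection takes the
  top *n* pathways by relevance with p-values reported, rather than
  thresholding on p. Pathway activity for a sample is the mean z-scored
  expression of measured members (z over the provided samples; constant
  genes contribute 0). This is a deliberate simplification of
  condition-responsive-subset activity scoring: no member-subset search is
  performed.

Ties everywhere break by gene id ascending, making every ranking
deterministic; all stochastic operations take an explicit seed.

## Evaluation

Cross-validation is stratified k-fold (default k = 10) with per-gene mean
imputation and z-scaling fit inside each training fold (a sklearn
pipeline), so no test-fold statistic leaks into the fit — the test suite
checks fold-wise equality against a hand-rolled train-only oracle on a
fixture with an extreme canary value. Samples are put in a canonical
sorted order before splitting, so fold assignment depends only on
(labels, k, seed): reordering input columns or comparing selectors on the
same dataset cannot change the folds, which makes selector comparisons
paired by design. Metrics are accuracy and macro-averaged F1 (macro
because multi-class case studies are the norm and no class should
dominate); the averaged view means over folds, then over classifiers.

The classifier panel is Gaussian naive Bayes, logistic regression (the
linear-model classifier; an ordinary regression on labels is not a
classifier), RBF-kernel SVM, 100-tree random forest, and kNN with k = 3.
Hyperparameters are fixed constants recorded in the config snapshot.

Kendall's W uses the tie-corrected form
$W = 12S / (m^2(n^3-n) - m\sum_j T_j)$ with average ranks for ties; a
panel of identical all-tied rankings has a zero denominator and is
reported as vacuous concordance 1.0. Overlap summaries are upset-style
exclusive intersection counts, which partition the union.

Enrichment is a local Fisher-exact over-representation test
(hypergeometric upper tail) against a user-supplied background, with
Benjamini–Hochberg adjustment (the conventional choice where only an
"adjusted p" is required), an adjusted-p cutoff (default 0.05), and
descending sort by the combined score $-\ln(p)\,z$, where *z* is the
overlap's deviation from its hypergeometric expectation in null SD units.

## Orchestration

Configuration is layered INI: built-in defaults, an optional main file,
and a user file that overrides only the keys it names; unknown sections or
keys fail with the offending name. A run writes stage subdirectories
(preprocessing/, coverage/, rankings/, metrics/, enrichment/, overlaps/,
logs/) plus a config snapshot that alone reproduces the run. Selector
failures are isolated — logged, excluded from downstream comparisons, and
reflected in a non-zero exit code — while preprocessing failures abort.
Kendall's W across selectors is computed on the intersection of their
ranked gene sets (prior-knowledge filters legitimately shrink the
universe); network selectors produce pathway-level rankings and are
evaluated by CV on their activity matrices but excluded from gene-level
concordance and overlap comparisons. Runtime per selector goes to a
separate ledger file so analytic outputs stay byte-identical across
identical runs.

## Synthetic fixtures

The generator emulates a normalized, roughly Gaussian (log-like)
expression study: unit within-class noise; `n_informative` planted genes
whose class-c mean is `± effect_size · c` (random sign per gene), so
adjacent classes differ by one effect size; balanced classes; uniform
missingness at `missing_rate`. Defaults — 1000 genes, 100 samples, 2
classes, 10 informative genes, effect size 2.0 within-class SDs — describe
a moderately powered two-group cohort in which single-gene separation is
strong but imperfect. The association KB scores planted genes near 0.9 and
a 30 % covered fraction of null genes near 0.1 (jitter ±0.05, clipped to
[0, 1]). Pathway fixtures are `n_pathways` random graphs of
`pathway_size` members with a `hub_fraction` of designated hubs wired to
every other member over a sparse random background, plus one signal
pathway built from the planted genes. A paired second cohort reuses the
planted structure with fresh noise and an optional global mean shift
emulating an un-harmonized cohort effect.

What the fixtures do **not** emulate: RNA-seq count distributions and
mean–variance coupling, gene–gene correlation beyond the planted class
structure, batch effects beyond a global shift, class imbalance (available
but not default), or realistic pathway topology. Tests passing on these
fixtures demonstrate correctness of the algorithms and calibration of the
statistics under the stated model — not performance on real cohorts.

## Numerical choices and limitations

- ANOVA with a class that has no observed value for a gene yields score 0
  for that gene rather than an error; datasets whose label counts violate
  the ≥ 2-per-class precondition are rejected up front.
- Lasso non-convergence within `max_iter` (default 5000) raises rather
  than returning a half-converged ranking.
- Z-scoring of constant genes maps them to 0 (no division by zero).
- Empirical p-values are positively biased by the add-one estimator at
  small permutation counts; this is the standard validity-preserving
  trade-off.
- The test suite and the acceptance script use scaled-down problem sizes
  (tens to hundreds of genes for pipeline-level checks, the full default
  spec for recovery checks); sizes are stated in each test and were chosen
  to exercise the algorithms, not to stress throughput.
- Live knowledge-base services, normalization, probe-level processing and
  figure rendering are out of scope; the quantities behind the usual plots
  (overlap counts, per-size metric curves, coverage summaries) are all
  written as tables.
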