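# tnbclayers

Two-layer molecular classification of triple-negative breast cancer (TNBC)
from bulk gene-expression cohorts.

TNBC lacks the three receptors (ER, PR, HER2) that drive targeted therapy in
other breast cancers, and it is molecularly heterogeneous. `tnbclayers`
implements a classification strategy that reads that heterogeneity as two
*independent* biological layers:

1. **Cellular layer** — where along the mammary stem-cell differentiation
   axis the tumor sits: `CLDN-low` → `CLDN-high` → `basal` → `LAR`
   (luminal androgen receptor).
2. **Immune layer** — how much immune activity the tumor carries:
   `IM+` vs `IM-`.

## Method

Starting from a probes × samples intensity matrix:

1. **Preprocess** — per-sample median scaling ("magnitude" normalization),
   log2, one-way batch-effect removal, gene mean-centering, collapse of
   probes to their highest-variance representative, selection of the
   top-k most variable genes (k = 2000 by default).
2. **Network** — all gene pairs are scored by Gaussian mutual information,
   MI(r) = −½·ln(1 − r²) for Pearson correlation r, and a maximum-weight
   spanning forest (Chow–Liu construction) is built over the scores; edges
   below the MI of |r| = 0.3 are discarded. The forest is cut into
   **branches** by repeatedly deleting its weakest edge until every
   component is small enough.
3. **Functional nodes** — each branch is annotated by hypergeometric
   over-representation against a user-supplied gene-set collection (GMT),
   Benjamini–Hochberg adjusted; annotated branches become functional nodes
   whose **activity** is the mean expression of their genes per sample.
4. **Metanodes** — nodes are grouped by average-linkage hierarchical
   clustering under correlation distance, and each group is tagged with the
   marker role (luminal / basal / immune) most enriched in its gene union.
   Claudin status is carried by the single functional node containing
   CLDN3/CLDN4/CLDN7.
5. **Classification** — sparse k-means (Witten–Tibshirani: non-negative
   feature weights, ‖w‖₂ = 1, ‖w‖₁ ≤ s, maximizing the weighted
   between-cluster sum of squares) splits the cohort into a high- and a
   low-activity group per layer. The cellular decision tree is:
   luminal-high → `LAR`; else basal-high → `basal`; else claudin activity
   separates `CLDN-high` from `CLDN-low`. The immune metanode gives
   `IM+`/`IM-` independently.
6. **Transfer** — per-subgroup centroids (mean centered-log2 profiles over
   the metanode genes) classify new cohorts by nearest centroid.
7. **Survival** — Kaplan–Meier curves, Mantel–Cox log-rank tests and a
   binary-covariate Cox model (Newton–Raphson, Breslow ties, Wald 95% CI)
   characterize the subgroups, alongside Kruskal–Wallis/Dunn, Fisher and
   chi-squared association tests.

Because the cohorts this method was designed around live in public
repositories, the package ships a **synthetic cohort generator**
(`tnbclayers.synthetic`) that reproduces the statistical structure the
analysis assumes — 26 latent-factor gene modules with role-specific mean
shifts, an independent immune layer, batch shifts, and exponential
relapse-free survival — so the entire pipeline is testable offline.

## Worked example

```python
from tnbclayers import synthetic, pipeline

spec = synthetic.default_cohort_spec(n_total=400, seed=0)
expr, truth = synthetic.generate_expression(spec, output_scale="raw")
result = pipeline.run_pipeline(
    expr,
    synthetic.default_gene_sets(spec),
    synthetic.default_markers(spec),
    pipeline.PipelineParams(top_k=expr.n_genes, seed=0),
)
print(result.manifest["cellular_counts"])
print(result.manifest["immune_counts"])
```

prints

```
{'basal': 252, 'LAR': 72, 'CLDN-low': 57, 'CLDN-high': 19}
{'IM-': 202, 'IM+': 198}
```

i.e. of 400 simulated tumors, 252 are called basal, 72 LAR, 57 CLDN-low and
19 CLDN-high, and the orthogonal immune split is nearly balanced — matching
the planted design (63% basal, 18% LAR, 50% IM+). Against the generator's
truth table the cellular labels reach an adjusted Rand index of 0.963 and
the immune labels 0.941. A survival contrast of the recovered immune groups
(simulated hazards 0.008 vs 0.016 events/month):

```python
from tnbclayers.survival import compare_groups
res = compare_groups(times, events, result.calls["immune"], "IM-", "IM+")
```

gives HR 0.552 (95% CI 0.431–0.706), log-rank p = 1.7e-06 — the protective
immune-positive effect the simulation planted.

The same stages are available as a CLI:

```bash
tnbclayers simulate --out sim/ --seed 3
tnbclayers preprocess --in sim/expression.tsv --out sim/pre.tsv
tnbclayers run --out run/ --seed 3          # whole pipeline, one call
```

## Layout

- `src/tnbclayers/io.py` — data model, TSV/GMT readers and writers
- `src/tnbclayers/synthetic.py` — cohort generator and default study design
- `src/tnbclayers/preprocess.py` — normalization chain
- `src/tnbclayers/network.py` — MI graph, spanning forest, branches
- `src/tnbclayers/nodes.py` — over-representation labeling
- `src/tnbclayers/activity.py` — node activity, metanodes, role assignment
- `src/tnbclayers/classify.py` — sparse k-means and the decision workflow
- `src/tnbclayers/transfer.py` — centroid construction and assignment
- `src/tnbclayers/survival.py` — KM / log-rank / Cox / association tests
- `src/tnbclayers/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
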