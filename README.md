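# tcellfate

Analytics for adoptive T-cell therapy cohorts profiled with paired
scRNA-seq/scTCR-seq: where engineered, antigen-specific CD8⁺ T cells sit on
the naïve → effector-memory (Tem) → NK-like/Temra (NKL) differentiation
axis, how clonal expansion couples to that axis, and whether clinical risk
factors explain which patients keep the cells long-term.

The package is written for translational immunologists and computational
biologists analyzing engineered-cell persistence — the motivating setting
is WT1-specific TCR-transduced CD8⁺ T cells infused into AML patients
after allogeneic transplant — but every operation is generic over a cell ×
gene matrix, per-cell metadata, a 2D embedding and clonotype assignments.

## What it computes

- **QC** — per-cell filtering at median ± k·MAD (k = 3.5 default, MAD
  scaled by 1.4826) over total counts, detected features and
  mitochondrial/ribosomal percentages; features kept when count > 1 in
  ≥ 3 cells.
- **Module scores** — for a gene set *S* with expression-bin-matched
  control genes *C*: `score(cell) = mean_{g∈S} x_g − mean_{g∈C} x_g` on
  log-normalized data (24 bins, 100 controls/gene, seeded); shipped
  self-renew (*TCF7, LEF1, SELL, CCR7, BCL2, IL7R, CD27, CD28*) and
  NK-like (*ZEB2, S1PR5, CX3CR1, KLRG1, NKG7, FCRL6, KLRD1, ADGRG1*)
  signatures, 75th-percentile "high" masks, and LOESS-smoothed score
  trends with 95% bands.
- **Blast score** — min of min-max-scaled *CD34* and *XIST* expression, a
  soft AND flagging recipient-origin blasts in a sex-mismatched transplant.
- **Gating / purification** — hierarchical marker gates (CD3 → CD8 →
  tetramer → Ki67) and positive-minus-negative marker scores split by the
  between-class-variance-maximizing two-class threshold.
- **Clonal dynamics** — frequency bins Rare (0, 10⁻⁴] … Hyperexpanded
  (0.1, 1], occupied-repertoire tables, expansion-stratified gene
  contrasts, and clonotype-anchored trajectories: for each expanded clone
  spanning ≥ 2 clusters, cluster centroids ordered by within-clone cell
  count give displacement vectors tracing its differentiation.
- **Embedding overlap** — engineered cells within Euclidean distance 0.1
  of any endogenous NKL/Temra cell in the embedding are labeled
  NKL-overlapping.
- **Persistence statistics** — 3%-of-CD8 persistence calls (day-28
  landmark, long-term > day 100), cohort summaries, and a from-first-
  principles two-sided Fisher exact test
  `p = Σ {P(T) : P(T) ≤ P(T_obs)}` over the hypergeometric support,
  accumulated in log space.
- **Synthetic cohorts** — a negative-binomial generator planting the full
  structure above (axis-linked signatures and clone sizes, transgene⁺
  subpopulation, AML-restricted XIST⁺CD34⁺WT1⁺ blasts) with ground truth
  for recovery testing, plus the packaged 15-patient trial summary table.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from tcellfate import (
    CohortSpec, PurityModel, build_risk_table, fisher_exact_2x2,
    generate_cohort, generate_patient_courses, module_score, qc_filter, purify,
)
from tcellfate.signatures import NK_LIKE

# clinical cohort: risk factors vs long-term persistence
courses = generate_patient_courses(fixture="paper_table1")
table = build_risk_table(courses)          # EBV cohort with WT1 data, n = 9
print(table.as_tuple(), round(fisher_exact_2x2(table), 3))
table2 = build_risk_table(courses, reclassify={"8": "lowrisk"})
print(table2.as_tuple(), round(fisher_exact_2x2(table2), 3))

# synthetic single-cell cohort: NK-like skewing along the planted axis
cells, clones, truth = generate_cohort(CohortSpec(n_patients=2, cells_per_sample=250, seed=7))
cells = qc_filter(cells)
nk = module_score(cells, NK_LIKE, n_ctrl=20, seed=0).scores
print(nk.groupby(cells.obs["cluster"]).mean().round(2))
```

prints

```
(1, 2, 6, 0) 0.083
(0, 3, 6, 0) 0.012
cluster
NKL_Temra     0.25
TTCR_Tem     -0.65
TTCR_Temra   -0.25
Tem          -1.13
blast        -0.83
naive_cm     -1.49
```

The contingency tuple is (persistent ∧ high-risk, persistent ∧ low-risk,
non-persistent ∧ high-risk, non-persistent ∧ low-risk): all six
non-persisting evaluable EBV patients carried a risk factor (p = 0.083;
p = 0.012 after reclassifying patient 8, whose disease was cleared before
the second infusion). The NK-like module score increases monotonically
from the naïve to the NKL/Temra end of the differentiation axis, as
planted by the generator.

A CLI mirrors the library: `tcellfate simulate`, `score`, `pipeline`,
`persistence` (see `tcellfate --help`).

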