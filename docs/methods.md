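# Methods

`tcellfate` re-implements, as a tested library, the correlative-analysis
procedures used to study engineered, WT1-specific CD8⁺ T cells (T cells
transduced with the TCR-C4 receptor) infused into AML patients after
allogeneic transplant: where the cells sit on the naïve → effector-memory
(Tem) → NK-like/Temra (NKL) differentiation axis, how clonal expansion
couples to that axis, and whether clinical risk factors explain which
patients retain the cells long-term. Because the underlying single-cell
data live in controlled-access archives, the package ships a synthetic
cohort generator that plants the same statistical structure, so every
stage is verifiable offline against known ground truth.

## Data model

Cells are held in a thin wrapper around `AnnData` with a raw `counts`
layer, a `lognorm` layer (counts scaled to 10,000 per cell, then log1p —
the default transform of mainstream single-cell toolkits) and per-cell
metadata (sample, subject, timepoint in days post-infusion, tissue PB/BM,
AML status, cluster label, optional 2D embedding). Clonotypes are a
separate per-cell table keyed by the sorted, `+`-joined `locus:CDR3aa`
string over productive chains (paired TRA+TRB when both were recovered,
TRB-only otherwise); when a cell carries more than one productive chain
per locus, the chain with the highest read support is kept. Clone
frequency is the clone's cell count divided by the total cells in the
sample, so frequencies over distinct clones sum to ≤ 1 and to exactly 1
when every cell has a clonotype.

## Quality control

Cells are filtered on four per-cell metrics (total counts, detected
features, % mitochondrial counts with the `MT-` prefix convention, %
ribosomal counts with `RPS`/`RPL` prefixes): a cell is removed when any
metric falls outside median ± k·MAD, with the MAD scaled by the normal
consistency constant 1.4826 and k defaulting to 3.5 (the permissive end of
the 1–3.5 range used in per-sample tuning; exposed in `QcParams`). A MAD
of zero means "no spread" and keeps all cells for that metric, avoiding
degenerate total removal. Features with a count > 1 in fewer than 3 cells
are removed. The two filters are iterated to a fixed point, which makes
`qc_filter` exactly idempotent; with k = 3.5 the fixed point is reached
within one or two iterations on realistic data, so this differs from a
single pass only in pathological cases.

## Module scores, blast score, LOESS

`module_score` implements the bin-matched-control scheme: features are
ranked by dataset-mean expression into `n_bins` = 24 equal-size bins; each
signature gene draws `n_ctrl` = 100 control features (seeded, without
replacement; with replacement plus a warning when the bin is smaller) from
its own bin; the score is mean(signature) − mean(control pool) on the
log-normalized layer. The score is exactly zero on constant matrices and
invariant to adding a constant to every feature, and its seed-to-seed
jitter shrinks as `n_ctrl` grows. The shipped signatures are the
self-renew module (TCF7, LEF1, SELL, CCR7, BCL2, IL7R, CD27, CD28) and the
NK-like module (ZEB2, S1PR5, CX3CR1, KLRG1, NKG7, FCRL6, KLRD1, ADGRG1).
"High" cells are those strictly above the 75th percentile
(linear-interpolation percentile) of the score vector.

The blast score flags recipient-origin leukemic cells in a sex-mismatched
(female patient, male donor) transplant from CD34/XIST co-expression: each
marker's log-normalized expression is min-max scaled across cells and the
score is the minimum over markers. No published formula exists for this
combination; min was chosen as the natural soft-AND — a cell scores
positive only when every marker is detected — and is recorded here as this
package's convention. WT1 can be added as a third marker.

`loess_trend` smooths (day, score) series by degree-1 local regression
with tricube weights over the `span` = 0.75 fraction of nearest points,
evaluated on a 100-point grid over the observed range. The pointwise 95%
band uses the equivalent-kernel variance with a single global residual
variance estimated from the in-sample fit (n − 2 degrees of freedom).
Local linear fits reproduce straight lines exactly, which the tests assert
to 1e-8.

## Gating and purification

`gate_hierarchy` applies an ordered marker-threshold tree (e.g. CD3 → CD8
→ tetramer → Ki67 split into proliferative Tem vs non-proliferative
Temra); terminal labels always partition the last parent gate. Panels
flagged `cytometry` are arcsinh-transformed (cofactor 5) before gating,
following standard cytometry practice; expression panels use the
log-normalized layer. `purify` scores cells as mean(positive markers) −
mean(negative markers); in `two_class` mode the cutoff is the 1-D
two-cluster split maximizing between-class variance over all n − 1 sorted
cut points (equivalent to Otsu's criterion), with ties broken toward the
first maximum and an all-equal score vector yielding all-negative calls
plus a warning. The interactive gates used on real cytometers are not
numerically reported anywhere, so the two-class splitter is the default
and fixed cutoffs are accepted where known.

## Clonal dynamics

Clone-frequency bins are half-open `(lo, hi]` intervals covering (0, 1]
with the conventional edges Rare (0, 1e-4], Small (1e-4, 1e-3], Medium
(1e-3, 0.01], Large (0.01, 0.1], Hyperexpanded (0.1, 1]; the published
figures show five ranges without printing edges, and these are the
defaults of the repertoire toolkit that analysis used. The occupied
repertoire is the per-cluster (or per-timepoint) cell count stratified by
bin. Trajectory inference keeps Large + Hyperexpanded clones (configurable)
occupying ≥ 2 clusters, orders each clone's clusters by its own within-
clone cell count ascending (ties by cluster label, for determinism),
computes per-cluster centroids as arithmetic means of member-cell embedding
coordinates, and emits displacement vectors between successive centroids
plus the net first-to-last vector. Ordering by the clone's own counts (not
cluster totals) encodes the assumption that a clone's least-abundant state
is its earliest. The expansion contrast compares Hyperexpanded+Large vs
Medium+Small cells per signature gene (fraction expressing, mean log-norm
expression, two-sided rank-sum p, Benjamini–Hochberg across the signature).

## Embedding overlap

Engineered cells are labeled NKL-overlapping when their nearest endogenous
NKL/Temra reference cell lies within 0.1 (inclusive) Euclidean distance in
the supplied 2D embedding. The implementation uses a k-d tree but is
tested to agree exactly with the brute-force all-pairs oracle; the
threshold is in raw embedding units and does not transfer across
embeddings with different scales — re-deriving it is the user's
responsibility.

## Persistence and risk statistics

Persistence calls use the 3% — of — circulating-CD8 threshold: the day-28
landmark takes the measurement nearest day 28 within ± 7 days (sampling
days vary around nominal visits; the window is configurable), and
long-term persistence additionally requires a > 3% measurement at some day
> 100. Under this landmark rule long-term persistence implies the day-28
crossing. The risk table crosses long-term persistence with high-risk
status (detectable disease within ~2 weeks pre-infusion OR relapse ≤ 3
months post-transplant) over the EBV-specific cohort with WT1 expression
data available; per-patient overrides support sensitivity reclassification.
For the packaged 15-patient trial fixture the clinical flags and
persistence calls are transcribed inputs (the raw longitudinal series are
published only graphically), documented per patient in the fixture TSV.

The Fisher exact test is implemented from first principles: the p-value is
the sum of hypergeometric probabilities, accumulated in log space via
log-gamma binomials and log-sum-exp, over all tables with the observed
margins whose probability is at most the observed table's probability
within a 1 + 1e-7 relative tolerance (the convention of standard
statistical environments, so printed p-values reproduce). Degenerate
margins give p = 1. The suite checks exact agreement with independent
enumeration for all tables with N ≤ 24 and a seeded sample up to N = 40.
On the trial cohort the 9-patient table (1, 2, 6, 0) gives p = 1/12 ≈ 0.083
and the patient-8 reclassification (0, 3, 6, 0) gives p = 1/84 ≈ 0.012.

## Synthetic cohort generator

`generate_cohort` emulates, per sample: (i) T cells placed on a 5-state
axis (naive_cm → Tem → TTCR_Tem → TTCR_Temra → NKL_Temra) whose occupancy
drifts toward the NKL end at later timepoints (`state_drift`, default 1.0);
(ii) zipf-like clone sizes (exponent 1.2) with larger clones homed further
along the axis at strength `expansion_coupling` (default 0.9) and member
cells spread over clusters up to the home state with geometrically
increasing counts, so the planted differentiation direction is recoverable
from count-ordered centroids; (iii) negative-binomial counts (shared
dispersion θ = 2) with signature genes elevated in their home states by
`signature_effect` (default 1.5 log-fold), a highly expressed transgene
feature (`TCRC4`) in a transgene⁺ subpopulation (default 20% of T cells,
concentrated in the engineered clusters), and CD34⁺WT1⁺ blasts (default 5%)
only in AML-positive samples, with XIST confined to blasts of female
patients (sex-mismatch logic; patients alternate F/M); (iv) an embedding
generated directly from the axis (arc in 2D, Gaussian jitter σ = 0.05) —
it is an input, mirroring pipelines whose UMAP is precomputed, not a
learned reduction. Defaults (2 patients × 4 timepoints × 500 cells, 800
genes) are sized so tests and the acceptance script finish quickly while
keeping ≥ 200 clones for rank-correlation checks.

What the generator does *not* model: transcriptome-wide gene–gene
correlation, batch effects, ambient RNA, doublets, or shared clones across
timepoints (each sample draws its own clones). Passing recovery tests
therefore demonstrates that the inference operations are correct under the
planted model, not that the biological conclusions would replicate on real
data. No quantitative per-timepoint effect sizes were published for the
NKL skewing; `signature_effect`, `state_drift` and the NB dispersion are
free parameters chosen once at realistic single-cell magnitudes and
documented here.

## Problem sizes and numerical choices

The test suite uses a shared 2,000-cell cohort (2 patients × 4 timepoints
× 250 cells); trajectory-recovery checks use 2,400 cells / ~300 clones per
seed over 3 seeds, and the overlap oracle runs at 500 × 500 points. All
randomness flows through `numpy.random.default_rng` seeds; outputs are
written with deterministic row order (cell_id ascending) so repeated runs
are byte-identical, which the suite asserts on the full pipeline. LOESS
falls back to a 1e-10 ridge term only when a local design is numerically
singular (all weight on one x).

## Known limitations

- The trial fixture encodes transcribed clinical groupings; it cannot
  re-derive persistence from raw series that were never published.
- The blast-score formula (min of scaled markers) is this package's
  convention for an operation whose published description names only the
  markers.
- Frequency-bin edges and QC k-values are configurable because the source
  analyses tuned them per sample without reporting the values.
- Module scores on panels much smaller than `n_bins × n_ctrl` genes fall
  back to replacement sampling; prefer lowering `n_ctrl` on small panels.
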