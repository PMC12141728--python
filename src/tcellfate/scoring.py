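"""Per-cell gene-module scores, percentile masks and LOESS score trends.

The module score follows the bin-matched-control scheme standard in
single-cell toolkits: features are ranked by dataset-mean expression into
equal-size bins, each signature gene draws control features from its own
bin, and the score is the signature mean minus the control-pool mean on the
log-normalized layer.  This makes the score robust to the overall
expression level of the signature genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tcellfate.dataio import CellTable, ModuleSignature

logger = logging.getLogger("tcellfate")


@dataclass
class ScoreResult:
    """Per-cell scores for one signature plus an optional high-score mask."""

    signature: str
    scores: pd.Series  # indexed by cell_id
    high_flag: pd.Series | None = None
    percentile: float | None = None


def module_score(
    cells: CellTable,
    sig: ModuleSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    layer: str = "lognorm",
) -> ScoreResult:
    """Signature mean minus bin-matched control mean, per cell.

    Controls are sampled without replacement from each signature gene's
    expression bin (``n_ctrl`` per gene, seeded); if a bin is smaller than
    ``n_ctrl`` the sample falls back to replacement with a warning.
    """
    present = [g for g in sig.genes if g in cells.var_names]
    missing = sorted(set(sig.genes) - set(present))
    if not present:
        raise KeyError(f"signature {sig.name}: no genes present (missing {missing})")
    if missing:
        logger.warning("signature %s: missing genes %s", sig.name, missing)

    X = cells.layer(layer)
    gene_mean = X.mean(axis=0)
    order = np.argsort(gene_mean, kind="stable")
    n_genes = X.shape[1]
    # equal-size bins over the mean-expression ranking
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // n_genes, n_bins - 1
    )

    rng = np.random.default_rng(seed)
    var_index = {g: i for i, g in enumerate(cells.var_names)}
    sig_idx = np.array([var_index[g] for g in present])
    ctrl_idx: list[np.ndarray] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        pool = pool[~np.isin(pool, sig_idx)]
        if len(pool) == 0:
            continue
        if len(pool) < n_ctrl:
            warnings.warn(
                f"control bin for gene index {gi} has {len(pool)} < {n_ctrl} "
                "candidates; sampling with replacement",
                stacklevel=2,
            )
            ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
        else:
            ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=False))
    ctrl = np.concatenate(ctrl_idx) if ctrl_idx else np.array([], dtype=int)

    sig_mean = X[:, sig_idx].mean(axis=1)
    ctrl_mean = X[:, ctrl].mean(axis=1) if len(ctrl) else np.zeros(len(X))
    scores = pd.Series(sig_mean - ctrl_mean, index=cells.cell_ids, name=sig.name)
    return ScoreResult(signature=sig.name, scores=scores)


def blast_score(
    cells: CellTable,
    markers: tuple[str, str] = ("CD34", "XIST"),
    extra: str | None = None,
    layer: str = "lognorm",
) -> ScoreResult:
    """Co-expression score for recipient-origin blasts.

    Each marker's log-normalized expression is min-max scaled to [0, 1]
    across cells; the score is the minimum over markers (a soft AND), so a
    cell scores above zero only when every marker is detected.  The blast
    flag is ``score > 0``.
    """
    names = list(markers) + ([extra] if extra else [])
    X = cells.expression(names, layer=layer)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (X - lo) / span
    score = scaled.min(axis=1)
    scores = pd.Series(score, index=cells.cell_ids, name="blast")
    return ScoreResult(
        signature="blast",
        scores=scores,
        high_flag=scores > 0,
        percentile=None,
    )


def percentile_mask(scores: pd.Series, q: float = 75.0) -> pd.Series:
    """True where a score strictly exceeds the q-th percentile of scores."""
    if len(scores) == 0:
        raise ValueError("no scores")
    cutoff = np.percentile(scores.to_numpy(float), q)  # linear interpolation
    return scores > cutoff


def loess_trend(
    points,
    span: float = 0.75,
    ci: float = 0.95,
    n_grid: int = 100,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tricube-weighted local linear regression with a pointwise CI.

    At each grid point the ``ceil(span * n)`` nearest observations receive
    tricube weights and a degree-1 weighted least-squares fit is evaluated;
    the confidence band comes from the equivalent-kernel variance with a
    global residual variance estimate.

    Returns a DataFrame with columns x, y, lo, hi.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values")
    n = len(x)
    k = max(2, int(np.ceil(span * n)))

    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)

    from scipy.stats import norm

    z = norm.ppf(0.5 + ci / 2)
    fits = np.empty(len(grid))
    ses = np.empty(len(grid))
    hat_rows = []
    for j, x0 in enumerate(grid):
        d = np.abs(x - x0)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            dmax = np.finfo(float).eps
        w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
        w[d > dmax] = 0.0
        # weighted degree-1 fit; equivalent kernel l so that yhat = l @ y
        W = np.diag(w)
        A = np.column_stack([np.ones(n), x - x0])
        AtWA = A.T @ W @ A
        # ridge fallback for degenerate local designs (all weight on one x)
        if np.linalg.cond(AtWA) > 1e12:
            AtWA = AtWA + np.eye(2) * 1e-10
        l = (np.linalg.solve(AtWA, A.T @ W))[0]
        fits[j] = l @ y
        hat_rows.append(l)

    # residual variance from in-sample equivalent-kernel predictions
    resid = y - np.array([row @ y for row in _rows_at(x, x, k)])
    dof = max(n - 2.0, 1.0)
    sigma2 = float(resid @ resid) / dof
    for j, l in enumerate(hat_rows):
        ses[j] = np.sqrt(sigma2 * float(l @ l))
    return pd.DataFrame(
        {"x": grid, "y": fits, "lo": fits - z * ses, "hi": fits + z * ses}
    )


def _rows_at(x: np.ndarray, targets: np.ndarray, k: int):
    """Equivalent-kernel rows of the LOESS smoother at the given targets."""
    n = len(x)
    for x0 in targets:
        d = np.abs(x - x0)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            dmax = np.finfo(float).eps
        w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
        w[d > dmax] = 0.0
        W = np.diag(w)
        A = np.column_stack([np.ones(n), x - x0])
        AtWA = A.T @ W @ A
        if np.linalg.cond(AtWA) > 1e12:
            AtWA = AtWA + np.eye(2) * 1e-10
        yield (np.linalg.solve(AtWA, A.T @ W))[0]
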