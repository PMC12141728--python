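"""Marker-threshold in-silico gating and score-based cell purification.

``gate_hierarchy`` mimics a flow-cytometry gating tree (e.g. CD3 -> CD8 ->
tetramer -> Ki67 split); ``purify`` scores cells on positive-minus-negative
marker expression and classifies them either by a fixed cutoff or by the
1-D two-class split that maximizes between-class variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tcellfate.dataio import CellTable, ValidationError

logger = logging.getLogger("tcellfate")

_COMPARATORS = {">": np.greater, "<=": np.less_equal}


@dataclass
class GateDefinition:
    """An ordered marker-threshold hierarchy ending in a two-way split.

    ``steps`` are (marker, comparator, threshold) filters applied in
    sequence; the terminal ``split_marker`` partitions the surviving cells
    into ``split_labels`` = (label if > threshold, label otherwise).
    """

    steps: list[tuple[str, str, float]]
    split_marker: str
    split_threshold: float
    split_labels: tuple[str, str]
    cytometry: bool = False  # arcsinh-transform raw values before gating
    arcsinh_cofactor: float = 5.0

    def __post_init__(self) -> None:
        for marker, cmp, thr in self.steps:
            if cmp not in _COMPARATORS:
                raise ValidationError(f"comparator must be one of {list(_COMPARATORS)}")
            if not np.isfinite(thr):
                raise ValidationError(f"non-finite threshold for {marker}")
        if not np.isfinite(self.split_threshold):
            raise ValidationError("non-finite split threshold")


@dataclass
class PurityModel:
    """Positive/negative marker lists plus a threshold mode."""

    positive_markers: list[str]
    negative_markers: list[str] = field(default_factory=list)
    threshold_mode: str = "two_class"  # or "fixed"
    fixed_cutoff: float = 0.0

    def __post_init__(self) -> None:
        if not self.positive_markers:
            raise ValidationError("positive_markers must be non-empty")
        overlap = set(self.positive_markers) & set(self.negative_markers)
        if overlap:
            raise ValidationError(f"markers in both lists: {sorted(overlap)}")
        if self.threshold_mode not in ("fixed", "two_class"):
            raise ValidationError("threshold_mode must be 'fixed' or 'two_class'")


def _gate_values(cells: CellTable, marker: str, gate: GateDefinition) -> np.ndarray:
    if marker not in cells.var_names:
        raise KeyError(f"gate marker absent from panel: {marker}")
    if gate.cytometry:
        raw = cells.expression([marker], layer="counts")[:, 0]
        return np.arcsinh(raw / gate.arcsinh_cofactor)
    return cells.expression([marker], layer="lognorm")[:, 0]


def gate_hierarchy(cells: CellTable, gate: GateDefinition):
    """Apply the gate tree; returns (per-cell labels, per-level counts).

    Cells failing any step receive the label ``None``; survivors of every
    step receive exactly one of the two terminal labels, so the terminal
    subset sizes always sum to the size of the last parent gate.
    """
    mask = np.ones(cells.n_cells, dtype=bool)
    levels = [("all", int(mask.sum()))]
    for marker, cmp, thr in gate.steps:
        vals = _gate_values(cells, marker, gate)
        mask &= _COMPARATORS[cmp](vals, thr)
        levels.append((f"{marker}{cmp}{thr:g}", int(mask.sum())))

    vals = _gate_values(cells, gate.split_marker, gate)
    pos_label, neg_label = gate.split_labels
    labels = pd.Series([None] * cells.n_cells, index=cells.cell_ids, dtype=object)
    labels[mask & (vals > gate.split_threshold)] = pos_label
    labels[mask & ~(vals > gate.split_threshold)] = neg_label
    levels.append((pos_label, int((labels == pos_label).sum())))
    levels.append((neg_label, int((labels == neg_label).sum())))
    counts = pd.DataFrame(levels, columns=["level", "n_cells"])
    return labels, counts


def two_class_split(scores: np.ndarray) -> float:
    """Threshold maximizing between-class variance over all n-1 cut points.

    Returns the midpoint between the two classes; all-equal input returns
    +inf (nothing positive) with a warning.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    n = len(s)
    uniq = np.unique(s)
    if len(uniq) == 1:
        warnings.warn("degenerate all-equal scores; labeling all negative", stacklevel=2)
        return np.inf
    csum = np.cumsum(s)
    total = csum[-1]
    best_var, best_cut = -np.inf, np.inf
    for i in range(1, n):  # lower class = s[:i]
        if s[i - 1] == s[i]:
            continue  # cannot cut inside a tie class
        w0, w1 = i / n, (n - i) / n
        m0 = csum[i - 1] / i
        m1 = (total - csum[i - 1]) / (n - i)
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var = var
            best_cut = 0.5 * (s[i - 1] + s[i])
    return best_cut


def purify(cells: CellTable, model: PurityModel, layer: str = "lognorm"):
    """Score and classify cells on positive-minus-negative marker means.

    Returns (positive flag per cell, score per cell, threshold used).
    """
    pos = cells.expression(model.positive_markers, layer=layer).mean(axis=1)
    if model.negative_markers:
        neg = cells.expression(model.negative_markers, layer=layer).mean(axis=1)
    else:
        neg = np.zeros(cells.n_cells)
    score = pos - neg
    if model.threshold_mode == "fixed":
        cutoff = model.fixed_cutoff
    else:
        cutoff = two_class_split(score)
    flags = pd.Series(score > cutoff, index=cells.cell_ids, name="positive")
    return flags, pd.Series(score, index=cells.cell_ids, name="purity_score"), cutoff
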