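"""Embedding-overlap classification of query cells against a reference.

A query cell (e.g. an engineered transgene+ T cell) is "overlapping" when
its nearest reference cell (e.g. endogenous NKL/Temra) lies within a
Euclidean threshold distance in the supplied 2D embedding.  The threshold
is in raw embedding units and is therefore specific to the embedding scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from tcellfate.dataio import CellTable, ValidationError


@dataclass
class OverlapParams:
    threshold: float = 0.1
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if self.metric != "euclidean":
            raise ValidationError("only the euclidean metric is supported")


def classify_overlap(
    query: CellTable, reference: CellTable, params: OverlapParams | None = None
) -> pd.DataFrame:
    """Flag query cells within the threshold distance of any reference cell.

    Returns a DataFrame indexed by query cell_id with columns
    ``nearest_distance`` and ``overlapping`` (min distance <= threshold).
    """
    params = params or OverlapParams()
    q, r = query.embedding, reference.embedding
    if q is None or r is None:
        raise ValidationError("both query and reference need embeddings")
    if np.isnan(q).any() or np.isnan(r).any():
        raise ValidationError("embeddings contain missing coordinates")
    if len(r) == 0:
        raise ValidationError("reference is empty")
    dist, _ = cKDTree(r).query(q, k=1)
    return pd.DataFrame(
        {"nearest_distance": dist, "overlapping": dist <= params.threshold},
        index=query.cell_ids,
    )


def overlap_summary(
    flags: pd.Series | pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Fraction of overlapping cells per group (e.g. per timepoint)."""
    if isinstance(flags, pd.DataFrame):
        flags = flags["overlapping"]
    aligned = groups.reindex(flags.index)
    out = (
        pd.DataFrame({"overlapping": flags.astype(bool), "group": aligned})
        .groupby("group", observed=True)["overlapping"]
        .agg(n_cells="size", n_overlapping="sum", fraction="mean")
    )
    out["fraction"] = out["fraction"].astype(float)
    return out
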