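"""Clonal frequency binning, occupied repertoire and clone trajectories.

Clone-frequency bins follow the conventional five-range scheme
(Rare -> Hyperexpanded) on half-open (lo, hi] intervals covering (0, 1].
Trajectories track each sufficiently expanded clone through the clusters it
occupies, ordered from its least to most abundant state, with per-cluster
embedding centroids and displacement vectors between successive centroids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from tcellfate.dataio import CellTable, ClonotypeTable, ModuleSignature, ValidationError

logger = logging.getLogger("tcellfate")

DEFAULT_BIN_LABELS = ("Rare", "Small", "Medium", "Large", "Hyperexpanded")
DEFAULT_BIN_EDGES = (0.0, 1e-4, 1e-3, 0.01, 0.1, 1.0)


@dataclass
class ClonalBinning:
    """Half-open (lo, hi] clone-frequency bins covering (0, 1]."""

    labels: tuple = DEFAULT_BIN_LABELS
    edges: tuple = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) != len(self.labels) + 1:
            raise ValidationError("need len(edges) == len(labels) + 1")
        if not np.all(np.diff(e) > 0):
            raise ValidationError("bin edges must be strictly increasing")
        if e[0] != 0.0 or e[-1] != 1.0:
            raise ValidationError("bins must cover (0, 1]")


@dataclass
class TrajectoryVector:
    """One clone's inferred movement between cluster centroids."""

    clonotype_key: str
    clusters: list[str]  # least -> most expanded
    counts: list[int]
    centroids: np.ndarray  # (len(clusters), 2)
    displacements: np.ndarray  # (len(clusters) - 1, 2)

    @property
    def net_vector(self) -> np.ndarray:
        return self.centroids[-1] - self.centroids[0]


def bin_clones(clones: ClonotypeTable, binning: ClonalBinning | None = None) -> pd.Series:
    """Label every clonotype-bearing cell by its clone-frequency bin."""
    binning = binning or ClonalBinning()
    freq = clones.df["clone_frequency"].to_numpy(float)
    if ((freq <= 0) | (freq > 1)).any():
        raise ValidationError("clone frequencies must lie in (0, 1]")
    cats = pd.cut(
        freq,
        bins=list(binning.edges),
        labels=list(binning.labels),
        right=True,
        include_lowest=False,
    )
    return pd.Series(cats, index=clones.df["cell_id"].to_numpy(), name="clone_bin")


def occupied_repertoire(
    cells: CellTable,
    clones: ClonotypeTable,
    binning: ClonalBinning | None = None,
    group_by: str = "cluster",
) -> pd.DataFrame:
    """Cell counts per (group, clone-frequency bin).

    ``group_by`` is a CellTable obs column, typically ``cluster`` or
    ``timepoint_days``.  Cells without a clonotype are excluded; totals per
    group therefore equal the clonotype-bearing group sizes.
    """
    binning = binning or ClonalBinning()
    bins = bin_clones(clones, binning)
    groups = cells.obs[group_by].reindex(bins.index)
    table = (
        pd.crosstab(groups, bins)
        .reindex(columns=list(binning.labels), fill_value=0)
    )
    table.index.name = group_by
    return table


def infer_trajectories(
    cells: CellTable,
    clones: ClonotypeTable,
    restrict_to: tuple = ("Large", "Hyperexpanded"),
    binning: ClonalBinning | None = None,
) -> list[TrajectoryVector]:
    """Clonotype-anchored differentiation trajectories in embedding space.

    For each clone in the retained frequency bins that occupies >= 2
    clusters: clusters are ordered by within-clone cell count ascending
    (ties broken by cluster label), the centroid of each cluster's member
    cells is the arithmetic mean of their embedding coordinates, and
    displacement vectors connect successive centroids.
    """
    if cells.embedding is None:
        raise ValidationError("cells lack embeddings")
    binning = binning or ClonalBinning()
    bins = bin_clones(clones, binning)
    df = clones.df.copy()
    df["clone_bin"] = bins.to_numpy()
    retained_keys = df.loc[df["clone_bin"].isin(restrict_to), "clonotype_key"].unique()

    obs = cells.obs
    emb = pd.DataFrame(cells.embedding, index=cells.cell_ids, columns=["x", "y"])
    out: list[TrajectoryVector] = []
    for key in sorted(retained_keys):
        members = df.loc[df["clonotype_key"] == key, "cell_id"]
        known = members[members.isin(obs.index)]
        if known.empty:
            continue
        if emb.loc[known].isna().any().any():
            warnings.warn(f"clone {key}: cells lack embeddings; skipped", stacklevel=2)
            continue
        clusters = obs.loc[known, "cluster"]
        if clusters.isna().any():
            warnings.warn(f"clone {key}: cells lack cluster labels; skipped", stacklevel=2)
            continue
        counts = clusters.value_counts()
        if len(counts) < 2:
            continue
        ordering = sorted(counts.index, key=lambda c: (counts[c], str(c)))
        centroids = np.array(
            [emb.loc[known[clusters.to_numpy() == c]].mean(axis=0) for c in ordering]
        )
        out.append(
            TrajectoryVector(
                clonotype_key=key,
                clusters=[str(c) for c in ordering],
                counts=[int(counts[c]) for c in ordering],
                centroids=centroids,
                displacements=np.diff(centroids, axis=0),
            )
        )
    return out


def expansion_contrast(
    cells: CellTable,
    clones: ClonotypeTable,
    signature: ModuleSignature,
    expanded_bins: tuple = ("Hyperexpanded", "Large"),
    reference_bins: tuple = ("Medium", "Small"),
    binning: ClonalBinning | None = None,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Per-gene contrast of expanded vs less-expanded cells.

    Returns a dot-plot-style table per signature gene: fraction of cells
    expressing (> 0) and mean log-normalized expression in each group, the
    mean difference, a two-sided rank-sum p-value and its BH adjustment
    across the signature genes.
    """
    bins = bin_clones(clones, binning or ClonalBinning())
    cell_bin = bins.reindex(cells.cell_ids)
    grp_a = cell_bin.isin(expanded_bins).to_numpy()
    grp_b = cell_bin.isin(reference_bins).to_numpy()
    if grp_a.sum() == 0 or grp_b.sum() == 0:
        raise ValidationError("both expansion groups must be non-empty")

    X = cells.expression(
        [g for g in signature.genes if g in cells.var_names], layer=layer
    )
    genes = [g for g in signature.genes if g in cells.var_names]
    rows = []
    for j, gene in enumerate(genes):
        a, b = X[grp_a, j], X[grp_b, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "gene": gene,
                "frac_expr_expanded": float((a > 0).mean()),
                "frac_expr_reference": float((b > 0).mean()),
                "mean_expanded": float(a.mean()),
                "mean_reference": float(b.mean()),
                "mean_diff": float(a.mean() - b.mean()),
                "pvalue": p,
            }
        )
    table = pd.DataFrame(rows)
    table["padj"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    return table
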