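"""Reading, writing and quality control for paired scRNA/scTCR cohorts.

The central in-memory container is :class:`CellTable`, a thin wrapper around
:class:`anndata.AnnData` that enforces the conventions every downstream stage
relies on: a raw ``counts`` layer, a ``lognorm`` layer (counts scaled to
10,000 per cell, then log1p), per-cell metadata in ``obs`` and an optional 2D
embedding in ``obsm["X_embed"]``.  Clonotype assignments live in a separate
:class:`ClonotypeTable` keyed by ``cell_id``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("tcellfate")

#: normal-consistency constant for the median absolute deviation
MAD_SCALE = 1.4826

TISSUES = ("PB", "BM")
AML_STATUSES = ("AML_pos", "AML_neg", "unknown")

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "timepoint_days",
    "tissue",
    "aml_status",
    "cluster",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass
class CellTable:
    """Per-cell expression plus metadata.

    Parameters
    ----------
    adata
        AnnData with cells in rows.  ``layers["counts"]`` holds raw counts;
        ``layers["lognorm"]`` the log-normalized values used for scoring.
        ``obs`` carries sample/subject/timepoint/tissue/aml_status/cluster;
        ``obsm["X_embed"]`` the 2D embedding when available.
    """

    adata: ad.AnnData

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def obs(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def cell_ids(self) -> pd.Index:
        return self.adata.obs_names

    @property
    def var_names(self) -> pd.Index:
        return self.adata.var_names

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_features(self) -> int:
        return self.adata.n_vars

    def layer(self, name: str = "lognorm") -> np.ndarray:
        """Return a dense (cells x features) matrix for ``name``."""
        mat = self.adata.layers[name]
        return np.asarray(mat.todense()) if sp.issparse(mat) else np.asarray(mat)

    def expression(self, genes, layer: str = "lognorm") -> np.ndarray:
        """Dense expression for a list of genes (cells x len(genes))."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.adata.var_names]
        if missing:
            raise KeyError(f"features absent from panel: {missing}")
        idx = [self.adata.var_names.get_loc(g) for g in genes]
        mat = self.adata.layers[layer][:, idx]
        return np.asarray(mat.todense()) if sp.issparse(mat) else np.asarray(mat)

    @property
    def embedding(self) -> np.ndarray | None:
        return self.adata.obsm.get("X_embed")

    def subset(self, mask) -> "CellTable":
        """Row-subset by boolean mask or cell-id list, keeping all layers."""
        return CellTable(self.adata[mask].copy())

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.adata.obs_names.has_duplicates:
            raise ValidationError("duplicate cell_id values")
        if "counts" in self.adata.layers:
            counts = self.adata.layers["counts"]
            mn = counts.min() if not sp.issparse(counts) else counts.data.min(initial=0)
            if mn < 0:
                raise ValidationError("negative values in counts layer")
        for sample, grp in self.adata.obs.groupby("sample_id", observed=True):
            if "X_embed" in self.adata.obsm:
                emb = self.adata.obsm["X_embed"][
                    self.adata.obs_names.get_indexer(grp.index)
                ]
                n_nan = int(np.isnan(emb).any(axis=1).sum())
                if 0 < n_nan < len(grp):
                    raise ValidationError(
                        f"sample {sample}: embedding present for some cells only"
                    )


@dataclass
class ClonotypeTable:
    """Per-cell clonotype key plus per-sample clone frequency.

    ``df`` columns: cell_id, sample_id, clonotype_key, clone_frequency,
    chain_info (";"-joined ``locus:CDR3aa:productive`` records).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.df["cell_id"].duplicated().any():
            raise ValidationError("cell_id appears more than once")
        if (self.df["clonotype_key"].str.len() == 0).any():
            raise ValidationError("empty clonotype_key")
        freq = self.df["clone_frequency"]
        if ((freq <= 0) | (freq > 1)).any():
            raise ValidationError("clone_frequency outside (0, 1]")
        per_sample = (
            self.df.drop_duplicates(["sample_id", "clonotype_key"])
            .groupby("sample_id")["clone_frequency"]
            .sum()
        )
        if (per_sample > 1 + 1e-9).any():
            raise ValidationError("clone frequencies sum to > 1 within a sample")

    def cells_of_clone(self, key: str) -> pd.DataFrame:
        return self.df[self.df["clonotype_key"] == key]


@dataclass
class ModuleSignature:
    """A named, positively-directed gene set (e.g. self-renew, NK-like)."""

    name: str
    genes: list[str]
    direction: str = "up"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name}: empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name}: duplicate genes")


@dataclass
class PatientCourse:
    """One patient's clinical flags and longitudinal engineered-cell series.

    ``series`` holds (day, percent-of-CD8) points; ``long_term_persist`` may
    carry a transcribed persistence call for cohorts whose raw series are not
    available (the packaged trial fixture).
    """

    patient_id: str
    virus_specificity: str  # "EBV" | "CMV"
    n_infusions: int
    detectable_disease_preinfusion: bool
    early_relapse_postHCT: bool
    wt1_data_available: bool
    series: list[tuple[float, float]] = field(default_factory=list)
    interval_days: tuple[float, float] | None = None
    long_term_persist: bool | None = None

    def __post_init__(self) -> None:
        days = [d for d, _ in self.series]
        if any(d < 0 for d in days):
            raise ValidationError("series days must be non-negative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("series days must be strictly increasing")
        if any(not (0 <= p <= 100) for _, p in self.series):
            raise ValidationError("series percentages must lie in [0, 100]")
        if self.n_infusions < 1:
            raise ValidationError("n_infusions must be >= 1")


@dataclass
class QcParams:
    """MAD-based cell filter plus minimum-cell feature filter settings.

    ``k`` per metric defaults to ``mad_upper`` (the study tuned per-sample
    values between ``mad_lower`` and ``mad_upper``; only the bounds are
    reported, so the permissive end is the default).
    """

    mad_lower: float = 1.0
    mad_upper: float = 3.5
    metrics: tuple[str, ...] = (
        "total_counts",
        "n_genes_by_counts",
        "pct_counts_mito",
        "pct_counts_ribo",
    )
    min_cells_per_feature: int = 3
    min_count: int = 1
    per_metric_k: dict | None = None

    def __post_init__(self) -> None:
        if not (0 < self.mad_lower <= self.mad_upper):
            raise ValidationError("require 0 < mad_lower <= mad_upper")
        if self.min_cells_per_feature < 1:
            raise ValidationError("min_cells_per_feature must be >= 1")
        if self.per_metric_k:
            for m, k in self.per_metric_k.items():
                if not (self.mad_lower <= k <= self.mad_upper):
                    raise ValidationError(
                        f"k for metric {m} outside [mad_lower, mad_upper]"
                    )

    def k_for(self, metric: str) -> float:
        if self.per_metric_k and metric in self.per_metric_k:
            return self.per_metric_k[metric]
        return self.mad_upper


# ---------------------------------------------------------------------------
# normalization helpers
# ---------------------------------------------------------------------------


def attach_lognorm(adata: ad.AnnData, target_sum: float = 1e4) -> None:
    """Compute the ``lognorm`` layer from ``counts`` in place."""
    tmp = ad.AnnData(
        X=adata.layers["counts"].copy(),
        obs=pd.DataFrame(index=adata.obs_names),
        var=pd.DataFrame(index=adata.var_names),
    )
    sc.pp.normalize_total(tmp, target_sum=target_sum)
    sc.pp.log1p(tmp)
    adata.layers["lognorm"] = tmp.X


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression(
    matrix_path,
    barcodes_path,
    features_path,
    metadata_path=None,
) -> CellTable:
    """Load a CellRanger-style MTX triplet plus optional per-cell metadata.

    The matrix is features x barcodes on disk (CellRanger convention) and is
    transposed to cells x features in memory.  Metadata is joined on barcode;
    cells missing from the metadata keep null cluster/embedding.
    """
    mat = scipy.io.mmread(str(matrix_path)).tocsr()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix {mat.shape} does not match {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    if barcodes.duplicated().any():
        raise ValidationError("duplicate barcodes")
    if features.duplicated().any():
        raise ValidationError("duplicate feature names")

    counts = mat.T.tocsr()
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    for col in METADATA_COLUMNS:
        obs[col] = pd.NA
    embed = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype={"cell_id": str})
        if "cell_id" not in meta.columns:
            raise FormatError("metadata must carry a cell_id column")
        meta = meta.set_index("cell_id")
        extra = meta.index.difference(obs.index)
        if len(extra):
            logger.warning("metadata rows for %d unknown barcodes ignored", len(extra))
        for col in meta.columns:
            if col in ("embed_x", "embed_y"):
                continue
            obs[col] = meta[col].reindex(obs.index)
        if {"embed_x", "embed_y"} <= set(meta.columns):
            embed = meta[["embed_x", "embed_y"]].reindex(obs.index).to_numpy(float)

    obs["sample_id"] = obs["sample_id"].fillna("unknown")
    adata = ad.AnnData(X=counts, obs=obs, var=pd.DataFrame(index=features))
    adata.layers["counts"] = counts.copy()
    attach_lognorm(adata)
    if embed is not None:
        adata.obsm["X_embed"] = embed
    return CellTable(adata)


def write_expression(cells: CellTable, out_dir) -> dict[str, Path]:
    """Write the counts layer back out as an MTX triplet + metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = np.argsort(cells.cell_ids.to_numpy())
    adata = cells.adata[order]
    counts = adata.layers["counts"]
    counts = counts if sp.issparse(counts) else sp.csr_matrix(counts)
    paths = {
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "metadata": out / "metadata.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), counts.T.tocoo())
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    pd.Series(adata.var_names).to_csv(paths["features"], sep="\t", index=False, header=False)
    meta = adata.obs.copy()
    if "X_embed" in adata.obsm:
        meta["embed_x"] = adata.obsm["X_embed"][:, 0]
        meta["embed_y"] = adata.obsm["X_embed"][:, 1]
    meta.index.name = "cell_id"
    meta.to_csv(paths["metadata"], sep="\t")
    return paths


# -- clonotypes -------------------------------------------------------------

_TENX_COLUMNS = {"barcode", "chain", "cdr3", "productive"}
_AIRR_COLUMNS = {"cell_id", "locus", "junction_aa", "productive"}
_KNOWN_LOCI = {"TRA", "TRB", "TRG", "TRD"}


def _truthy(v) -> bool:
    return str(v).strip().lower() in {"true", "t", "yes", "1"}


def _build_keys(chains: pd.DataFrame) -> pd.DataFrame:
    """Resolve productive chains into one clonotype key per cell.

    One chain per locus is kept (highest read support); the key is the
    sorted, "+"-joined list of ``locus:CDR3aa`` over the kept chains, so
    paired TRA+TRB cells and TRB-only cells both receive stable keys.
    """
    unknown = ~chains["locus"].isin(_KNOWN_LOCI)
    if unknown.any():
        warnings.warn(
            f"dropping {int(unknown.sum())} contigs with unknown locus codes",
            stacklevel=2,
        )
        chains = chains[~unknown]
    chains = chains[chains["productive"]]
    if chains.empty:
        return pd.DataFrame(columns=["cell_id", "clonotype_key", "chain_info"])
    chains = chains.sort_values(
        ["cell_id", "locus", "reads", "cdr3"], ascending=[True, True, False, True]
    ).drop_duplicates(["cell_id", "locus"], keep="first")

    def per_cell(grp: pd.DataFrame) -> pd.Series:
        parts = sorted(f"{l}:{c}" for l, c in zip(grp["locus"], grp["cdr3"]))
        info = ";".join(f"{l}:{c}:True" for l, c in zip(grp["locus"], grp["cdr3"]))
        return pd.Series({"clonotype_key": "+".join(parts), "chain_info": info})

    out = chains.groupby("cell_id", sort=True).apply(per_cell, include_groups=False)
    return out.reset_index()


def read_clonotypes(
    path,
    dialect: str,
    sample_id: str | None = None,
    total_cells: int | None = None,
) -> ClonotypeTable:
    """Parse clonotype assignments from a 10x contig CSV or AIRR TSV.

    Parameters
    ----------
    dialect
        ``"tenx_contigs"`` (filtered_contig_annotations.csv) or ``"airr"``
        (rearrangement TSV with cell_id/locus/junction_aa/productive).
    sample_id
        Sample the file belongs to; taken from a ``sample_id`` column when
        present, else ``"sample_1"``.
    total_cells
        Denominator for clone frequencies.  Defaults to the number of
        distinct cells in the file (including cells that end up dropped for
        lacking productive chains).
    """
    if dialect == "tenx_contigs":
        raw = pd.read_csv(path)
        if not _TENX_COLUMNS <= set(raw.columns):
            raise FormatError(f"10x contig file must carry {sorted(_TENX_COLUMNS)}")
        chains = pd.DataFrame(
            {
                "cell_id": raw["barcode"].astype(str),
                "locus": raw["chain"].astype(str),
                "cdr3": raw["cdr3"].astype(str),
                "productive": raw["productive"].map(_truthy),
                "reads": raw.get("reads", pd.Series(0, index=raw.index)),
            }
        )
    elif dialect == "airr":
        raw = pd.read_csv(path, sep="\t")
        if not _AIRR_COLUMNS <= set(raw.columns):
            raise FormatError(f"AIRR file must carry {sorted(_AIRR_COLUMNS)}")
        chains = pd.DataFrame(
            {
                "cell_id": raw["cell_id"].astype(str),
                "locus": raw["locus"].astype(str),
                "cdr3": raw["junction_aa"].astype(str),
                "productive": raw["productive"].map(_truthy),
                "reads": raw.get("consensus_count", pd.Series(0, index=raw.index)),
            }
        )
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if sample_id is None:
        sample_id = (
            str(raw["sample_id"].iloc[0]) if "sample_id" in raw.columns else "sample_1"
        )
    n_total = total_cells if total_cells is not None else chains["cell_id"].nunique()
    cells = _build_keys(chains)
    if cells.empty:
        raise ValidationError("no cells with productive chains")
    cells["sample_id"] = sample_id
    sizes = cells.groupby("clonotype_key")["cell_id"].transform("size")
    cells["clone_frequency"] = sizes / max(n_total, 1)
    cells = cells.sort_values("cell_id").reset_index(drop=True)
    return ClonotypeTable(
        cells[["cell_id", "sample_id", "clonotype_key", "clone_frequency", "chain_info"]]
    )


def compute_clone_frequencies(clones: ClonotypeTable, totals: dict[str, int]) -> ClonotypeTable:
    """Recompute clone_frequency against per-sample total cell counts."""
    df = clones.df.copy()
    sizes = df.groupby(["sample_id", "clonotype_key"])["cell_id"].transform("size")
    denom = df["sample_id"].map(totals)
    df["clone_frequency"] = sizes / denom
    return ClonotypeTable(df)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def _qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    tmp = ad.AnnData(
        X=adata.layers["counts"].copy(),
        obs=pd.DataFrame(index=adata.obs_names),
        var=pd.DataFrame(index=adata.var_names),
    )
    tmp.var["mito"] = tmp.var_names.str.startswith("MT-")
    tmp.var["ribo"] = tmp.var_names.str.startswith(("RPS", "RPL"))
    sc.pp.calculate_qc_metrics(
        tmp, qc_vars=["mito", "ribo"], percent_top=None, log1p=False, inplace=True
    )
    return tmp.obs


def _mad_keep_mask(values: np.ndarray, k: float) -> np.ndarray:
    """Keep values within median +/- k * scaled MAD; MAD = 0 keeps all."""
    med = np.median(values)
    mad = MAD_SCALE * np.median(np.abs(values - med))
    if mad == 0:
        return np.ones(len(values), dtype=bool)
    return np.abs(values - med) <= k * mad


def qc_filter(cells: CellTable, params: QcParams | None = None) -> CellTable:
    """Remove metric-outlier cells and rarely-detected features.

    Cells whose any QC metric lies beyond ``median +/- k*MAD`` are removed;
    features with count > ``min_count`` in fewer than
    ``min_cells_per_feature`` cells are removed.  The two filters are
    iterated to a fixed point so the operation is idempotent.
    """
    params = params or QcParams()
    adata = cells.adata.copy()
    n_cells0, n_feat0 = adata.shape
    for _ in range(100):
        metrics = _qc_metrics(adata)
        keep_cells = np.ones(adata.n_obs, dtype=bool)
        for metric in params.metrics:
            if metric not in metrics.columns:
                raise KeyError(f"unknown QC metric: {metric}")
            keep_cells &= _mad_keep_mask(
                metrics[metric].to_numpy(float), params.k_for(metric)
            )
        counts = adata.layers["counts"]
        counts = counts if sp.issparse(counts) else sp.csr_matrix(counts)
        detected = np.asarray((counts[keep_cells] > params.min_count).sum(axis=0)).ravel()
        keep_feats = detected >= params.min_cells_per_feature
        if keep_cells.all() and keep_feats.all():
            break
        adata = adata[keep_cells, keep_feats].copy()
        if adata.n_obs == 0 or adata.n_vars == 0:
            raise ValidationError("empty after QC: everything removed")
    logger.info(
        "qc_filter: %d -> %d cells, %d -> %d features",
        n_cells0, adata.n_obs, n_feat0, adata.n_vars,
    )
    attach_lognorm(adata)
    return CellTable(adata)


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir,
    seed: int | None = None,
    params: dict | None = None,
    inputs: list | None = None,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write one TSV per table plus a JSON run manifest.

    Rows are sorted by their first column (cell_id for per-cell tables) so
    repeated runs produce identical bytes.
    """
    from tcellfate import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        if len(df):
            df = df.sort_values(list(df.columns[:1]), kind="mergesort")
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    manifest = {
        "version": __version__,
        "seed": seed,
        "params": params or {},
        "input_checksums": {str(p): _checksum(Path(p)) for p in (inputs or [])},
        "tables": sorted(tables),
    }
    mpath = out / "manifest.json"
    if mpath.exists() and not overwrite:
        raise FileExistsError(f"{mpath} exists; pass overwrite=True")
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths
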