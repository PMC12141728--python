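"""Synthetic paired scRNA/scTCR cohorts with planted ground truth.

The generator emulates the statistical structure of a post-transplant
engineered T-cell trial: multi-timepoint CD8+ cells arranged along a
naive -> Tem -> NKL/Temra differentiation axis, clone sizes coupled to
position on that axis, a transgene-positive subpopulation concentrated in
the engineered-cell clusters, and XIST+CD34+WT1+ recipient-origin blasts
present only in AML-positive samples of sex-mismatched (female) patients.

Counts are negative-binomial with cluster-by-gene means; the 2D embedding
is generated (axis mapped to an arc plus Gaussian jitter), mirroring
pipelines where the UMAP is a precomputed input rather than a product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from tcellfate.dataio import (
    CellTable,
    ClonotypeTable,
    PatientCourse,
    ValidationError,
    attach_lognorm,
)
from tcellfate.signatures import (
    BLAST_GENES,
    NK_LIKE_GENES,
    SELF_RENEW_GENES,
    TRANSGENE,
)

DEFAULT_AXIS = ("naive_cm", "Tem", "TTCR_Tem", "TTCR_Temra", "NKL_Temra")

DEFAULT_SAMPLES = (
    (49, "PB", "AML_pos"),
    (256, "PB", "AML_pos"),
    (405, "PB", "AML_neg"),
    (1322, "PB", "AML_neg"),
)

#: embedding jitter (Gaussian sigma, in embedding units)
EMBED_SIGMA = 0.05
#: center of the off-arc blast island
BLAST_CENTER = (0.5, -0.6)


@dataclass
class CohortSpec:
    """Study conditions for one generated cohort."""

    n_patients: int = 2
    samples_per_patient: tuple = DEFAULT_SAMPLES
    cells_per_sample: int = 500
    n_genes: int = 800
    cluster_axis: tuple = DEFAULT_AXIS
    signature_effect: float = 1.5
    expansion_coupling: float = 0.9
    transgene_fraction: float = 0.2
    blast_fraction: float = 0.05
    noise_model: float = 2.0  # negative-binomial dispersion theta
    state_drift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("transgene_fraction", "blast_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.cells_per_sample < 1:
            raise ValidationError("cells_per_sample must be >= 1")
        if len(self.cluster_axis) < 2:
            raise ValidationError("cluster_axis needs at least 2 states")
        has_aml = any(s[2] == "AML_pos" for s in self.samples_per_patient)
        if self.blast_fraction > 0 and not has_aml:
            raise ValidationError("blast_fraction > 0 requires an AML_pos sample")


@dataclass
class GroundTruth:
    """Planted per-cell and per-clone truth used by recovery tests.

    ``cells`` columns: cell_id, true_cluster, axis_pos, transgene, blast.
    ``clones`` columns: clonotype_key, home_cluster, dir_x, dir_y (unit
    vector of the planted differentiation direction in embedding space).
    """

    cells: pd.DataFrame
    clones: pd.DataFrame


def _arc(axis_pos: np.ndarray) -> np.ndarray:
    """Noiseless embedding of an axis position in [0, 1] onto a 2D arc."""
    axis_pos = np.asarray(axis_pos, dtype=float)
    return np.column_stack([axis_pos, 0.4 * np.sin(np.pi * axis_pos)])


def _gene_panel(n_genes: int) -> list[str]:
    special = (
        SELF_RENEW_GENES
        + NK_LIKE_GENES
        + BLAST_GENES
        + [TRANSGENE, "MKI67", "CD3D", "CD3E", "CD3G", "CD8A", "NCAM1", "RPS4Y1"]
        + ["MT-CO1", "MT-ND1", "MT-ATP6", "RPS18", "RPL13", "RPL10"]
    )
    if n_genes < len(special):
        raise ValidationError(f"n_genes must be >= {len(special)}")
    fillers = [f"GENE{i:04d}" for i in range(n_genes - len(special))]
    return special + fillers


def _clone_layout(
    rng: np.random.Generator,
    n_cells: int,
    n_clusters: int,
    coupling: float,
    drift_shift: float,
):
    """Assign clones, clone sizes and per-cell clusters for one sample.

    Clone sizes follow a zipf-like law; larger clones are homed further
    along the axis with strength ``coupling``.  Within a clone, cells are
    spread over clusters up to the home cluster with geometrically
    increasing weights, so cell counts grow toward the home state.
    """
    n_clones = max(3, n_cells // 8)
    weights = np.arange(1, n_clones + 1, dtype=float) ** -1.2
    sizes = rng.multinomial(n_cells, weights / weights.sum())
    keep = sizes > 0
    sizes = sizes[keep]
    order = np.argsort(np.argsort(sizes, kind="stable"), kind="stable")
    size_quantile = (order + 0.5) / len(sizes)  # largest clone -> ~1
    home_pos = np.clip(
        coupling * size_quantile
        + (1 - coupling) * rng.uniform(size=len(sizes))
        + drift_shift,
        0.0,
        1.0,
    )
    home_cluster = np.minimum((home_pos * n_clusters).astype(int), n_clusters - 1)

    decay = 1.0 - 0.7 * coupling  # flat spread when uncoupled
    cell_cluster = np.empty(n_cells, dtype=int)
    cell_clone = np.empty(n_cells, dtype=int)
    pos = 0
    for c, (sz, kh) in enumerate(zip(sizes, home_cluster)):
        w = decay ** (kh - np.arange(kh + 1))
        counts = rng.multinomial(sz, w / w.sum())
        members = np.repeat(np.arange(kh + 1), counts)
        cell_cluster[pos : pos + sz] = members
        cell_clone[pos : pos + sz] = c
        pos += sz
    return cell_clone, cell_cluster, sizes, home_cluster


def _mean_matrix(
    spec: CohortSpec,
    genes: list[str],
    base: np.ndarray,
    cluster_idx: np.ndarray,
    transgene: np.ndarray,
    blast: np.ndarray,
    female: bool,
) -> np.ndarray:
    """Expected expression per cell per gene before NB noise."""
    n_cells = len(cluster_idx)
    n_clusters = len(spec.cluster_axis)
    axis_center = (cluster_idx + 0.5) / n_clusters
    mu = np.tile(base, (n_cells, 1))
    gidx = {g: i for i, g in enumerate(genes)}
    eff = np.exp(spec.signature_effect)

    def boost(gene, weight):
        mu[:, gidx[gene]] = base[gidx[gene]] * np.exp(spec.signature_effect * weight)

    tcell = ~blast
    for g in SELF_RENEW_GENES:
        boost(g, np.where(tcell, 1.0 - axis_center, 0.0))
    for g in NK_LIKE_GENES:
        boost(g, np.where(tcell, axis_center, 0.0))
    boost("MKI67", np.where(tcell, np.clip(1 - 2 * np.abs(axis_center - 0.45), 0, 1), 0))
    boost("NCAM1", np.where(tcell, axis_center**2, 0.0))
    for g in ("CD3D", "CD3E", "CD3G", "CD8A"):
        mu[:, gidx[g]] = np.where(tcell, base[gidx[g]] * eff, 0.01)
    # the transgene is driven by a strong viral promoter: high expression in
    # transduced cells, near-zero ambient background elsewhere
    mu[:, gidx[TRANSGENE]] = np.where(transgene, base[gidx[TRANSGENE]] * eff, 0.005)
    for g in ("CD34", "WT1"):
        mu[:, gidx[g]] = np.where(blast, base[gidx[g]] * eff, 0.02)
    # XIST marks recipient (female) origin: only blasts of a sex-mismatched
    # (female) patient express it; donor-derived T cells are male.
    mu[:, gidx["XIST"]] = np.where(blast & female, base[gidx["XIST"]] * eff, 0.0)
    mu[:, gidx["RPS4Y1"]] = np.where(blast & female, 0.0, base[gidx["RPS4Y1"]])
    return mu


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and dispersion theta."""
    mu = np.maximum(mu, 1e-12)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(np.int32)


def generate_cohort(spec: CohortSpec) -> tuple[CellTable, ClonotypeTable, GroundTruth]:
    """Generate a paired expression + clonotype cohort with planted truth."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_panel(spec.n_genes)
    n_clusters = len(spec.cluster_axis)
    n_special = len(genes) - sum(g.startswith("GENE") for g in genes)

    base = np.exp(rng.normal(-1.5, 0.8, size=len(genes)))
    gidx = {g: i for i, g in enumerate(genes)}
    # signature markers are reliably detectable genes; floor their baseline
    # so no draw leaves a marker below the detection filter
    for g in SELF_RENEW_GENES + NK_LIKE_GENES:
        base[gidx[g]] = max(base[gidx[g]], 0.5)
    for g in ("MT-CO1", "MT-ND1", "MT-ATP6"):
        base[gidx[g]] = 2.0
    for g in ("RPS18", "RPL13", "RPL10", "RPS4Y1"):
        base[gidx[g]] = 1.5
    for g in ("CD3D", "CD3E", "CD3G", "CD8A"):
        base[gidx[g]] = 1.0
    base[gidx[TRANSGENE]] = 2.5
    for g in BLAST_GENES:
        base[gidx[g]] = 0.8

    n_timepoints = len(spec.samples_per_patient)
    obs_rows, count_blocks, embed_blocks = [], [], []
    clone_rows, truth_cell_rows, truth_clone_rows = [], [], []
    clone_counter = 0

    for p in range(spec.n_patients):
        subject = f"P{p + 1:02d}"
        female = p % 2 == 0
        for i, (day, tissue, aml) in enumerate(spec.samples_per_patient):
            if tissue not in ("PB", "BM"):
                raise ValidationError(f"unknown tissue {tissue!r}")
            if aml not in ("AML_pos", "AML_neg", "unknown"):
                raise ValidationError(f"unknown aml_status {aml!r}")
            sample = f"{subject}_{tissue}_d{day}"
            n_cells = spec.cells_per_sample
            n_blast = (
                rng.binomial(n_cells, spec.blast_fraction) if aml == "AML_pos" else 0
            )
            n_t = n_cells - n_blast

            t_rank = i / max(n_timepoints - 1, 1)
            drift_shift = 0.35 * spec.state_drift * t_rank
            cell_clone, cell_cluster, sizes, home_cluster = _clone_layout(
                rng, n_t, n_clusters, spec.expansion_coupling, drift_shift
            )

            # per-cell axis position: uniform within the cluster band
            axis_pos = (cell_cluster + rng.uniform(size=n_t)) / n_clusters
            embed_t = _arc(axis_pos) + rng.normal(0, EMBED_SIGMA, size=(n_t, 2))

            # transgene cells concentrated in the engineered clusters
            n_pos = int(round(spec.transgene_fraction * n_t))
            cluster_w = np.array(
                [
                    4.0 if spec.cluster_axis[k].startswith("TTCR") else 1.0
                    for k in range(n_clusters)
                ]
            )
            w_cell = cluster_w[cell_cluster]
            transgene = np.zeros(n_t, dtype=bool)
            if n_pos > 0:
                chosen = rng.choice(n_t, size=n_pos, replace=False, p=w_cell / w_cell.sum())
                transgene[chosen] = True

            cell_ids = [f"{sample}_c{j:05d}" for j in range(n_cells)]
            blast_flag = np.zeros(n_cells, dtype=bool)
            blast_flag[n_t:] = True
            full_cluster = np.array(
                [spec.cluster_axis[k] for k in cell_cluster] + ["blast"] * n_blast
            )
            full_axis = np.concatenate([axis_pos, np.full(n_blast, np.nan)])
            full_transgene = np.concatenate([transgene, np.zeros(n_blast, dtype=bool)])
            embed_b = np.array(BLAST_CENTER) + rng.normal(0, EMBED_SIGMA, size=(n_blast, 2))
            embed = np.vstack([embed_t, embed_b]) if n_blast else embed_t

            mu = _mean_matrix(
                spec,
                genes,
                base,
                np.concatenate([cell_cluster, np.zeros(n_blast, dtype=int)]),
                full_transgene,
                blast_flag,
                female,
            )
            count_blocks.append(_nb_sample(rng, mu, spec.noise_model))
            embed_blocks.append(embed)

            for j, cid in enumerate(cell_ids):
                obs_rows.append(
                    {
                        "cell_id": cid,
                        "sample_id": sample,
                        "subject_id": subject,
                        "timepoint_days": day,
                        "tissue": tissue,
                        "aml_status": aml,
                        "cluster": full_cluster[j],
                        "sex": "F" if female else "M",
                    }
                )
                truth_cell_rows.append(
                    {
                        "cell_id": cid,
                        "true_cluster": full_cluster[j],
                        "axis_pos": full_axis[j],
                        "transgene": bool(full_transgene[j]),
                        "blast": bool(blast_flag[j]),
                    }
                )

            clone_keys = {
                c: f"TRB:CASS{clone_counter + c:06d}LF" for c in range(len(sizes))
            }
            clone_counter += len(sizes)
            for j in range(n_t):
                c = cell_clone[j]
                key = clone_keys[c]
                clone_rows.append(
                    {
                        "cell_id": cell_ids[j],
                        "sample_id": sample,
                        "clonotype_key": key,
                        "clone_frequency": sizes[c] / n_cells,
                        "chain_info": f"{key}:True",
                    }
                )
            for c, (sz, kh) in enumerate(zip(sizes, home_cluster)):
                occupied = np.unique(cell_cluster[cell_clone == c])
                lo = occupied.min()
                start = _arc([(lo + 0.5) / n_clusters])[0]
                end = _arc([(kh + 0.5) / n_clusters])[0]
                vec = end - start
                norm = np.linalg.norm(vec)
                direction = vec / norm if norm > 0 else np.array([np.nan, np.nan])
                truth_clone_rows.append(
                    {
                        "clonotype_key": clone_keys[c],
                        "sample_id": sample,
                        "size": int(sz),
                        "home_cluster": spec.cluster_axis[kh],
                        "dir_x": direction[0],
                        "dir_y": direction[1],
                    }
                )

    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    counts = sp.csr_matrix(np.vstack(count_blocks))
    adata = ad.AnnData(X=counts.copy(), obs=obs, var=pd.DataFrame(index=genes))
    adata.layers["counts"] = counts
    attach_lognorm(adata)
    adata.obsm["X_embed"] = np.vstack(embed_blocks)
    adata.uns["n_special_genes"] = n_special

    cells = CellTable(adata)
    clones = ClonotypeTable(pd.DataFrame(clone_rows))
    truth = GroundTruth(
        cells=pd.DataFrame(truth_cell_rows).set_index("cell_id"),
        clones=pd.DataFrame(truth_clone_rows),
    )
    return cells, clones, truth


# ---------------------------------------------------------------------------
# patient courses
# ---------------------------------------------------------------------------

_TABLE1_RESOURCE = "table1.tsv"


def load_table1() -> pd.DataFrame:
    """The packaged 15-patient trial summary table."""
    with resources.files("tcellfate.data").joinpath(_TABLE1_RESOURCE).open() as fh:
        return pd.read_csv(fh, sep="\t")


def generate_patient_courses(
    n: int = 15, seed: int = 0, fixture: str = "random"
) -> list[PatientCourse]:
    """Patient courses: the transcribed trial cohort or simulated series.

    ``paper_table1`` ignores ``n``/``seed`` and returns the 15 trial
    patients with clinical flags and transcribed persistence calls (their
    raw longitudinal series are not part of the public record, so
    ``series`` is left empty for that fixture).  ``random`` simulates
    courses that cross / do not cross the 3% persistence threshold, with
    the planted label stored in ``long_term_persist``.
    """
    if fixture == "paper_table1":
        df = load_table1()
        out = []
        for _, r in df.iterrows():
            interval = None
            if pd.notna(r["interval_start"]):
                interval = (float(r["interval_start"]), float(r["interval_end"]))
            out.append(
                PatientCourse(
                    patient_id=str(r["patient_id"]),
                    virus_specificity=r["virus_specificity"],
                    n_infusions=int(r["n_infusions"]),
                    detectable_disease_preinfusion=bool(r["detectable_disease_preinfusion"]),
                    early_relapse_postHCT=bool(r["early_relapse_postHCT"]),
                    wt1_data_available=bool(r["wt1_data_available"]),
                    interval_days=interval,
                    long_term_persist=bool(r["long_term_persist"]),
                )
            )
        return out
    if fixture != "random":
        raise ValueError(f"unknown fixture {fixture!r}")

    rng = np.random.default_rng(seed)
    days = [0, 7, 14, 28, 60, 110, 150]
    out = []
    for i in range(n):
        persist = i % 2 == 0
        if persist:
            peak = rng.uniform(5, 25)
            vals = [0.1, peak * 0.4, peak * 0.8, peak, peak * 0.9, peak * 0.7, peak * 0.6]
        else:
            ceiling = rng.uniform(0.3, 2.5)
            vals = list(np.minimum(rng.uniform(0.05, ceiling, size=len(days)), 2.9))
        out.append(
            PatientCourse(
                patient_id=f"S{i + 1:03d}",
                virus_specificity="EBV" if rng.uniform() < 0.7 else "CMV",
                n_infusions=int(rng.integers(1, 5)),
                detectable_disease_preinfusion=bool(rng.uniform() < 0.4),
                early_relapse_postHCT=bool(rng.uniform() < 0.2),
                wt1_data_available=True,
                series=list(zip(days, [float(min(v, 100.0)) for v in vals])),
                long_term_persist=persist,
            )
        )
    return out
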