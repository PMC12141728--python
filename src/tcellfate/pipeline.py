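"""End-to-end driver: synthetic cohort -> QC -> scoring -> gating ->
clonal dynamics -> embedding overlap, with deterministic TSV outputs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from tcellfate import clonal, dataio, gating, overlap, scoring, signatures, synthetic


def run_pipeline(
    spec: synthetic.CohortSpec,
    out_dir=None,
    qc_params: dataio.QcParams | None = None,
    overlap_params: overlap.OverlapParams | None = None,
    overwrite: bool = False,
):
    """Run every stage on a generated cohort; optionally write results.

    Returns (tables dict, cells, clones, truth).  With ``out_dir`` set, the
    tables are written as TSVs plus a JSON manifest in deterministic order.
    """
    cells, clones, truth = synthetic.generate_cohort(spec)
    cells = dataio.qc_filter(cells, qc_params or dataio.QcParams())
    keep = clones.df["cell_id"].isin(cells.cell_ids)
    clones = dataio.ClonotypeTable(clones.df[keep].reset_index(drop=True))

    # per-cell module scores and high-score masks
    score_tables = {}
    for name in ("self_renew", "nk_like"):
        # n_ctrl sized to the default panel's bin width (bins hold ~25 non-signature genes)
        res = scoring.module_score(
            cells, signatures.BUILTIN[name], n_ctrl=20, seed=spec.seed
        )
        score_tables[name] = res.scores
    blast = scoring.blast_score(cells)

    # transgene purification
    flags, purity_scores, cutoff = gating.purify(
        cells, gating.PurityModel(positive_markers=[signatures.TRANSGENE])
    )

    # clonal structure
    bins = clonal.bin_clones(clones)
    occupancy = clonal.occupied_repertoire(cells, clones, group_by="cluster")
    trajectories = clonal.infer_trajectories(cells, clones)

    # embedding overlap of engineered cells with the endogenous NKL state
    nkl_ref = cells.subset(
        ((cells.obs["cluster"] == "NKL_Temra") & ~flags.to_numpy()).to_numpy()
    )
    query = cells.subset(flags.to_numpy())
    ov = overlap.classify_overlap(query, nkl_ref, overlap_params)
    ov_by_time = overlap.overlap_summary(ov, cells.obs["timepoint_days"])

    cell_table = pd.DataFrame(
        {
            "cell_id": cells.cell_ids,
            "sample_id": cells.obs["sample_id"].to_numpy(),
            "timepoint_days": cells.obs["timepoint_days"].to_numpy(),
            "cluster": cells.obs["cluster"].to_numpy(),
            "self_renew_score": score_tables["self_renew"].to_numpy(),
            "nk_like_score": score_tables["nk_like"].to_numpy(),
            "blast_score": blast.scores.to_numpy(),
            "blast": blast.high_flag.to_numpy(),
            "transgene_pos": flags.to_numpy(),
            "purity_score": purity_scores.to_numpy(),
        }
    )
    traj_table = pd.DataFrame(
        [
            {
                "clonotype_key": t.clonotype_key,
                "clusters": "->".join(t.clusters),
                "counts": ",".join(map(str, t.counts)),
                "net_dx": t.net_vector[0],
                "net_dy": t.net_vector[1],
            }
            for t in trajectories
        ],
        columns=["clonotype_key", "clusters", "counts", "net_dx", "net_dy"],
    )
    clone_table = clones.df.assign(clone_bin=bins.to_numpy())
    tables = {
        "cells": cell_table.round(6),
        "clones": clone_table.round(6),
        "occupied_repertoire": occupancy.reset_index(),
        "trajectories": traj_table.round(6),
        "overlap_by_timepoint": ov_by_time.reset_index().round(6),
    }
    if out_dir is not None:
        dataio.write_results(
            tables,
            Path(out_dir),
            seed=spec.seed,
            params={"purify_cutoff": round(float(cutoff), 6)},
            overwrite=overwrite,
        )
    return tables, cells, clones, truth
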