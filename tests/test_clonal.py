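import numpy as np
import pandas as pd
import pytest

from tcellfate import (
    ClonalBinning,
    ClonotypeTable,
    ModuleSignature,
    bin_clones,
    expansion_contrast,
    infer_trajectories,
    occupied_repertoire,
)
from tcellfate.dataio import ValidationError
from tcellfate.signatures import NK_LIKE

from conftest import make_table


def _clones(records):
    """ClonotypeTable from (cell_id, clonotype_key, frequency) tuples."""
    df = pd.DataFrame(records, columns=["cell_id", "clonotype_key", "clone_frequency"])
    # scope each clone to its own sample so arbitrary fixture frequencies
    # respect the per-sample sum <= 1 invariant
    df["sample_id"] = df["clonotype_key"]
    df["chain_info"] = df["clonotype_key"] + ":True"
    return ClonotypeTable(df)


def _embedded_table(coords, clusters, cell_ids):
    cells = make_table(
        np.ones((len(coords), 1)), ["g0"], cell_ids=cell_ids, cluster=clusters
    )
    cells.adata.obsm["X_embed"] = np.asarray(coords, dtype=float)
    return cells


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def test_default_bin_assignments():
    clones = _clones(
        [
            ("c1", "K1", 0.00005),
            ("c2", "K2", 0.005),
            ("c3", "K3", 0.15),
            ("c4", "K4", 0.01),   # exactly at an internal edge -> (1e-3, 0.01]
            ("c5", "K5", 0.9),
        ]
    )
    bins = bin_clones(clones)
    assert bins.tolist() == ["Rare", "Medium", "Hyperexpanded", "Medium", "Hyperexpanded"]


def test_single_clone_sample_is_hyperexpanded():
    bins = bin_clones(_clones([("c1", "K1", 1.0)]))
    assert bins.iloc[0] == "Hyperexpanded"


def test_bins_partition_unit_interval():
    rng = np.random.default_rng(21)
    freqs = np.concatenate([rng.uniform(1e-6, 1, 200), [1e-4, 1e-3, 0.01, 0.1, 1.0]])
    clones = _clones([(f"c{i}", f"K{i}", f) for i, f in enumerate(freqs)])
    bins = bin_clones(clones)
    assert not bins.isna().any()  # every frequency lands in exactly one bin


def test_frequency_outside_unit_interval_rejected():
    df = pd.DataFrame(
        {
            "cell_id": ["c1"],
            "sample_id": ["s1"],
            "clonotype_key": ["K1"],
            "clone_frequency": [1.5],
            "chain_info": ["K1:True"],
        }
    )
    with pytest.raises(ValidationError):
        ClonotypeTable(df)


def test_invalid_binning_edges_rejected():
    with pytest.raises(ValidationError):
        ClonalBinning(labels=("a", "b"), edges=(0.0, 0.5, 0.9))


# ---------------------------------------------------------------------------
# occupied repertoire
# ---------------------------------------------------------------------------


def test_occupied_repertoire_hand_tabulated():
    cells = _embedded_table(
        np.zeros((6, 2)),
        ["A", "A", "B", "B", "C", "C"],
        [f"c{i}" for i in range(6)],
    )
    clones = _clones(
        [
            ("c0", "K1", 0.5),   # Hyperexpanded
            ("c1", "K1", 0.5),
            ("c2", "K1", 0.5),
            ("c3", "K2", 0.005),  # Medium
            ("c4", "K2", 0.005),
            ("c5", "K3", 0.05),   # Large
        ]
    )
    table = occupied_repertoire(cells, clones, group_by="cluster")
    assert table.loc["A", "Hyperexpanded"] == 2
    assert table.loc["B", "Hyperexpanded"] == 1
    assert table.loc["B", "Medium"] == 1
    assert table.loc["C", "Medium"] == 1
    assert table.loc["C", "Large"] == 1
    assert table.to_numpy().sum() == 6  # conservation over bins


def test_occupied_repertoire_single_clone_single_cluster():
    cells = _embedded_table(np.zeros((1, 2)), ["A"], ["c0"])
    table = occupied_repertoire(cells, _clones([("c0", "K1", 1.0)]))
    assert table.to_numpy().sum() == 1
    assert table.loc["A", "Hyperexpanded"] == 1


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def test_single_cluster_clone_yields_no_trajectory():
    cells = _embedded_table(np.zeros((3, 2)), ["A", "A", "A"], ["c0", "c1", "c2"])
    clones = _clones([(f"c{i}", "K1", 0.5) for i in range(3)])
    assert infer_trajectories(cells, clones) == []


def test_two_cluster_centroid_vector():
    coords = [(-1, 0), (1, 0), (1, 0), (1, 0), (1, 0), (1, 0), (-1, 0)]
    clusters = ["A", "B", "B", "B", "B", "B", "A"]
    ids = [f"c{i}" for i in range(7)]
    cells = _embedded_table(coords, clusters, ids)
    clones = _clones([(cid, "K1", 0.5) for cid in ids])
    (traj,) = infer_trajectories(cells, clones)
    assert traj.clusters == ["A", "B"]
    assert traj.counts == [2, 5]
    np.testing.assert_allclose(traj.centroids, [[-1, 0], [1, 0]])
    np.testing.assert_allclose(traj.displacements, [[2, 0]])


def test_trajectories_invariant_to_cell_order_and_sum_to_net():
    rng = np.random.default_rng(22)
    n = 18
    coords = rng.normal(size=(n, 2))
    clusters = rng.choice(["A", "B", "C"], size=n).tolist()
    ids = [f"c{i}" for i in range(n)]
    clones = _clones([(cid, "K1", 0.5) for cid in ids])

    base = infer_trajectories(_embedded_table(coords, clusters, ids), clones)
    perm = rng.permutation(n)
    shuffled = infer_trajectories(
        _embedded_table(coords[perm], [clusters[i] for i in perm], [ids[i] for i in perm]),
        clones,
    )
    assert len(base) == len(shuffled) == 1
    np.testing.assert_allclose(base[0].centroids, shuffled[0].centroids)
    np.testing.assert_allclose(
        base[0].displacements.sum(axis=0), base[0].net_vector, atol=1e-12
    )


def test_trajectories_match_naive_oracle_on_small_instances():
    rng = np.random.default_rng(23)
    for trial in range(5):
        n = int(rng.integers(6, 20))
        coords = rng.normal(size=(n, 2))
        clusters = [str(c) for c in rng.integers(0, 3, size=n)]
        keys = [f"K{k}" for k in rng.integers(0, 3, size=n)]
        ids = [f"c{i}" for i in range(n)]
        cells = _embedded_table(coords, clusters, ids)
        clones = _clones([(cid, key, 0.5) for cid, key in zip(ids, keys)])
        got = {t.clonotype_key: t for t in infer_trajectories(cells, clones)}

        # oracle: direct enumeration and coordinate averaging
        expected = {}
        for key in sorted(set(keys)):
            member = [i for i in range(n) if keys[i] == key]
            by_cluster = {}
            for i in member:
                by_cluster.setdefault(clusters[i], []).append(i)
            if len(by_cluster) < 2:
                continue
            order = sorted(by_cluster, key=lambda c: (len(by_cluster[c]), c))
            cents = np.array([coords[by_cluster[c]].mean(axis=0) for c in order])
            expected[key] = (order, cents)
        assert set(got) == set(expected)
        for key, (order, cents) in expected.items():
            assert got[key].clusters == order
            np.testing.assert_allclose(got[key].centroids, cents, atol=1e-12)


def test_trajectory_recovery_degrades_with_decoupling():
    from tcellfate import CohortSpec, generate_cohort

    def alignment(coupling, seed):
        spec = CohortSpec(
            n_patients=1, cells_per_sample=300, expansion_coupling=coupling,
            blast_fraction=0.0, seed=seed,
        )
        cells, clones, truth = generate_cohort(spec)
        trajs = infer_trajectories(cells, clones)
        tc = truth.clones.set_index("clonotype_key")
        hits = total = 0
        for t in trajs:
            d = tc.loc[t.clonotype_key, ["dir_x", "dir_y"]].to_numpy(float)
            if np.isnan(d).any():
                continue
            total += 1
            hits += float(t.net_vector @ d) > 0
        return hits / max(total, 1)

    strong = np.mean([alignment(0.9, s) for s in (1, 2, 3)])
    weak = np.mean([alignment(0.2, s) for s in (1, 2, 3)])
    assert strong > weak


# ---------------------------------------------------------------------------
# expansion contrast
# ---------------------------------------------------------------------------


def _contrast_fixture(elevated):
    ids = [f"c{i}" for i in range(12)]
    rng = np.random.default_rng(24)
    X = rng.gamma(2, 1, size=(12, 3))
    if elevated:
        X[:6] += 2.0  # expanded cells upregulated in every gene
    cells = make_table(X, ["GA", "GB", "GC"], cell_ids=ids)
    clones = _clones(
        [(ids[i], "BIG", 0.5) for i in range(6)]
        + [(ids[i], f"S{i}", 0.005) for i in range(6, 12)]
    )
    return cells, clones


def test_identical_groups_give_null_contrast():
    ids = [f"c{i}" for i in range(8)]
    X = np.tile([[1.0, 2.0]], (8, 1))
    cells = make_table(X, ["GA", "GB"], cell_ids=ids)
    clones = _clones(
        [(ids[i], "BIG", 0.5) for i in range(4)]
        + [(ids[i], f"S{i}", 0.005) for i in range(4, 8)]
    )
    out = expansion_contrast(cells, clones, ModuleSignature("s", ["GA", "GB"]))
    assert (out["mean_diff"] == 0).all()
    assert (out["padj"] == 1.0).all()


def test_planted_elevation_gives_positive_differences():
    cells, clones = _contrast_fixture(elevated=True)
    out = expansion_contrast(cells, clones, ModuleSignature("s", ["GA", "GB", "GC"]))
    assert (out["mean_diff"] > 0).all()
    assert out["frac_expr_expanded"].between(0, 1).all()
    assert out["frac_expr_reference"].between(0, 1).all()


def test_planted_nkl_elevation_in_expanded_cells(qc_cohort):
    _, cells, clones, _ = qc_cohort
    out = expansion_contrast(cells, clones, NK_LIKE)
    assert (out["mean_diff"] > 0).all()


def test_empty_group_errors():
    cells, clones = _contrast_fixture(elevated=False)
    with pytest.raises(ValidationError, match="non-empty"):
        expansion_contrast(
            cells, clones, ModuleSignature("s", ["GA"]), expanded_bins=("Rare",)
        )
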