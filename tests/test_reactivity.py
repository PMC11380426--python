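import numpy as np
import pandas as pd
import pytest

from ptrtkit.datatypes import GeneSetCollection
from ptrtkit.reactivity import (
    IRRELEVANT,
    PTRT,
    RELEVANT,
    PtrtThresholds,
    call_ptrt_clusters,
    compute_cluster_indices,
    label_reactivity,
    relevant_composition,
)
from ptrtkit.repertoire import call_clonotypes
from ptrtkit.scoring import normalize_log1p

from conftest import make_contigs, make_dataset


def pair(cell, nt_b="TGTTTTGCT"):
    return [
        (cell, "TRA", "TRAV1", "TRAJ1", "TGTGCTTTT", "CAF", True, 5),
        (cell, "TRB", "TRBV1", "TRBJ1", nt_b, "CFA", True, 5),
    ]


def toy_dataset():
    """Two clusters x two conditions; cluster A tumor-only, 50/50 margins.

    Cells: A-tumor c1..c5, B-control c6..c10 -> Ro/e of A in tumor = 2.0.
    All cells get singleton clonotypes except c1/c2 which share one.
    """
    n = 10
    counts = np.ones((n, 4), dtype=int)
    counts[:, 3] = 0
    counts[0, 3] = 1  # MKI67 detected in one cluster-A cell
    cells = [f"c{i+1}" for i in range(n)]
    meta = {
        "cluster": ["A"] * 5 + ["B"] * 5,
        "condition": ["tumor"] * 5 + ["control"] * 5,
        "donor": ["d1"] * n,
        "compartment": ["CD8"] * n,
    }
    ds = make_dataset(counts, genes=["g1", "g2", "g3", "MKI67"], cells=cells, meta=meta)
    rows = []
    for i, c in enumerate(cells):
        nt = "TGTTTTGCT" if i < 2 else f"TGT{'ACT' * (i + 1)}"
        rows += pair(c, nt_b=nt)
    return normalize_log1p(ds), call_clonotypes(make_contigs(rows))


@pytest.fixture(scope="module")
def toy():
    return toy_dataset()


@pytest.fixture(scope="module")
def indices(toy):
    ds, assign = toy
    sets = GeneSetCollection(sets={"s1": ["g1"], "s2": ["g2"]})
    return compute_cluster_indices(
        ds, assign, sets, seed=0, min_tumor_cells=1, n_bins=1, n_ctrl=2
    )


class TestClusterIndices:
    def test_tumor_only_cluster_enrichment_two(self, indices):
        assert indices.loc["A", "tumor_enrichment"] == pytest.approx(2.0)

    def test_expansion_from_shared_clone(self, indices):
        # cluster A tumor cells: clone sizes {2,1,1,1}
        from ptrtkit.repertoire import entropy_stats

        assert indices.loc["A", "clonal_expansion"] == pytest.approx(
            entropy_stats([2, 1, 1, 1]).expansion_index
        )

    def test_singleton_cluster_without_tumor_cells_flagged(self, indices):
        assert np.isnan(indices.loc["B", "clonal_expansion"])
        assert indices.loc["B", "insufficient"] or indices.loc["B", "n_tumor_cells"] == 0

    def test_proliferation_fraction(self, indices):
        assert indices.loc["A", "proliferation"] == pytest.approx(1 / 5)
        assert indices.loc["B", "proliferation"] == 0.0

    def test_signaling_z_mean_zero_per_set(self, indices):
        for col in ("z_s1", "z_s2"):
            assert indices[col].mean() == pytest.approx(0.0, abs=1e-9)

    def test_constant_matrix_zero_z(self):
        n = 8
        ds = make_dataset(
            np.ones((n, 3), dtype=int),
            meta={
                "cluster": ["A"] * 4 + ["B"] * 4,
                "condition": ["tumor"] * n,
                "donor": ["d"] * n,
                "compartment": ["CD8"] * n,
            },
        )
        ds = normalize_log1p(ds)
        rows = []
        for i in range(n):
            rows += pair(f"c{i+1}", nt_b=f"TGT{'ACT' * (i + 1)}")
        assign = call_clonotypes(make_contigs(rows))
        sets = GeneSetCollection(sets={"s": ["g1"]})
        idx = compute_cluster_indices(
            ds, assign, sets, proliferation_genes=["g2"], seed=0,
            min_tumor_cells=1, n_bins=1,
        )
        np.testing.assert_allclose(idx["z_s"], 0.0, atol=1e-12)


class TestCallPtrt:
    def _row(self, **kw):
        base = {
            "tumor_enrichment": 2.0, "clonal_expansion": 0.6, "proliferation": 0.2,
            "signaling_z_median": 1.1, "insufficient": False,
        }
        base.update(kw)
        return base

    def test_all_criteria_pass(self):
        idx = pd.DataFrame([self._row()], index=["A"])
        assert call_ptrt_clusters(idx)["is_ptrt"].iloc[0]

    def test_single_failing_criterion_blocks(self):
        idx = pd.DataFrame([self._row(tumor_enrichment=0.4)], index=["A"])
        assert not call_ptrt_clusters(idx)["is_ptrt"].iloc[0]

    def test_boundary_semantics(self):
        # >= for the three indices, strict > for signaling z
        at_thresh = self._row(
            tumor_enrichment=1.2, clonal_expansion=0.2, proliferation=0.05,
            signaling_z_median=0.0,
        )
        idx = pd.DataFrame([at_thresh], index=["A"])
        assert not call_ptrt_clusters(idx)["is_ptrt"].iloc[0]
        idx.loc["A", "signaling_z_median"] = 1e-9
        assert call_ptrt_clusters(idx)["is_ptrt"].iloc[0]

    def test_insufficient_cluster_never_called(self):
        idx = pd.DataFrame([self._row(insufficient=True)], index=["A"])
        assert not call_ptrt_clusters(idx)["is_ptrt"].iloc[0]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        idx = pd.DataFrame(
            {
                "tumor_enrichment": rng.uniform(0, 3, 20),
                "clonal_expansion": rng.uniform(0, 1, 20),
                "proliferation": rng.uniform(0, 1, 20),
                "signaling_z_median": rng.normal(size=20),
                "insufficient": False,
            },
            index=[f"cl{i}" for i in range(20)],
        )
        base = set(call_ptrt_clusters(idx).query("is_ptrt").index)
        for field, delta in [
            ("tumor_enrichment", 0.5), ("clonal_expansion", 0.2),
            ("proliferation", 0.1), ("signaling_z", 0.7),
        ]:
            t = PtrtThresholds(**{field: getattr(PtrtThresholds(), field) + delta})
            raised = set(call_ptrt_clusters(idx, t).query("is_ptrt").index)
            assert raised <= base


class TestLabels:
    @pytest.fixture(scope="class")
    def labeled(self, toy):
        ds, assign = toy
        return ds, assign, label_reactivity(ds, assign, ["A"])

    def test_ptrt_cluster_cells_labeled_ptrt(self, labeled):
        ds, _, labels = labeled
        assert (labels.labels[:5] == PTRT).all()

    def test_partition_identity(self, labeled):
        ds, _, labels = labeled
        assert labels.labels.isin([PTRT, RELEVANT, IRRELEVANT]).all()
        assert len(labels.labels) == ds.n_cells

    def test_unassigned_cell_outside_ptrt_is_irrelevant(self, toy):
        ds, _ = toy
        rows = []
        for i in range(5):  # only cluster-A cells have TCRs now
            rows += pair(f"c{i+1}", nt_b=f"TGT{'ACT' * (i + 1)}")
        assign = call_clonotypes(make_contigs(rows))
        labels = label_reactivity(ds, assign, ["A"])
        assert (labels.labels[5:] == IRRELEVANT).all()

    def test_shared_clonotype_outside_becomes_relevant(self):
        ds, _ = toy_dataset()
        # move c2 (shares clonotype with c1) into cluster B
        ds.cell_meta.loc["c2", "cluster"] = "B"
        rows = []
        cells = list(ds.cell_ids)
        for i, c in enumerate(cells):
            nt = "TGTTTTGCT" if i < 2 else f"TGT{'ACT' * (i + 1)}"
            rows += pair(c, nt_b=nt)
        assign = call_clonotypes(make_contigs(rows))
        labels = label_reactivity(ds, assign, ["A"])
        assert labels.labels["c2"] == RELEVANT
        assert labels.tumor_reactive["c2"]

    def test_fresh_clonotype_bystander_changes_nothing(self, toy):
        ds, assign = toy
        before = label_reactivity(ds, assign, ["A"]).labels
        # add an 11th cell with a brand-new clonotype in cluster B
        import scipy.sparse as sp

        counts = np.vstack([np.asarray(ds.counts.todense()), np.ones((1, 4), int)])
        meta = pd.concat(
            [ds.cell_meta,
             pd.DataFrame({"cluster": ["B"], "condition": ["control"],
                           "donor": ["d1"], "compartment": ["CD8"]}, index=["c11"])]
        )
        ds2 = make_dataset(counts, genes=list(ds.gene_ids),
                           cells=list(ds.cell_ids) + ["c11"], meta=meta)
        rows = []
        for i, c in enumerate(ds.cell_ids):
            nt = "TGTTTTGCT" if i < 2 else f"TGT{'ACT' * (i + 1)}"
            rows += pair(c, nt_b=nt)
        rows += pair("c11", nt_b="TGTGGGGGGAAA")
        assign2 = call_clonotypes(make_contigs(rows))
        after = label_reactivity(ds2, assign2, ["A"]).labels
        pd.testing.assert_series_equal(before, after[before.index])
        assert after["c11"] == IRRELEVANT


class TestComposition:
    def test_fraction_by_hand(self, toy):
        ds, assign = toy
        ds2, _ = toy_dataset()
        ds2.cell_meta.loc["c2", "cluster"] = "B"
        rows = []
        for i, c in enumerate(ds2.cell_ids):
            nt = "TGTTTTGCT" if i < 2 else f"TGT{'ACT' * (i + 1)}"
            rows += pair(c, nt_b=nt)
        assign2 = call_clonotypes(make_contigs(rows))
        labels = label_reactivity(ds2, assign2, ["A"])
        comp = relevant_composition(labels, ds2.cell_meta["cluster"])
        assert comp["B"] == pytest.approx(1 / 6)
        assert comp["A"] == 0.0  # pTRT cluster: zero by construction
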