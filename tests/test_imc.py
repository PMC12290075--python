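import io

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import imctc
from imctc.imc import (
    GateNode,
    GateTree,
    UNGATED,
    apply_gates,
    arcsinh_transform,
    cluster_graph,
    default_gate_tree,
    filter_masks,
    load_gate_tree,
    marker_stats,
    percentile_normalize,
)
from imctc.simulate import IMC_MARKERS, IonPopulation, default_imc_populations


class TestFilterMasks:
    def test_boundaries_inclusive(self):
        df = pd.DataFrame(
            {"area": [39, 40, 200, 201], "DNA1": [10.0] * 4, "CD45": [1] * 4}
        )
        kept = filter_masks(df)
        assert kept["area"].tolist() == [40, 200]

    def test_dna1_threshold(self):
        df = pd.DataFrame({"area": [100, 100], "DNA1": [3.999, 4.0]})
        assert filter_masks(df)["DNA1"].tolist() == [4.0]

    def test_empty_table(self):
        df = pd.DataFrame({"area": [], "DNA1": []})
        assert len(filter_masks(df)) == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            filter_masks(pd.DataFrame({"area": [100]}))

    def test_pre_identified_ctc_bypass(self):
        df = pd.DataFrame(
            {
                "area": [10, 10, 10],
                "DNA1": [1.0, 1.0, 10.0],
                "population": ["im.CTC", "epi.CTC", "B cell"],
            }
        )
        kept = filter_masks(df)
        assert kept["population"].tolist() == ["im.CTC", "epi.CTC"]

    def test_idempotent(self):
        df = imctc.simulate_ion_counts(
            default_imc_populations(), 50, seed=4, qc_fail_fraction=0.2
        )
        once = filter_masks(df)
        pd.testing.assert_frame_equal(filter_masks(once), once)


class TestArcsinh:
    def test_closed_form_values(self):
        assert arcsinh_transform(0.0) == 0.0
        assert arcsinh_transform(1.0, 1.0) == pytest.approx(0.8813736, abs=1e-6)

    def test_monotone_and_cofactor(self):
        x = np.array([0.0, 1.0, 5.0, 50.0])
        y = arcsinh_transform(x, 2.0)
        assert np.all(np.diff(y) > 0)
        np.testing.assert_allclose(y, np.arcsinh(x / 2.0))

    def test_invalid_cofactor(self):
        with pytest.raises(ValueError):
            arcsinh_transform([1.0], 0.0)


class TestPercentileNormalize:
    def test_constant_column_scales_to_one(self):
        df = pd.DataFrame({"m": [5.0] * 20})
        out, flagged = percentile_normalize(df, ["m"])
        assert (out["m"] == 1.0).all() and flagged == []

    def test_linear_interpolation_percentile(self):
        df = pd.DataFrame({"m": np.arange(1, 101, dtype=float)})
        out, _ = percentile_normalize(df, ["m"], p=99)
        np.testing.assert_allclose(out["m"], np.arange(1, 101) / 99.01)
        assert out["m"].max() > 1.0  # no clipping above the percentile

    def test_zero_percentile_column_flagged(self):
        df = pd.DataFrame({"z": [0.0] * 10, "m": [1.0] * 10})
        out, flagged = percentile_normalize(df, ["z", "m"])
        assert flagged == ["z"]
        assert (out["z"] == 0.0).all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            percentile_normalize(pd.DataFrame({"m": []}), ["m"])


class TestClusterGraph:
    def test_two_separated_gaussians_perfectly_split(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(0, 1, (500, 3)), rng.normal(10, 1, (500, 3))]
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        labels = cluster_graph(df, ["a", "b", "c"], k_neighbors=30, seed=0)
        truth = np.r_[np.zeros(500), np.ones(500)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_population_one_cluster(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (200, 3)), columns=["a", "b", "c"])
        labels = cluster_graph(df, ["a", "b", "c"], k_neighbors=30, seed=0)
        assert len(set(labels)) == 1

    def test_deterministic_given_seed(self):
        df = imctc.simulate_ion_counts(default_imc_populations(), 60, seed=5)
        l1 = cluster_graph(df, IMC_MARKERS, k_neighbors=15, seed=3)
        l2 = cluster_graph(df, IMC_MARKERS, k_neighbors=15, seed=3)
        assert np.array_equal(l1, l2)

    def test_k_too_large_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            cluster_graph(df, ["a"], k_neighbors=3, seed=0)

    def test_recovers_default_scenario_populations(self):
        """Percentile normalisation then graph clustering separates the five
        leukocyte lineages and both CTC phenotypes (ARI >= 0.9)."""
        df = imctc.simulate_ion_counts(default_imc_populations(), 150, seed=6)
        norm, _ = percentile_normalize(df, IMC_MARKERS)
        labels = cluster_graph(norm, IMC_MARKERS, k_neighbors=30, seed=0)
        assert adjusted_rand_score(df["population"], labels) >= 0.9


@pytest.fixture(scope="module")
def gated():
    df = imctc.simulate_ion_counts(default_imc_populations(), 150, seed=7)
    return df, apply_gates(df, default_gate_tree())


@pytest.fixture(scope="module")
def ion_table():
    return imctc.simulate_ion_counts(default_imc_populations(), 100, seed=9)


class TestGates:

    def test_leukocyte_lineages_recovered(self, gated):
        df, labels = gated
        for pop in ("CD4 T cell", "CD8 T cell", "B cell", "NK cell", "monocyte"):
            sub = labels[df["population"] == pop]
            assert (sub == pop).mean() > 0.95, pop

    def test_ck_positive_cells_excluded_from_leukocyte_gates(self, gated):
        df, labels = gated
        ctc = labels[df["population"].isin(["im.CTC", "epi.CTC"])]
        leukocyte_gates = {"CD4 T cell", "CD8 T cell", "B cell", "NK cell",
                           "monocyte", "T cell", "leukocyte"}
        assert not ctc.isin(leukocyte_gates).any()

    def test_all_zero_cell_ungated(self):
        df = pd.DataFrame({m: [0] for m in IMC_MARKERS})
        labels = apply_gates(df, default_gate_tree())
        assert labels.iloc[0] == UNGATED

    def test_cd4_gate_only_inside_cd3(self):
        # CD45+, CD4+ but CD3- must not reach the CD4 T-cell leaf
        row = {m: 0.0 for m in IMC_MARKERS}
        row.update({"CD45": 60.0, "CD4": 30.0})
        labels = apply_gates(pd.DataFrame([row]), default_gate_tree())
        assert labels.iloc[0] == "leukocyte"  # matches root gate, no leaf

    def test_cd3_without_cd4_cd8_keeps_t_cell_label(self):
        row = {m: 0.0 for m in IMC_MARKERS}
        row.update({"CD45": 60.0, "CD3": 40.0})
        labels = apply_gates(pd.DataFrame([row]), default_gate_tree())
        assert labels.iloc[0] == "T cell"

    def test_cyclic_tree_rejected(self):
        with pytest.raises(ValueError):
            GateTree(
                (
                    GateNode("a", "b", ()),
                    GateNode("b", "a", ()),
                )
            )

    def test_yaml_roundtrip(self):
        doc = """
cofactor: 2.0
gates:
  - name: pos
    parent: null
    rules: {CD45: ">= 1.0"}
"""
        tree = load_gate_tree(io.StringIO(doc))
        assert tree.cofactor == 2.0
        assert tree.nodes[0].rules == (("CD45", ">=", 1.0),)

    def test_im_ctc_nearest_leukocyte_centroid_is_cd4_t(self):
        """On normalised markers, im.CTCs sit nearest the CD4 T-cell centroid
        among all leukocyte populations."""
        df = imctc.simulate_ion_counts(default_imc_populations(), 200, seed=8)
        norm, _ = percentile_normalize(df, IMC_MARKERS)
        cents = norm.groupby("population")[IMC_MARKERS].mean()
        im = cents.loc["im.CTC"]
        leuko = ["CD4 T cell", "CD8 T cell", "B cell", "NK cell", "monocyte"]
        dists = {p: np.linalg.norm(cents.loc[p] - im) for p in leuko}
        assert min(dists, key=dists.get) == "CD4 T cell"


class TestMarkerStats:
    @pytest.fixture()
    def table(self, ion_table):
        return ion_table

    def test_matrix_symmetric_unit_diagonal(self, table):
        res = marker_stats(table, "population", "im.CTC", "epi.CTC",
                           ["CD45", "CD3", "CD44", "Vimentin", "Ki67"])
        m = res.spearman
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)

    def test_rank_invariance_under_monotone_transform(self, table):
        markers = ["CD45", "CD44"]
        r1 = marker_stats(table, "population", "im.CTC", "epi.CTC", markers).spearman
        warped = table.copy()
        warped["CD45"] = np.expm1(np.sqrt(warped["CD45"]))
        r2 = marker_stats(warped, "population", "im.CTC", "epi.CTC", markers).spearman
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-12)

    def test_antitone_pair_is_minus_one(self):
        df = pd.DataFrame(
            {"x": np.arange(10.0), "y": -np.arange(10.0), "grp": ["a"] * 5 + ["b"] * 5}
        )
        res = marker_stats(df, "grp", "a", "b", ["x", "y"])
        assert res.spearman.loc["x", "y"] == pytest.approx(-1.0)

    def test_unknown_group_rejected(self, table):
        with pytest.raises(ValueError):
            marker_stats(table, "population", "im.CTC", "nope", ["CD45"])

    def test_group_summaries_reflect_expression_difference(self, table):
        res = marker_stats(table, "population", "im.CTC", "epi.CTC", ["CD45"])
        s = res.summaries.set_index("population")
        assert s.loc["im.CTC", "mean"] > s.loc["epi.CTC", "mean"]
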