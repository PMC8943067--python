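"""Hierarchical clustering, 2/3-1/3 scoring, Cramér's V, and marker tests."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from toponome.clustering import (
    composition_table,
    cramers_v,
    default_contrasts,
    group_marker_means,
    hierarchical_cluster,
    linkage_to_newick,
    pairwise_marker_tests,
    score_clusters,
)
from toponome.datasets import (
    female_study_composition,
    sex_comparison_composition,
    treatment_comparison_composition,
)


class TestHierarchical:
    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.random((6, 3))
        a = hierarchical_cluster(X, k=6)
        assert sorted(a.labels) == [1, 2, 3, 4, 5, 6]

    def test_two_separated_blobs_split_exactly(self, rng):
        X = np.vstack([rng.normal(0, 0.01, (10, 4)), rng.normal(5, 0.01, (8, 4))])
        a = hierarchical_cluster(X, k=2)
        lab = a.labels.to_numpy()
        assert len(set(lab[:10])) == 1 and len(set(lab[10:])) == 1
        assert lab[0] != lab[-1]

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical_cluster(rng.random((3, 2)), k=4)

    def test_labels_contiguous_and_deterministic(self, rng):
        X = rng.random((20, 3))
        a = hierarchical_cluster(X, k=5)
        b = hierarchical_cluster(X, k=5)
        assert set(a.labels) == {1, 2, 3, 4, 5}
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_newick_export_parses(self, rng):
        X = rng.random((6, 3))
        a = hierarchical_cluster(X, k=2, ids=list("abcdef"))
        nwk = linkage_to_newick(a.linkage_matrix, list("abcdef"))
        assert nwk.endswith(";") and nwk.count(",") == 5
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert {t.name for t in tree.get_terminals()} == set("abcdef")


class TestComposition:
    def test_single_level_counts_cluster_sizes(self):
        labels = pd.Series([1, 1, 2, 3, 3, 3], index=list("abcdef"))
        meta = pd.DataFrame({"group": ["V"] * 6}, index=list("abcdef"))
        tab = composition_table(labels, meta, "group")
        assert list(tab.loc["V"]) == [2, 1, 3]

    def test_published_table_margins(self):
        """The 7-cluster female composition has the published column totals
        and 103 cells in all."""
        tab = female_study_composition()
        assert list(tab.sum(axis=0)) == [11, 17, 23, 14, 20, 10, 8]
        assert int(tab.to_numpy().sum()) == 103
        assert list(tab.sum(axis=1)) == [55, 48]

    def test_random_assignment_matches_tally(self, rng):
        cells = [f"c{i}" for i in range(40)]
        labels = pd.Series(rng.integers(1, 5, 40), index=cells)
        meta = pd.DataFrame({"sex": rng.choice(["F", "M"], 40)}, index=cells)
        tab = composition_table(labels, meta, "sex")
        for s in ("F", "M"):
            for cl in tab.columns:
                assert tab.loc[s, cl] == sum(
                    (labels[c] == cl) and (meta.loc[c, "sex"] == s) for c in cells
                )

    def test_missing_metadata_rejected(self):
        labels = pd.Series([1, 2], index=["a", "b"])
        meta = pd.DataFrame({"group": ["V"]}, index=["a"])
        with pytest.raises(ValueError):
            composition_table(labels, meta, "group")


class TestScoring:
    def test_female_study_categories(self):
        """Scoring the published 7-cluster table: 51 cells predominantly
        Vehicle, 27 predominantly rescue, 25 mixed."""
        sc = score_clusters(female_study_composition(), "Vehicle")
        s = sc.summary
        assert s.loc["predominantly Vehicle", "n_cells"] == 51
        assert s.loc["predominantly SP-A1 rescue", "n_cells"] == 27
        assert s.loc["mixed", "n_cells"] == 25
        assert s.loc["predominantly Vehicle", "percent"] == pytest.approx(49.5, abs=0.05)
        assert s.loc["predominantly SP-A1 rescue", "percent"] == pytest.approx(26.2, abs=0.05)
        assert s.loc["mixed", "percent"] == pytest.approx(24.3, abs=0.05)
        # the predominantly-Vehicle clusters are 3, 5 and 7
        pv = sc.per_cluster.query("label == 'predominantly Vehicle'")["cluster"]
        assert set(pv) == {3, 5, 7}

    def test_exact_one_third_boundary_is_predominant_other(self):
        """A 2-of-6 cluster sits exactly at 1/3 and is labelled predominantly
        the other level, not mixed."""
        tab = pd.DataFrame({1: [2, 4]}, index=pd.Index(["V", "R"], name="g"))
        sc = score_clusters(tab, "V")
        assert sc.per_cluster.loc[0, "label"] == "predominantly R"

    def test_even_split_is_mixed(self):
        tab = pd.DataFrame({1: [5, 5]}, index=pd.Index(["V", "R"], name="g"))
        assert score_clusters(tab, "V").per_cluster.loc[0, "label"] == "mixed"

    def test_scale_invariance(self, rng):
        tab = pd.DataFrame(
            rng.integers(1, 30, (2, 6)), index=pd.Index(["A", "B"], name="g")
        )
        a = score_clusters(tab, "A").per_cluster["label"]
        b = score_clusters(tab * 7, "A").per_cluster["label"]
        assert list(a) == list(b)

    def test_cells_partition_and_percents_sum(self, rng):
        tab = pd.DataFrame(
            rng.integers(0, 30, (2, 8)) + 1, index=pd.Index(["A", "B"], name="g")
        )
        sc = score_clusters(tab, "A")
        assert sc.summary["n_cells"].sum() == tab.to_numpy().sum()
        assert sc.summary["percent"].sum() == pytest.approx(100.0)

    def test_non_binary_factor_rejected(self):
        tab = pd.DataFrame({1: [1, 2, 3]}, index=pd.Index(list("abc"), name="g"))
        with pytest.raises(ValueError):
            score_clusters(tab, "a")


class TestCramersV:
    def test_perfect_association(self):
        assert cramers_v([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_independence(self):
        assert cramers_v([[5, 5], [5, 5]]) == pytest.approx(0.0)

    def test_published_sex_and_treatment_values(self):
        assert cramers_v(sex_comparison_composition()) == pytest.approx(0.75, abs=0.005)
        assert cramers_v(treatment_comparison_composition()) == pytest.approx(0.39, abs=0.005)

    def test_agrees_with_independent_implementation(self, rng):
        from scipy.stats.contingency import association

        for _ in range(10):
            tab = rng.integers(1, 40, (3, 5))
            assert cramers_v(tab) == pytest.approx(association(tab, method="cramer"))

    def test_permutation_invariance_and_phi_equivalence(self, rng):
        tab = rng.integers(1, 40, (2, 2))
        v = cramers_v(tab)
        assert cramers_v(tab[::-1]) == pytest.approx(v)
        assert cramers_v(tab[:, ::-1]) == pytest.approx(v)
        # |phi| for the 2x2 table
        a, b = tab[0]
        c, d = tab[1]
        n = tab.sum()
        phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        assert v == pytest.approx(abs(phi))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cramers_v([[0, 0], [3, 4]])


class TestMarkerMeans:
    def make_profiles(self, rng, n=20):
        rows = []
        for i in range(n):
            rows.append(
                dict(cell_id=i, sample_id="S", group=rng.choice(["V", "R"]),
                     sex=rng.choice(["F", "M"]),
                     **{f"f_{m}": rng.random() for m in range(4)})
            )
        return pd.DataFrame(rows)

    def test_single_cell_means_equal_profile(self, rng):
        df = self.make_profiles(rng, n=1)
        out = group_marker_means(df)
        for m in range(4):
            assert out.loc["All", f"f_{m}"] == pytest.approx(df.loc[0, f"f_{m}"])

    def test_identical_groups_identical_rows(self):
        df = pd.DataFrame(
            [dict(group=g, sex="F", f_0=0.2, f_1=0.4) for g in ("V", "R") for _ in range(3)]
        )
        out = group_marker_means(df, "group")
        assert out.loc["V", "f_0"] == out.loc["R", "f_0"]

    def test_matches_brute_force_column_means(self, rng):
        df = self.make_profiles(rng)
        out = group_marker_means(df, ["group", "sex"])
        for key, sub in df.groupby(["group", "sex"]):
            for m in range(4):
                assert out.loc[key, f"f_{m}"] == pytest.approx(sub[f"f_{m}"].mean())


class TestPairwiseTests:
    def make_profiles(self, rng, shift_marker=None, delta=0.0, n=30):
        rows = []
        for g in ("SP-A1", "Vehicle"):
            for s in ("F", "M"):
                for i in range(n):
                    f = rng.random(7) * 0.5
                    if shift_marker is not None and g == "Vehicle":
                        f[shift_marker] += delta
                    rows.append(dict(cell_id=i, sample_id=f"{g}{s}", group=g, sex=s,
                                     **{f"f_{m}": f[m] for m in range(7)}))
        return pd.DataFrame(rows)

    def test_default_design_is_42_tests(self, rng):
        out = pairwise_marker_tests(self.make_profiles(rng))
        assert len(out) == 42
        assert out["contrast"].nunique() == 6

    def test_identical_groups_nothing_significant(self, rng):
        df = self.make_profiles(rng)
        # make the two treatment groups byte-identical within sex
        df.loc[df.group == "Vehicle", [f"f_{m}" for m in range(7)]] = (
            df.loc[df.group == "SP-A1", [f"f_{m}" for m in range(7)]].to_numpy()
        )
        out = pairwise_marker_tests(df)
        treat = out[out["contrast"].str.startswith("SP-A1 vs Vehicle")]
        assert (treat["pvalue"] > 0.9).all()
        assert not treat["significant"].any()

    def test_planted_shift_flags_only_that_marker(self, rng):
        df = self.make_profiles(rng, shift_marker=3, delta=0.4, n=40)
        out = pairwise_marker_tests(df)
        treat = out[out["contrast"] == "SP-A1 vs Vehicle (all)"].set_index("marker")
        assert treat.loc[3, "significant"]
        sex_all = out[out["contrast"] == "F vs M (all)"]
        assert not sex_all["significant"].any()

    def test_bh_hand_example(self):
        """BH on p = {0.01, 0.02, 0.03, 0.04} with 4 tests adjusts all to
        0.04 (running minimum of p * n/i)."""
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        # and the same through the package surface
        rng = np.random.default_rng(0)
        df = self.make_profiles(rng, n=5)
        out = pairwise_marker_tests(df)
        # adjusted values are the BH transform of the raw column
        _, oracle, _, _ = multipletests(out["pvalue"], method="fdr_bh")
        np.testing.assert_allclose(out["p_adjusted"], oracle)

    def test_undersized_group_rejected(self, rng):
        df = self.make_profiles(rng, n=1)
        with pytest.raises(ValueError):
            pairwise_marker_tests(df)
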