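import numpy as np
import pandas as pd
import pytest

from spcdelta import (
    assign_categories,
    category_distribution,
    export_gene_lists,
    fixture_category_map,
    hierarchical_cluster,
    load_fixture_table,
    rank_extremes,
    sample_correlation_matrix,
)

from .oracles import average_linkage_merges, pearson_direct


class TestFixtures:
    @pytest.mark.parametrize(
        "compartment,direction,n_rows",
        [
            ("cell", "down", 19),
            ("cell", "up", 16),
            ("secretome", "down", 28),
            ("secretome", "up", 28),
            ("xenograft", "down", 72),
            ("xenograft", "up", 37),
        ],
    )
    def test_fixture_shapes(self, compartment, direction, n_rows):
        table = load_fixture_table(compartment, direction)
        assert len(table) == n_rows
        assert {"category", "gene", "description", "rsc"} <= set(table.columns)

    def test_unknown_fixture_errors(self):
        with pytest.raises(ValueError):
            load_fixture_table("plasma", "up")


class TestCategories:
    def test_known_assignments_from_fixture_map(self):
        cmap = fixture_category_map()
        assert cmap["TUBB2A"] == "Cytoskeletal"
        assert cmap["FN1"] == "Extracellular matrix"

    def test_unmapped_defaults_to_unknown(self):
        table = pd.DataFrame({"gene": ["NOVEL1"]})
        out = assign_categories(table, {})
        assert out["category"].tolist() == ["Unknown function"]

    def test_distribution_rounding_half_up(self):
        # 2 of 18 -> 11.1; 1 of 18 -> 5.6 (round half-up to one decimal)
        table = pd.DataFrame(
            {"category": ["Drug resistance"] * 2 + ["Protein transport"] + ["Other"] * 15}
        )
        dist = category_distribution(table).set_index("category")
        assert dist.loc["Drug resistance", "percentage"] == 11.1
        assert dist.loc["Protein transport", "percentage"] == 5.6

    def test_single_category_is_hundred(self):
        dist = category_distribution(pd.DataFrame({"category": ["X"] * 7}))
        assert dist["percentage"].tolist() == [100.0]

    def test_percentages_sum_to_hundred_within_rounding(self):
        # each category contributes at most 0.05 rounding slack
        for compartment, direction in [("cell", "down"), ("xenograft", "down")]:
            table = load_fixture_table(compartment, direction)
            dist = category_distribution(table)
            slack = 0.05 * len(dist)
            assert dist["percentage"].sum() == pytest.approx(100.0, abs=slack)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            category_distribution(pd.DataFrame({"category": []}))


class TestExtremes:
    @pytest.mark.parametrize(
        "compartment,direction,gene,rsc",
        [
            ("cell", "down", "TUBB2A", -42.9),
            ("cell", "up", "PLS1", 7.1),
            ("secretome", "down", "FN1", -15.3),
            ("secretome", "up", "HBB", 5.0),
            ("xenograft", "down", "TUBB2A", -78.1),
            ("xenograft", "up", "POTEF", 23.0),
        ],
    )
    def test_most_extreme_protein_per_table(self, compartment, direction, gene, rsc):
        table = load_fixture_table(compartment, direction)
        assert rank_extremes(table, direction) == (gene, rsc)

    def test_invariant_to_row_order(self):
        table = load_fixture_table("cell", "down")
        shuffled = table.sample(frac=1.0, random_state=3)
        assert rank_extremes(shuffled, "down") == rank_extremes(table, "down")

    def test_tie_breaks_lexicographically(self):
        table = pd.DataFrame({"gene": ["ZZZ", "AAA"], "rsc": [5.0, 5.0]})
        assert rank_extremes(table, "up") == ("AAA", 5.0)

    def test_singleton(self):
        table = pd.DataFrame({"gene": ["ONLY"], "rsc": [-2.0]})
        assert rank_extremes(table, "down") == ("ONLY", -2.0)


class TestCorrelation:
    @staticmethod
    def _profiles(seed=0, n_prot=6, n_samp=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(size=(n_prot, n_samp)),
            index=[f"P{i}" for i in range(n_prot)],
            columns=[f"S{j}" for j in range(n_samp)],
        )

    def test_self_correlation_is_one(self):
        corr = sample_correlation_matrix(self._profiles())
        assert np.allclose(np.diag(corr), 1.0)

    def test_anticorrelated_profiles(self):
        x = np.array([0.1, 0.5, 0.9, 0.2])
        frame = pd.DataFrame({"A": x, "B": 1.0 - x})
        corr = sample_correlation_matrix(frame)
        assert corr.loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        nspc = self._profiles(seed=5)
        corr = sample_correlation_matrix(nspc)
        for a in nspc.columns:
            for b in nspc.columns:
                assert corr.loc[a, b] == pytest.approx(
                    pearson_direct(nspc[a], nspc[b]), abs=1e-12
                )

    def test_symmetric_positive_semidefinite(self):
        corr = sample_correlation_matrix(self._profiles(seed=8, n_prot=20, n_samp=10))
        assert np.allclose(corr, corr.T)
        eigenvalues = np.linalg.eigvalsh(corr.to_numpy())
        assert eigenvalues.min() > -1e-8

    def test_zero_variance_sample_named(self):
        frame = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="flat"):
            sample_correlation_matrix(frame)


class TestClustering:
    def test_identical_samples_merge_first(self):
        corr = pd.DataFrame(
            [[1.0, 1.0, 0.2], [1.0, 1.0, 0.3], [0.2, 0.3, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        corr = (corr + corr.T) / 2
        order, _, linkage = hierarchical_cluster(corr)
        assert linkage[0][2] == pytest.approx(0.0)
        assert abs(order.index("A") - order.index("B")) == 1

    def test_forced_topology_groups_close_pair(self):
        corr = pd.DataFrame(
            [[1.0, 0.99, 0.1], [0.99, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=["s1", "s2", "s3"], columns=["s1", "s2", "s3"],
        )
        order, reordered, _ = hierarchical_cluster(corr)
        assert abs(order.index("s1") - order.index("s2")) == 1
        assert list(reordered.index) == order

    def test_merge_heights_match_brute_force_average_linkage(self):
        rng = np.random.default_rng(17)
        profiles = pd.DataFrame(
            rng.uniform(size=(12, 6)), columns=[f"S{j}" for j in range(6)]
        )
        corr = sample_correlation_matrix(profiles)
        _, _, linkage = hierarchical_cluster(corr)
        dist = 1.0 - corr.to_numpy()
        np.fill_diagonal(dist, 0.0)
        merges = average_linkage_merges(dist)
        assert np.allclose(sorted(linkage[:, 2]), sorted(m[2] for m in merges), atol=1e-12)

    def test_asymmetric_input_rejected(self):
        bad = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            hierarchical_cluster(bad)


class TestGeneLists:
    def test_fixture_symbol_counts(self, tmp_path):
        tables = {
            (c, d): load_fixture_table(c, d)
            for c, d in [("cell", "up"), ("secretome", "down")]
        }
        lists = export_gene_lists(tables, tmp_path)
        assert len(lists[("cell", "up")]) == 16
        assert len(lists[("secretome", "down")]) == 28
        written = (tmp_path / "genes_cell_up.txt").read_text().strip().split("\n")
        assert written == lists[("cell", "up")]

    def test_empty_table_empty_file(self, tmp_path):
        lists = export_gene_lists({("cell", "up"): pd.DataFrame({"gene": []})}, tmp_path)
        assert lists[("cell", "up")] == []
        assert (tmp_path / "genes_cell_up.txt").read_text() == ""

    def test_duplicates_removed(self):
        table = pd.DataFrame({"gene": ["FN1", "FN1", "PLEC"]})
        lists = export_gene_lists({("secretome", "down"): table})
        assert lists[("secretome", "down")] == ["FN1", "PLEC"]
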