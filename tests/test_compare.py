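import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cubkit import anova_duncan, correlate_indices, rscu_cluster

from .oracles import oracle_pearson


class TestCorrelations:
    def test_perfect_linearity(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2 * np.arange(10.0)})
        table = correlate_indices(df).table
        row = table[(table.index_a == "x") & (table.index_b == "y")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p_value < 1e-6

    def test_self_correlation_is_exactly_one(self):
        df = pd.DataFrame({"x": np.random.default_rng(0).normal(size=20)})
        table = correlate_indices(df).table
        assert table[(table.index_a == "x") & (table.index_b == "x")].iloc[0].r == 1.0

    def test_constant_column_undefined(self):
        df = pd.DataFrame({"x": np.ones(12), "y": np.arange(12.0)})
        table = correlate_indices(df).table
        row = table[(table.index_a == "x") & (table.index_b == "y")].iloc[0]
        assert np.isnan(row.r)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.normal(size=5), "y": rng.normal(size=5)})
        with pytest.warns(UserWarning, match="observations"):
            table = correlate_indices(df).table
        row = table[(table.index_a == "x") & (table.index_b == "y")].iloc[0]
        assert row.r == pytest.approx(oracle_pearson(df.x, df.y), abs=1e-12)

    def test_pairwise_complete_handling(self):
        df = pd.DataFrame(
            {"x": [1, 2, 3, 4, np.nan, 6.0] * 3, "y": [2, 4, 6, 8, 10, np.nan] * 3}
        )
        table = correlate_indices(df).table
        row = table[(table.index_a == "x") & (table.index_b == "y")].iloc[0]
        assert row.n == 12  # rows with either value missing excluded

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        mat = correlate_indices(df).matrix("r")
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)


class TestAnovaDuncan:
    def test_identical_groups_share_one_letter(self):
        g = {"a": [1.0, 1, 1, 1], "b": [1.0, 1, 1, 1], "c": [1.0, 1, 1, 1]}
        res = anova_duncan(g)
        assert set(res.summary.letters) == {"a"}

    def test_huge_separation_gets_distinct_letters(self):
        rng = np.random.default_rng(1)
        g = {"lo": rng.normal(0, 0.01, 10), "hi": rng.normal(100, 0.01, 10)}
        res = anova_duncan(g)
        letters = res.letters()
        assert letters["hi"] == "a" and letters["lo"] == "b"
        assert res.p_value < 1e-12

    def test_two_groups_agree_with_pooled_t_test(self):
        rng = np.random.default_rng(42)
        agree = 0
        for _ in range(50):
            x = rng.normal(0, 1, 12)
            y = rng.normal(rng.uniform(0, 1.2), 1, 12)
            res = anova_duncan({"x": x, "y": y}, alpha=0.05)
            duncan_reject = len(set(res.summary.letters)) > 1
            t_reject = stats.ttest_ind(x, y, equal_var=True).pvalue < 0.05
            agree += duncan_reject == t_reject
        assert agree == 50

    def test_null_rate_two_groups_approximates_alpha(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_runs = 400
        for _ in range(n_runs):
            g = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)}
            res = anova_duncan(g, alpha=0.05)
            rejections += len(set(res.summary.letters)) > 1
        rate = rejections / n_runs
        assert 0.02 <= rate <= 0.09  # binomial noise around 0.05

    def test_null_rate_three_groups_bounded_by_protection_level(self):
        # Duncan's span-3 significance level is 1 - 0.95^2 = 0.0975
        rng = np.random.default_rng(8)
        rejections = 0
        n_runs = 300
        for _ in range(n_runs):
            g = {lab: rng.normal(0, 1, 10) for lab in "abc"}
            rejections += len(set(anova_duncan(g).summary.letters)) > 1
        assert rejections / n_runs <= 0.0975 + 0.05

    def test_middle_group_can_share_both_letters(self):
        rng = np.random.default_rng(3)
        g = {
            "lo": rng.normal(0.0, 1, 15),
            "mid": rng.normal(1.1, 1, 15),
            "hi": rng.normal(2.2, 1, 15),
        }
        res = anova_duncan(g)
        letters = res.letters()
        assert letters["hi"] != letters["lo"]
        assert set(letters["mid"]) & (set(letters["hi"]) | set(letters["lo"]))

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            anova_duncan({"only": [1.0, 2.0]})
        with pytest.raises(ValueError):
            anova_duncan({"a": [1.0], "b": [1.0, 2.0]})


def _vec(values, n=59):
    rng = np.random.default_rng(values)
    return pd.Series(rng.normal(size=n), index=[f"c{i}" for i in range(n)])


class TestRSCUCluster:
    def test_identical_vectors_merge_first_at_zero(self):
        v = _vec(1)
        tree = rscu_cluster({"a": v, "b": v.copy(), "c": _vec(2) + 10})
        assert tree.heights[0] == pytest.approx(0.0)
        nwk = tree.to_newick()
        assert "a" in nwk and "b" in nwk and "c" in nwk

    def test_root_split_separates_blobs(self):
        base1, base2 = _vec(3), _vec(4) + 100
        vectors = {
            "a1": base1 + 0.01, "a2": base1 - 0.01,
            "b1": base2 + 0.01, "b2": base2 - 0.01,
        }
        tree = rscu_cluster(vectors)
        # last merge joins the two blobs at a much greater height
        assert tree.heights[-1] > 10 * tree.heights[-2]
        nwk = tree.to_newick()
        a_side = nwk.index("a1")
        assert ("a2" in nwk[: nwk.index("b1")]) == ("a2" in nwk[: nwk.index("b2")])

    def test_deterministic_under_input_reordering(self):
        vectors = {lab: _vec(i) for i, lab in enumerate("abcdef")}
        fwd = rscu_cluster(vectors).to_newick()
        rev = rscu_cluster(dict(reversed(list(vectors.items())))).to_newick()
        assert fwd == rev

    def test_heights_non_decreasing_and_leaves_match(self):
        vectors = {lab: _vec(i + 10) for i, lab in enumerate("abcd")}
        tree = rscu_cluster(vectors)
        assert np.all(np.diff(tree.heights) >= -1e-12)
        assert tree.labels == ("a", "b", "c", "d")

    def test_nan_entries_imputed(self):
        v1, v2 = _vec(5), _vec(6)
        v1.iloc[0] = np.nan
        tree = rscu_cluster({"a": v1, "b": v2})
        assert np.isfinite(tree.heights).all()

    def test_requires_two_labels(self):
        with pytest.raises(ValueError):
            rscu_cluster({"a": _vec(1)})
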