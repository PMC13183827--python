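"""Selection indices: rescaling, factor analysis, MGIDI/MTSI/FAI/SH,
gains and coincidence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from turmsel import indices
from turmsel.fieldbook import TraitSpec
from turmsel.genparams import selection_intensity


def _specs(*names, decrease=()):
    return [TraitSpec(n, direction="decrease" if n in decrease else "increase")
            for n in names]


class TestRescale:
    def test_increase_and_decrease(self):
        df = pd.DataFrame({"a": [0.0, 50, 100], "b": [0.0, 50, 100]},
                          index=list("xyz"))
        out = indices.rescale_traits(df, _specs("a", "b", decrease=("b",)))
        assert list(out["a"]) == [0, 50, 100]
        assert list(out["b"]) == [100, 50, 0]

    def test_rank_preservation(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        out = indices.rescale_traits(df, _specs("a"))
        rho = stats.spearmanr(df["a"], out["a"]).statistic
        assert rho == pytest.approx(1)
        out_dec = indices.rescale_traits(df, _specs("a", decrease=("a",)))
        assert stats.spearmanr(df["a"], out_dec["a"]).statistic == pytest.approx(-1)

    def test_constant_trait_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="a"):
            indices.rescale_traits(df, _specs("a"))


class TestFactorAnalysis:
    def test_two_block_structure(self):
        """Two independent blocks of three near-duplicate traits produce two
        rotated factors, one per block."""
        rng = np.random.default_rng(1)
        f1, f2 = rng.normal(size=(2, 200))
        X = pd.DataFrame({
            "a1": f1, "a2": f1 + rng.normal(scale=0.01, size=200),
            "a3": f1 + rng.normal(scale=0.01, size=200),
            "b1": f2, "b2": f2 + rng.normal(scale=0.01, size=200),
            "b3": f2 + rng.normal(scale=0.01, size=200)})
        fm = indices.factor_analysis(X)
        assert fm.retained_k == 2
        L = fm.loadings.abs()
        for block, traits in (("a", ["a1", "a2", "a3"]), ("b", ["b1", "b2", "b3"])):
            dominant = L.loc[traits].idxmax(axis=1).unique()
            assert len(dominant) == 1
            assert (L.loc[traits, dominant[0]] > 0.95).all()

    def test_identity_correlation_tie_policy(self):
        rng = np.random.default_rng(2)
        n = 500
        # whitened data: sample correlation exactly identity
        raw = rng.normal(size=(n, 4))
        raw -= raw.mean(axis=0)
        W = np.linalg.inv(np.linalg.cholesky(np.cov(raw, rowvar=False)))
        X = pd.DataFrame(raw @ W.T, columns=list("abcd"))
        fm = indices.factor_analysis(X)
        assert fm.retained_k == 1

    def test_rotation_preserves_total_variance(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(150, 2))
        X = pd.DataFrame(base @ rng.normal(size=(2, 6)) +
                         0.5 * rng.normal(size=(150, 6)),
                         columns=[f"t{i}" for i in range(6)])
        fm = indices.factor_analysis(X)
        k = fm.retained_k
        assert fm.communalities.sum() == pytest.approx(
            fm.eigenvalues[:k].sum(), rel=1e-8)
        assert ((fm.loadings ** 2).sum().sum()
                == pytest.approx(fm.eigenvalues[:k].sum(), rel=1e-8))


def _population(seed=0, n=60):
    rng = np.random.default_rng(seed)
    sink = rng.normal(size=n)
    X = pd.DataFrame({
        "TY": 0.9 * sink + 0.3 * rng.normal(size=n),
        "WPR": 0.8 * sink + 0.4 * rng.normal(size=n),
        "NPR": 0.6 * sink + 0.6 * rng.normal(size=n),
        "DR": -0.3 * sink + 0.9 * rng.normal(size=n),
    }, index=[f"g{i:03d}" for i in range(n)])
    return X


class TestMgidi:
    def test_genotype_at_ideotype_ranks_first(self):
        X = _population()
        best = X.max() + 1.0
        X.loc["ideal"] = best  # will rescale to 100 on every trait
        resc = indices.rescale_traits(X, _specs(*X.columns))
        fm = indices.factor_analysis(resc)
        ideo = fm.project(pd.Series(100.0, index=X.columns))
        res = indices.mgidi(fm, ideo, si=0.2)
        assert res.scores["ideal"] == pytest.approx(0, abs=1e-8)
        assert res.ranking[0] == "ideal"

    def test_symmetric_genotypes_tie(self):
        X = _population(seed=4)
        resc = indices.rescale_traits(X, _specs(*X.columns))
        fm = indices.factor_analysis(resc)
        ideo = fm.project(pd.Series(100.0, index=X.columns))
        F = fm.scores
        mirrored = 2 * ideo - F.loc["g000"].to_numpy()
        d1 = np.sqrt(((F.loc["g000"].to_numpy() - ideo) ** 2).sum())
        d2 = np.sqrt(((mirrored - ideo) ** 2).sum())
        assert d1 == pytest.approx(d2)

    def test_selected_count_rounding(self):
        assert indices.n_selected(0.20, 265) == 53
        assert indices.n_selected(0.20, 262) == 52
        assert indices.n_selected(0.5, 5) == 3  # half-up

    def test_affine_invariance_of_raw_traits(self):
        X = _population(seed=5)
        specs = _specs(*X.columns)
        X2 = X * 3.7 + 11.0
        def run(data):
            resc = indices.rescale_traits(data, specs)
            fm = indices.factor_analysis(resc)
            ideo = fm.project(pd.Series(100.0, index=data.columns))
            return indices.mgidi(fm, ideo, si=0.2)
        r1, r2 = run(X), run(X2)
        assert r1.ranking == r2.ranking
        np.testing.assert_allclose(r1.scores, r2.scores, atol=1e-8)


class TestFai:
    def test_ideotype_probability_one(self):
        X = _population(seed=6)
        X.loc["ideal"] = X.max() + 1.0
        X.loc["worst"] = X.min() - 1.0
        resc = indices.rescale_traits(X, _specs(*X.columns))
        fm = indices.factor_analysis(resc)
        res = indices.fai(fm, si=0.2)
        assert res.scores["ideal"] == pytest.approx(1.0)
        assert res.scores["worst"] == pytest.approx(0.0)
        assert res.ranking[0] == "ideal"

    def test_equidistant_probability_half(self):
        X = _population(seed=7)
        resc = indices.rescale_traits(X, _specs(*X.columns))
        fm = indices.factor_analysis(resc)
        ideo = fm.project(pd.Series(100.0, index=X.columns))
        anti = fm.project(pd.Series(0.0, index=X.columns))
        mid = (ideo + anti) / 2
        d_id = np.sqrt(((mid - ideo) ** 2).sum())
        d_an = np.sqrt(((mid - anti) ** 2).sum())
        assert d_id == pytest.approx(d_an)
        p = (1 / d_id) / (1 / d_id + 1 / d_an)
        assert p == pytest.approx(0.5)

    def test_positive_rank_correlation_with_mgidi(self):
        X = _population(seed=8, n=120)
        resc = indices.rescale_traits(X, _specs(*X.columns))
        fm = indices.factor_analysis(resc)
        ideo = fm.project(pd.Series(100.0, index=X.columns))
        rm = indices.mgidi(fm, ideo, si=0.2)
        rf = indices.fai(fm, si=0.2)
        rho = stats.spearmanr(rm.scores.rank(), (-rf.scores).rank()).statistic
        assert rho > 0.5


class TestMtsi:
    def test_theta_one_reduces_to_mgidi(self):
        a, b = _population(seed=9), _population(seed=10)
        b.index = a.index
        specs = _specs(*a.columns)
        res = indices.mtsi({"Y1": a, "Y2": b}, specs, si=0.2, theta=1.0)
        pooled = (a + b) / 2
        resc = indices.rescale_traits(pooled, specs)
        fm = indices.factor_analysis(resc)
        ideo = fm.project(pd.Series(100.0, index=pooled.columns))
        ref = indices.mgidi(fm, ideo, si=0.2)
        assert res.ranking == ref.ranking

    def test_identical_years_match_mgidi(self):
        a = _population(seed=11)
        specs = _specs(*a.columns)
        res = indices.mtsi({"Y1": a, "Y2": a.copy()}, specs, si=0.2, theta=0.5)
        resc = indices.rescale_traits(a, specs)
        fm = indices.factor_analysis(resc)
        ideo = fm.project(pd.Series(100.0, index=a.columns))
        ref = indices.mgidi(fm, ideo, si=0.2)
        assert res.ranking == ref.ranking

    def test_unstable_genotype_penalized(self):
        a = _population(seed=12, n=80)
        b = a.copy()
        # one genotype with high mean but wildly different years
        a.loc["g000"] = a.max() + 2.0
        b.loc["g000"] = a.min() - 2.0
        specs = _specs(*a.columns)
        r_mtsi = indices.mtsi({"Y1": a, "Y2": b}, specs, si=0.2, theta=0.5)
        r_mgidi = indices.mtsi({"Y1": a, "Y2": b}, specs, si=0.2, theta=1.0)
        assert r_mtsi.ranking.index("g000") > r_mgidi.ranking.index("g000")

    def test_single_year_rejected(self):
        with pytest.raises(ValueError, match="MGIDI"):
            indices.mtsi({"Y1": _population()}, _specs("TY"), si=0.2)


class TestSmithHazel:
    def test_identity_matrices_give_trait_sum(self):
        X = _population(seed=13)
        eye = pd.DataFrame(np.eye(4), index=X.columns, columns=X.columns)
        w = pd.Series(1.0, index=X.columns)
        res = indices.smith_hazel(eye, eye, w, X, si=0.2)
        np.testing.assert_allclose(res.b_vector, 1.0)
        Z = (X - X.mean()) / X.std(ddof=1)
        np.testing.assert_allclose(res.scores, Z.sum(axis=1), atol=1e-10)

    def test_two_trait_hand_inversion(self):
        P = pd.DataFrame([[2.0, 0], [0, 1.0]], index=["a", "b"], columns=["a", "b"])
        G = pd.DataFrame([[1.0, 0], [0, 0.5]], index=["a", "b"], columns=["a", "b"])
        w = pd.Series([1.0, 1.0], index=["a", "b"])
        means = pd.DataFrame({"a": [0., 1, 2], "b": [2., 1, 0]}, index=list("xyz"))
        res = indices.smith_hazel(P, G, w, means, si=0.34)
        np.testing.assert_allclose(res.b_vector, [0.5, 0.5])

    def test_zero_weights_all_tie(self):
        X = _population(seed=14)
        eye = pd.DataFrame(np.eye(4), index=X.columns, columns=X.columns)
        w = pd.Series(0.0, index=X.columns)
        res = indices.smith_hazel(eye, eye, w, X, si=0.2)
        assert res.scores.nunique() == 1
        # deterministic lexicographic tie-break
        assert res.selected == sorted(X.index)[:indices.n_selected(0.2, len(X))]

    def test_beats_single_trait_index_for_aggregate_worth(self):
        """With known G and P, corr(b'x, w'g) exceeds the correlation of any
        single-trait index with aggregate worth, across 50 seeds."""
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 150
            g = rng.multivariate_normal([0, 0], [[1.0, 0.4], [0.4, 1.0]], size=n)
            e = rng.multivariate_normal([0, 0], [[0.8, 0.1], [0.1, 1.2]], size=n)
            x = g + e
            G = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
            P = G + pd.DataFrame([[0.8, 0.1], [0.1, 1.2]], index=["a", "b"],
                                 columns=["a", "b"])
            w = pd.Series([1.0, 1.0], index=["a", "b"])
            means = pd.DataFrame(x, columns=["a", "b"])
            res = indices.smith_hazel(P, G, w, means, si=0.2)
            worth = g.sum(axis=1)
            r_index = np.corrcoef(res.scores, worth)[0, 1]
            r_single = max(np.corrcoef(x[:, 0], worth)[0, 1],
                           np.corrcoef(x[:, 1], worth)[0, 1])
            wins += r_index >= r_single - 1e-9
        assert wins >= 45


class TestGains:
    def test_select_all_zero_gain(self):
        X = _population(seed=15)
        gains = indices.selection_gains(X, list(X.index), {t: 0.8 for t in X.columns})
        np.testing.assert_allclose(gains["differential"], 0, atol=1e-12)
        np.testing.assert_allclose(gains["SG_pct"], 0, atol=1e-12)

    def test_hand_computed_gain(self):
        means = pd.DataFrame({"t": [8.0, 12.0, 10.0, 10.0]}, index=list("abcd"))
        gains = indices.selection_gains(means, ["b"], {"t": 0.5})
        # mean_all 10, selected 12, H2 0.5 -> SG = 10%
        assert gains.loc[0, "SG_pct"] == pytest.approx(10.0)

    def test_truncation_differential_matches_intensity(self):
        """Selecting the top 20% of a simulated normal trait realizes a
        standardized differential close to k(0.2)."""
        rng = np.random.default_rng(16)
        n = 4000
        means = pd.DataFrame({"t": rng.normal(50, 10, n)},
                             index=[f"g{i}" for i in range(n)])
        top = means["t"].nlargest(indices.n_selected(0.2, n)).index.tolist()
        gains = indices.selection_gains(means, top, {"t": 1.0})
        d_std = gains.loc[0, "differential"] / means["t"].std(ddof=1)
        assert d_std == pytest.approx(selection_intensity(0.2), abs=0.06)


class TestCoincidence:
    def test_identical_sets_full_overlap(self):
        res = indices.coincidence({"A": {"a", "b"}, "B": {"a", "b"}})
        assert res.pairwise.loc[0, "pct"] == pytest.approx(100)
        assert res.all_methods_common == ["a", "b"]

    def test_disjoint_sets(self):
        res = indices.coincidence({"A": {"a", "b"}, "B": {"c", "d"}})
        assert res.pairwise.loc[0, "n_common"] == 0
        assert res.all_methods_common == []

    def test_percentage_arithmetic(self):
        sel = [f"g{i}" for i in range(53)]
        other = sel[:48] + [f"h{i}" for i in range(5)]
        res = indices.coincidence({"MGIDI": sel, "FAI": other})
        assert res.pairwise.loc[0, "n_common"] == 48
        assert res.pairwise.loc[0, "pct"] == pytest.approx(90.6, abs=0.05)

    def test_symmetry_and_venn_partition(self):
        sets = {"A": {"a", "b", "c"}, "B": {"b", "c", "d"}, "C": {"c", "d", "e"}}
        res = indices.coincidence(sets)
        total = sum(res.venn_partition_counts.values())
        assert total == len({"a", "b", "c", "d", "e"})
        assert res.venn_partition_counts["A&B&C"] == 1
        assert res.all_methods_common == ["c"]
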