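"""Federer block adjustment and augmented-design ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from turmsel import arcbd
from conftest import make_fieldbook


def ols_block_effects(fb, year, trait):
    """Oracle: sum-to-zero block effects from an OLS fit of the additive
    check + block model restricted to check plots."""
    df = fb.to_frame()
    sub = df[(df["year"] == year) & (df["role"] == "check")].dropna(subset=[trait])
    y = sub[trait].to_numpy(float)
    blocks = sorted(sub["block"].unique())
    checks = sorted(sub["genotype"].unique())
    # effect coding: last level = -sum of the others
    def code(labels, levels):
        X = np.zeros((len(labels), len(levels) - 1))
        for i, lab in enumerate(labels):
            k = levels.index(lab)
            if k < len(levels) - 1:
                X[i, k] = 1
            else:
                X[i, :] = -1
        return X
    X = np.column_stack([np.ones(len(y)),
                         code(list(sub["genotype"]), checks),
                         code(list(sub["block"]), blocks)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    nb = len(blocks) - 1
    b = beta[-nb:]
    return dict(zip(blocks, np.append(b, -b.sum())))


def ols_entry_means(fb, year, trait):
    """Oracle: per-genotype entry means y - beta_block from the full
    two-way OLS fit (blocks effect-coded, all plots)."""
    effects = ols_block_effects(fb, year, trait)
    df = fb.to_frame()
    sub = df[df["year"] == year].dropna(subset=[trait])
    corrected = sub[trait] - sub["block"].map(effects)
    return corrected.groupby(sub["genotype"]).mean()


class TestBlockEffects:
    def test_identical_checks_give_zero_effects(self):
        fb = make_fieldbook(value_fn=lambda y, b, g, t, rng:
                            5.0 if g.startswith("C") else float(rng.normal()))
        eff = arcbd.estimate_block_effects(fb, "Y1", "T1")
        assert all(abs(v) < 1e-12 for v in eff.values())

    def test_two_point_centering(self):
        vals = {"B1": 10.0, "B2": 14.0}
        fb = make_fieldbook(n_blocks=2, checks=("C1",), n_tests=2,
                            value_fn=lambda y, b, g, t, rng:
                            vals[b] if g == "C1" else 0.0)
        eff = arcbd.estimate_block_effects(fb, "Y1", "T1")
        assert eff == {"B1": -2.0, "B2": 2.0}

    def test_matches_ols_oracle(self):
        fb = make_fieldbook(n_blocks=4, checks=("C1", "C2", "C3"), n_tests=10, seed=7)
        eff = arcbd.estimate_block_effects(fb, "Y1", "T1")
        oracle = ols_block_effects(fb, "Y1", "T1")
        for blk in eff:
            assert eff[blk] == pytest.approx(oracle[blk], abs=1e-9)

    def test_missing_check_names_block(self):
        def vf(year, block, geno, trait, rng):
            if geno == "C2" and block == "B3":
                return float("nan")
            return float(rng.normal(10, 1))
        fb = make_fieldbook(value_fn=vf)
        with pytest.raises(arcbd.BlockEffectError, match="B3"):
            arcbd.estimate_block_effects(fb, "Y1", "T1")


class TestAdjustMeans:
    def test_zero_effects_leave_means_unchanged(self):
        fb = make_fieldbook(value_fn=lambda y, b, g, t, rng:
                            5.0 if g.startswith("C") else float(rng.normal(20, 3)))
        am = arcbd.adjust_means(fb, "Y1", "T1")
        pd.testing.assert_series_equal(am["raw_mean"], am["adjusted_mean"],
                                       check_names=False)

    def test_direct_formula(self):
        # test plot at 20 in a block whose checks average +3 above the rest
        def vf(year, block, geno, trait, rng):
            if geno.startswith("C"):
                return {"B1": 13.0, "B2": 7.0}[block]
            return 20.0
        fb = make_fieldbook(n_blocks=2, checks=("C1", "C2"), n_tests=2, value_fn=vf)
        am = arcbd.adjust_means(fb, "Y1", "T1").set_index("genotype")
        tests = am[am["role"] == "test"]
        for g, row in tests.iterrows():
            expected = 20.0 - row["block_effect"]
            assert row["adjusted_mean"] == pytest.approx(expected)
            assert abs(row["block_effect"]) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_matches_full_ols_entry_means(self, seed):
        fb = make_fieldbook(n_blocks=5, n_tests=15, seed=seed)
        am = arcbd.adjust_means(fb, "Y1", "T1").set_index("genotype")
        oracle = ols_entry_means(fb, "Y1", "T1")
        for g in am.index:
            assert am.loc[g, "adjusted_mean"] == pytest.approx(oracle[g], abs=1e-9)

    def test_check_means_invariant_to_block_permutation(self):
        fb = make_fieldbook(seed=5)
        am1 = arcbd.adjust_means(fb, "Y1", "T1")
        perm = {"B1": "B3", "B2": "B1", "B3": "B4", "B4": "B2"}
        from turmsel.fieldbook import FieldBook, PlotRecord
        fb2 = FieldBook(records=[PlotRecord(r.year, perm[r.block], r.plot, r.genotype,
                                            r.role, r.values) for r in fb.records],
                        traits=fb.traits)
        am2 = arcbd.adjust_means(fb2, "Y1", "T1")
        checks1 = am1[am1["role"] == "check"].set_index("genotype")["adjusted_mean"]
        checks2 = am2[am2["role"] == "check"].set_index("genotype")["adjusted_mean"]
        pd.testing.assert_series_equal(checks1, checks2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50, allow_nan=False), seed=st.integers(0, 50))
    def test_translation_equivariance(self, shift, seed):
        """Adding a constant to every plot of one block moves every adjusted
        mean by exactly shift/n_blocks (the grand check mean absorbs
        shift/b), so all genotype differences are untouched."""
        fb = make_fieldbook(seed=seed)
        am1 = arcbd.adjust_means(fb, "Y1", "T1").set_index("genotype")
        from turmsel.fieldbook import FieldBook, PlotRecord
        fb2 = FieldBook(records=[
            PlotRecord(r.year, r.block, r.plot, r.genotype, r.role,
                       {k: v + shift if r.block == "B2" else v
                        for k, v in r.values.items()})
            for r in fb.records], traits=fb.traits)
        am2 = arcbd.adjust_means(fb2, "Y1", "T1").set_index("genotype")
        delta = am2["adjusted_mean"] - am1.loc[am2.index, "adjusted_mean"]
        np.testing.assert_allclose(delta, shift / 4, atol=1e-8)


def projection_ss(y, X0, X1, X2):
    """Oracle: sequential sums of squares via explicit projections."""
    def proj(X):
        return X @ np.linalg.pinv(X.T @ X) @ X.T
    P0, P1, P2 = proj(X0), proj(X1), proj(X2)
    return (float(y @ (P1 - P0) @ y), float(y @ (P2 - P1) @ y),
            float(y @ (np.eye(len(y)) - P2) @ y))


class TestAnova:
    def test_zero_error_case(self):
        check_vals = {"C1": 4.0, "C2": 8.0, "C3": 9.0}
        fb = make_fieldbook(value_fn=lambda y, b, g, t, rng:
                            check_vals.get(g, float(rng.normal(10, 2))))
        an = arcbd.arcbd_anova(fb, "Y1", "T1")
        tbl = an.table.set_index("source")
        assert tbl.loc["Residuals", "SS"] == pytest.approx(0, abs=1e-18)
        # checks SS equals the between-check SS of the replicated values
        nb = an.n_blocks
        vals = np.array(list(check_vals.values()))
        assert tbl.loc["Genotypes: checks", "SS"] == pytest.approx(
            nb * ((vals - vals.mean()) ** 2).sum())

    @pytest.mark.parametrize("seed", [1, 2, 8])
    def test_matches_projection_oracle(self, seed):
        fb = make_fieldbook(n_blocks=4, n_tests=9, seed=seed)
        an = arcbd.arcbd_anova(fb, "Y1", "T1")
        df = fb.to_frame().dropna(subset=["T1"])
        y = df["T1"].to_numpy(float)
        X0 = np.ones((len(y), 1))
        Xg = pd.get_dummies(df["genotype"]).to_numpy(float)
        Xb = pd.get_dummies(df["block"]).to_numpy(float)
        ss_g, ss_b, ss_r = projection_ss(y, X0, np.column_stack([X0, Xg]),
                                         np.column_stack([X0, Xg, Xb]))
        tbl = an.table.set_index("source")
        assert tbl.loc["Genotypes (ignoring blocks)", "SS"] == pytest.approx(ss_g)
        assert tbl.loc["Block (eliminating genotypes)", "SS"] == pytest.approx(ss_b, abs=1e-8)
        assert tbl.loc["Residuals", "SS"] == pytest.approx(ss_r, abs=1e-8)
        # and the genotype sub-partition adds up
        parts = (tbl.loc["Genotypes: checks", "SS"]
                 + tbl.loc["Genotypes: tests", "SS"]
                 + tbl.loc["Genotypes: tests vs checks", "SS"])
        assert parts == pytest.approx(ss_g)

    def test_ss_identity_property(self):
        for seed in range(5):
            fb = make_fieldbook(seed=seed)
            an = arcbd.arcbd_anova(fb, "Y1", "T1")
            tbl = an.table.set_index("source")
            df = fb.to_frame().dropna(subset=["T1"])
            y = df["T1"].to_numpy(float)
            total = ((y - y.mean()) ** 2).sum()
            assert (tbl.loc["Genotypes (ignoring blocks)", "SS"]
                    + tbl.loc["Block (eliminating genotypes)", "SS"]
                    + tbl.loc["Residuals", "SS"]) == pytest.approx(total)

    def test_single_check_rejected(self):
        fb = make_fieldbook(checks=("C1",))
        with pytest.raises(ValueError, match="residual"):
            arcbd.arcbd_anova(fb, "Y1", "T1")

    def test_simulated_genetic_signal_flagged(self, default_sim):
        """Plant height in a default simulated trial: genotype MS far above
        residual MS, highly significant."""
        fb, _ = default_sim
        an = arcbd.arcbd_anova(fb, "2024", "PH")
        tbl = an.table.set_index("source")
        assert tbl.loc["Genotypes: tests", "MS"] > 3 * an.ms_residual
        assert tbl.loc["Genotypes: tests", "sig"] == "**"


class TestPrecision:
    def test_zero_mse(self):
        fb = make_fieldbook(value_fn=lambda y, b, g, t, rng:
                            {"C1": 4.0, "C2": 8.0, "C3": 9.0}.get(g, 10.0))
        ps = arcbd.precision_stats(arcbd.arcbd_anova(fb, "Y1", "T1"))
        assert ps.CV_pct == pytest.approx(0)
        assert ps.CD == pytest.approx(0)

    def test_direct_cv_formula(self):
        fb = make_fieldbook(seed=2)
        an = arcbd.arcbd_anova(fb, "Y1", "T1")
        ps = arcbd.precision_stats(an)
        assert ps.CV_pct == pytest.approx(100 * np.sqrt(an.ms_residual) / an.grand_mean)

    def test_sed_and_cd_against_quantile_oracle(self):
        fb = make_fieldbook(n_blocks=14, checks=("C1", "C2", "C3"), n_tests=30, seed=3)
        an = arcbd.arcbd_anova(fb, "Y1", "T1")
        ps = arcbd.precision_stats(an)
        mse = an.ms_residual
        sed = np.sqrt(2 * mse * (1 + 1 / 3))
        assert ps.sed["test_test_diff_block"] == pytest.approx(sed)
        t = stats.t.ppf(0.975, an.df_residual)
        assert ps.CD == pytest.approx(t * sed)
        assert ps.SEm == pytest.approx(np.sqrt(mse / 14))
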