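"""The inference battery against independent oracles.

scipy.stats, statsmodels and pingouin act as external references; the
implementations under test share no code with them.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sstats

from thetamod.stats import (
    DegenerateInputError,
    InsufficientDataError,
    ancova_group,
    one_sample_t,
    p_from_statistic,
    partial_corr,
    pearson,
    rm_anova_2x2x2,
    steiger_dependent,
)


class TestPKernel:
    def test_t_and_f_match_scipy_on_grid(self):
        for t in (0.5, 0.93, 2.4, 5.0):
            for df in (5, 33, 100):
                assert p_from_statistic("t", t, df) == pytest.approx(
                    2 * sstats.t.sf(t, df), abs=1e-12
                )
        for f in (0.2, 3.6, 11.14):
            for dfs in ((1, 35), (2, 34), (3, 50)):
                assert p_from_statistic("F", f, dfs) == pytest.approx(
                    sstats.f.sf(f, *dfs), abs=1e-12
                )

    def test_f1_equals_two_sided_t_identity(self):
        for f in (0.3, 1.7, 7.02, 24.0):
            for d in (5, 20, 35):
                assert p_from_statistic("F", f, (1, d)) == pytest.approx(
                    p_from_statistic("t", np.sqrt(f), d), rel=1e-12
                )

    def test_z_tails(self):
        assert p_from_statistic("z", 0.0, None, sided="one") == pytest.approx(0.5)
        assert p_from_statistic("z", 2.35, None, sided="one") == pytest.approx(
            0.00939, abs=5e-6
        )
        assert p_from_statistic("z", -1.0, None, sided="two") == pytest.approx(
            p_from_statistic("z", 1.0, None, sided="two")
        )

    def test_negative_t_one_sided_is_upper_tail(self):
        assert p_from_statistic("t", -2.0, 10, sided="one") == pytest.approx(
            sstats.t.sf(-2.0, 10), rel=1e-9
        )

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            p_from_statistic("t", 1.0, 0)


class TestPearson:
    def test_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        res = pearson(x, y)
        ref_r, ref_p = sstats.pearsonr(x, y)
        assert res.r == pytest.approx(ref_r, abs=1e-12)
        assert res.p == pytest.approx(ref_p, abs=1e-12)
        assert res.df == 28

    def test_collinear_bypasses_t(self, rng):
        x = rng.normal(size=10)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_monotone_in_r_and_n(self):
        def p_of(r, n):
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            return p_from_statistic("t", t, n - 2)

        assert p_of(0.5, 30) < p_of(0.3, 30) < p_of(0.1, 30)
        assert p_of(0.3, 100) < p_of(0.3, 30) < p_of(0.3, 10)

    def test_nan_pairs_dropped(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        x[3] = np.nan
        res = pearson(x, y)
        assert res.n == 19

    def test_degenerate_and_small_n(self, rng):
        with pytest.raises(DegenerateInputError):
            pearson(np.ones(10), rng.normal(size=10))
        with pytest.raises(InsufficientDataError):
            pearson(np.arange(3), np.arange(3))


class TestPartialCorr:
    def test_formula_equals_residualization(self, rng):
        x = rng.normal(size=25)
        z = rng.normal(size=25)
        y = 0.5 * x + 0.7 * z + rng.normal(size=25)
        res = partial_corr(x, y, z)
        design = np.column_stack([np.ones(25), z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 0.3 * x + 0.5 * z + rng.normal(size=40)
        res = partial_corr(x, y, z)
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                              x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_independent_covariate_leaves_r(self):
        rng = np.random.default_rng(99)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.45 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        plain = pearson(x, y).r
        partial = partial_corr(x, y, z).r
        assert partial == pytest.approx(plain, abs=0.02)

    def test_self_partialling_returns_zero(self, rng, caplog):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = partial_corr(x, y, x)
        assert res.r == 0.0 and res.p == 1.0

    def test_df_conventions(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        z = rng.normal(size=20)
        assert partial_corr(x, y, z).df == 17
        assert partial_corr(x, y, z, df_convention="n-2").df == 18

    def test_two_covariates_residualization(self, rng):
        x = rng.normal(size=30)
        z = rng.normal(size=(30, 2))
        y = 0.5 * x + z @ [0.3, -0.4] + rng.normal(size=30)
        res = partial_corr(x, y, z)
        design = np.column_stack([np.ones(30), z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
        assert res.df == 30 - 2 - 2


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        res = steiger_dependent(0.4, 0.4, 0.2, 50)
        assert res.z == pytest.approx(0.0)
        assert res.p_one_sided == pytest.approx(0.5)

    def test_antisymmetric(self):
        a = steiger_dependent(0.5, 0.1, 0.3, 40)
        b = steiger_dependent(0.1, 0.5, 0.3, 40)
        assert a.z == pytest.approx(-b.z, rel=1e-12)

    def test_larger_gap_larger_z(self):
        z1 = steiger_dependent(0.5, 0.3, 0.2, 50).z
        z2 = steiger_dependent(0.6, 0.2, 0.2, 50).z
        assert z2 > z1 > 0

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            steiger_dependent(0.9, -0.9, 0.9, 30)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            steiger_dependent(1.2, 0.0, 0.0, 30)


class TestOneSampleT:
    def test_matches_scipy(self, rng):
        x = rng.normal(0.3, 1.0, 34)
        t, df, p = one_sample_t(x)
        ref = sstats.ttest_1samp(x, 0.0)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        assert df == 33

    def test_constant_at_mu0(self):
        t, df, p = one_sample_t(np.full(10, 2.0), mu0=2.0)
        assert t == 0.0 and p == 1.0

    def test_constant_elsewhere_degenerate(self):
        with pytest.raises(DegenerateInputError):
            one_sample_t(np.full(10, 2.0), mu0=0.0)

    def test_quadrature_oracle(self, rng):
        """p from the closed form vs numerical integration of the t density."""
        for _ in range(20):
            t = float(rng.uniform(0.1, 4.0))
            df = int(rng.integers(3, 80))
            dens = lambda u: sstats.t.pdf(u, df)  # noqa: E731
            tail, _ = integrate.quad(dens, t, np.inf)
            assert p_from_statistic("t", t, df) == pytest.approx(2 * tail, abs=1e-8)


def _rm_fixture(rng, n=10, effects=None):
    rows = []
    effects = effects or {}
    for s in range(n):
        base = rng.normal()
        for c in ("social", "nonsocial"):
            for h in (1, 2):
                for r in ("left", "right"):
                    val = base + rng.normal(0, 0.5)
                    val += effects.get("half", 0.0) * (h - 1)
                    val += effects.get("condition", 0.0) * (c == "social")
                    rows.append(dict(subject=f"S{s}", condition=c, half=h,
                                     region=r, value=val))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_statsmodels_anovarm(self, rng):
        sm = pytest.importorskip("statsmodels.stats.anova")
        df = _rm_fixture(rng, n=12, effects={"half": 0.4})
        mine = rm_anova_2x2x2(df)
        ref = sm.AnovaRM(df, "value", "subject",
                         within=["condition", "half", "region"]).fit().anova_table
        for _, row in mine.table.iterrows():
            key = row["effect"].replace(" x ", ":")
            assert row["F"] == pytest.approx(ref.loc[key, "F Value"], rel=1e-9)
            assert row["p"] == pytest.approx(ref.loc[key, "Pr > F"], abs=1e-9)

    def test_eta_identity(self, rng):
        mine = rm_anova_2x2x2(_rm_fixture(rng))
        for _, row in mine.table.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(
                row["F"] / (row["F"] + row["df2"]), rel=1e-12
            )

    def test_null_half_effect_is_zero(self, rng):
        df = _rm_fixture(rng, n=8)
        wide = df.pivot_table(index="subject", columns=["condition", "half", "region"],
                              values="value")
        for c in ("social", "nonsocial"):
            for r in ("left", "right"):
                wide[(c, 2, r)] = wide[(c, 1, r)]
        long = wide.stack(["condition", "half", "region"], future_stack=True)
        long = long.rename("value").reset_index()
        res = rm_anova_2x2x2(long)
        assert res.effect("half")["F"] == pytest.approx(0.0, abs=1e-20)

    def test_listwise_deletion(self, rng):
        df = _rm_fixture(rng, n=8)
        df = df[~((df["subject"] == "S0") & (df["half"] == 2))]
        res = rm_anova_2x2x2(df)
        assert res.n == 7

    def test_insufficient_n(self, rng):
        with pytest.raises(InsufficientDataError):
            rm_anova_2x2x2(_rm_fixture(rng, n=2))


class TestAncova:
    def test_matches_statsmodels_type3(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        sma = pytest.importorskip("statsmodels.api")
        g = np.repeat(["a", "b", "c"], 20)
        x = rng.normal(size=60)
        y = 1 + 0.5 * x + (g == "a") * 0.3 + rng.normal(size=60) * 0.5
        mine = ancova_group(y, x, g)
        fit = smf.ols("y ~ x * C(g, Sum)",
                      data=pd.DataFrame({"y": y, "x": x, "g": g})).fit()
        ref = sma.stats.anova_lm(fit, typ=3)
        pairs = {"predictor": "x", "group": "C(g, Sum)",
                 "predictor x group": "x:C(g, Sum)"}
        for eff, key in pairs.items():
            row = mine.effect(eff)
            assert row["F"] == pytest.approx(ref.loc[key, "F"], rel=1e-9)
            assert row["p"] == pytest.approx(ref.loc[key, "PR(>F)"], abs=1e-12)

    def test_covariate_term_included(self, rng):
        g = np.repeat(["a", "b"], 25)
        x = rng.normal(size=50)
        c = rng.normal(size=50)
        y = 0.5 * x + 0.8 * c + rng.normal(size=50)
        res = ancova_group(y, x, g, covariate=c)
        assert set(res.table["effect"]) == {"predictor", "group",
                                            "predictor x group", "covariate"}
        assert res.effect("covariate")["p"] < 0.01

    def test_exact_fit_guard(self):
        g = np.repeat(["a", "b"], 10)
        x = np.arange(20.0)
        y = 2.0 * x + 1.0
        res = ancova_group(y, x, g)
        assert np.isinf(res.effect("predictor")["F"])
        assert res.effect("predictor")["p"] == 0.0

    def test_aliased_term_named(self, rng):
        g = np.repeat(["a", "b"], 15)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        with pytest.raises(DegenerateInputError, match="aliased"):
            ancova_group(y, x, g, covariate=x)

    def test_group_correlations_reported(self, rng):
        g = np.repeat(["a", "b"], 30)
        x = rng.normal(size=60)
        y = np.where(g == "a", 0.9, 0.05) * x + rng.normal(size=60) * 0.4
        res = ancova_group(y, x, g)
        assert res.extra["group_r"]["a"].r > res.extra["group_r"]["b"].r

    def test_interaction_type1_error_calibrated(self):
        """Equal true slopes: the interaction test rejects at ~alpha."""
        rng = np.random.default_rng(7)
        alpha_hits = 0
        reps = 1000
        for _ in range(reps):
            g = np.repeat(["a", "b", "c"], 100)
            x = rng.normal(size=300)
            y = 0.4 * x + rng.normal(size=300)
            res = ancova_group(y, x, g)
            alpha_hits += res.effect("predictor x group")["p"] < 0.05
        assert 0.03 <= alpha_hits / reps <= 0.07
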