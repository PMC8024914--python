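"""Rankit transform, partial correlation, Steiger's z, VIF, moderation, ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from noveltybandit.clinstats import (
    group_ancova,
    moderation_jn,
    partial_correlation,
    rankit_transform,
    steiger_z,
    vif,
    zscore,
)


class TestRankit:
    def test_four_distinct_values_match_normal_quantiles(self):
        out = rankit_transform(np.array([7.0, 1.0, 3.0, 5.0]))
        expected = stats.norm.ppf([7 / 8, 1 / 8, 3 / 8, 5 / 8])
        assert np.allclose(out, expected, atol=1e-12)

    def test_antisymmetry_under_order_reversal(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=25)
        fwd = rankit_transform(x)
        rev = rankit_transform(-x)
        assert np.allclose(fwd, -rev, atol=1e-12)

    def test_order_preserving_with_ties_and_nan(self):
        x = np.array([3.0, 1.0, np.nan, 3.0, 0.0])
        out = rankit_transform(x)
        assert np.isnan(out[2])
        assert out[1] > out[4]
        assert out[0] == out[3] > out[1]
        ranks = stats.rankdata(x[np.isfinite(x)], method="average")
        assert ranks.sum() == 4 * 5 / 2

    def test_single_value_and_constant_warn_zero(self):
        with pytest.warns(UserWarning):
            assert rankit_transform(np.array([7.0]))[0] == 0.0
        with pytest.warns(UserWarning):
            assert np.allclose(rankit_transform(np.full(5, 2.0)), 0.0)

    def test_blom_variant_differs(self):
        x = np.arange(10.0)
        assert not np.allclose(rankit_transform(x), rankit_transform(x, variant="blom"))

    def test_zscore_after_rankit_standardized(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=200)
        z = zscore(rankit_transform(x))
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=1) - 1) < 1e-8


class TestPartialCorrelation:
    def test_matches_closed_form_from_correlation_matrix(self):
        rng = np.random.default_rng(3)
        n = 200
        z = rng.standard_normal(n)
        x = 0.6 * z + rng.standard_normal(n)
        y = -0.4 * z + 0.3 * x + rng.standard_normal(n)
        r, df, p = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(closed, abs=1e-10)
        assert df == n - 3

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        n = 120
        frame = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "y": rng.standard_normal(n),
                "c1": rng.standard_normal(n),
                "c2": rng.standard_normal(n),
            }
        )
        frame["y"] += 0.5 * frame["x"] + 0.3 * frame["c1"]
        r, df, p = partial_correlation(
            frame["x"].to_numpy(), frame["y"].to_numpy(), frame[["c1", "c2"]].to_numpy()
        )
        ref = pingouin.partial_corr(frame, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_identity_gives_unit_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        c = rng.standard_normal(50)
        r, _, p = partial_correlation(x, x.copy(), c)
        assert r == pytest.approx(1.0)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        c = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_z(0.4, 0.4, 0.3, 100)
        assert z == 0.0
        assert p == 1.0

    def test_antisymmetric_in_swapped_correlations(self):
        z1, _ = steiger_z(0.51, 0.56, 0.49, 128)
        z2, _ = steiger_z(0.56, 0.51, 0.49, 128)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_close_dependent_correlations_not_significant(self):
        """|z| < 1.96 for r12=.51, r13=.56, r23=.49 at n=128, and a bootstrap
        confidence interval for the difference covers zero."""
        z, p = steiger_z(0.51, 0.56, 0.49, 128)
        assert abs(z) < 1.96
        assert p > 0.05
        # bootstrap oracle over resampled trivariate normals with that structure
        R = np.array([[1.0, 0.51, 0.56], [0.51, 1.0, 0.49], [0.56, 0.49, 1.0]])
        L = np.linalg.cholesky(R)
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(1000):
            X = rng.standard_normal((128, 3)) @ L.T
            C = np.corrcoef(X.T)
            diffs.append(C[0, 1] - C[0, 2])
        lo, hi = np.quantile(diffs, [0.025, 0.975])
        assert lo < 0 < hi

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(1.0, 0.5, 0.3, 50)


class TestVIF:
    def test_orthogonal_columns_unit_vif(self):
        rng = np.random.default_rng(8)
        # columns orthogonal to each other and to the intercept
        Q, _ = np.linalg.qr(np.column_stack([np.ones(100), rng.standard_normal((100, 3))]))
        out = vif(Q[:, 1:])
        assert np.allclose(out, 1.0, atol=1e-8)

    def test_two_columns_closed_form(self):
        rng = np.random.default_rng(9)
        n = 5000
        z = rng.standard_normal(n)
        r_target = 0.49
        x1 = z
        x2 = r_target * z + np.sqrt(1 - r_target**2) * rng.standard_normal(n)
        out = vif(np.column_stack([x1, x2]))
        r = np.corrcoef(x1, x2)[0, 1]
        expected = 1 / (1 - r**2)
        assert np.allclose(out, expected, atol=1e-8)
        assert out[0] == pytest.approx(1.316, abs=0.05)

    def test_perfect_collinearity_infinite(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(50)
        out = vif(np.column_stack([x, 2 * x, rng.standard_normal(50)]))
        assert np.isinf(out[0]) and np.isinf(out[1])


class TestModerationJN:
    @staticmethod
    def _crossover(rng, n=128, b=0.5):
        m = rng.uniform(-2, 2, n)
        x = rng.standard_normal(n)
        y = b * (-m) * x + rng.standard_normal(n) * 0.5
        return y, x, m

    def test_boundaries_match_grid_scan_oracle(self):
        rng = np.random.default_rng(11)
        y, x, m = self._crossover(rng)
        res = moderation_jn(y, x, m)
        assert len(res.boundaries) == 2
        grid = np.linspace(m.min() - 1, m.max() + 1, 4001)
        pvals = np.array([res.simple_slope(mv)[3] for mv in grid])
        sig = pvals < 0.05
        crossings = grid[np.flatnonzero(np.diff(sig.astype(int)) != 0)]
        assert len(crossings) == 2
        for found, scanned in zip(sorted(res.boundaries), sorted(crossings)):
            assert found == pytest.approx(scanned, abs=0.01)

    def test_pvalue_crosses_alpha_at_boundary(self):
        rng = np.random.default_rng(12)
        y, x, m = self._crossover(rng)
        res = moderation_jn(y, x, m)
        for b in res.boundaries:
            assert res.simple_slope(b)[3] == pytest.approx(0.05, abs=1e-6)
            inner = res.simple_slope(b - 1e-4)[3]
            outer = res.simple_slope(b + 1e-4)[3]
            assert (inner - 0.05) * (outer - 0.05) < 0

    def test_moderator_rescaling_equivariance(self):
        rng = np.random.default_rng(13)
        y, x, m = self._crossover(rng)
        res1 = moderation_jn(y, x, m)
        res2 = moderation_jn(y, x, 2 * m)
        assert np.allclose(sorted(res2.boundaries), [2 * b for b in sorted(res1.boundaries)],
                           atol=1e-8)

    def test_zero_interaction_no_finite_boundary(self):
        rng = np.random.default_rng(14)
        n = 400
        x = rng.standard_normal(n)
        m = rng.standard_normal(n)
        y = 0.8 * x + rng.standard_normal(n) * 0.3
        res = moderation_jn(y, x, m)
        # strong constant slope: significant everywhere within the data range
        if res.boundaries:
            assert all(abs(b) > np.abs(m).max() for b in res.boundaries)
        else:
            assert res.whole_range == "significant"

    def test_covariates_accepted(self):
        rng = np.random.default_rng(15)
        y, x, m = self._crossover(rng)
        cov = rng.standard_normal((128, 2))
        res = moderation_jn(y, x, m, covariates=cov)
        assert "cov0" in res.params.index and "cov1" in res.params.index


class TestGroupAncova:
    @staticmethod
    def _cohort(rng, n=128, audit_explore_effect=0.0, rho=0.49):
        """Null or planted cohort at the statistical layer: per-condition
        betas with a shared subject effect; the planted AUDIT effect loads
        on explore betas only, as a per-SD slope of the explore-minus-non-
        explore noise scale.  ``rho`` sets the AUDIT-CUDIT correlation
        (0 makes the planted slope the exact partial standardized effect)."""
        audit = rng.standard_normal(n)
        cudit = rho * audit + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        np_z = rng.standard_normal(n)
        sex = (rng.random(n) < 0.6).astype(float)
        base = rng.standard_normal(n)
        be = base + audit_explore_effect * np.sqrt(2) * audit + rng.standard_normal(n)
        bn = base + rng.standard_normal(n)
        return pd.DataFrame(
            {
                "audit_rankit_z": audit,
                "cudit_z": cudit,
                "np_z": np_z,
                "sex": sex,
                "roi_beta_explore": be,
                "roi_beta_nonexplore": bn,
            }
        )

    def test_null_type_one_error_calibrated(self):
        """Decision-interaction rejection rate ~5% under the null (1000 seeds)."""
        rng = np.random.default_rng(16)
        n_seeds = 1000
        rejections = 0
        for _ in range(n_seeds):
            out = group_ancova(self._cohort(rng))
            row = out[(out.term == "audit_rankit_z_x_decision")]
            rejections += int(row.p.iloc[0] < 0.05)
        rate = rejections / n_seeds
        mc_se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rate - 0.05) < 2.5 * mc_se

    def test_planted_audit_decision_effect_detected(self):
        """>=80% power at a standardized decision-interaction slope of 0.3."""
        rng = np.random.default_rng(17)
        hits = 0
        n_seeds = 50
        for _ in range(n_seeds):
            out = group_ancova(self._cohort(rng, audit_explore_effect=-0.3, rho=0.0))
            row = out[(out.term == "audit_rankit_z_x_decision")]
            hits += int(row.p.iloc[0] < 0.05)
        assert hits >= 0.8 * n_seeds

    def test_identical_betas_kill_decision_effects(self):
        rng = np.random.default_rng(18)
        below = 0
        n_seeds = 60
        for _ in range(n_seeds):
            cohort = self._cohort(rng)
            cohort["roi_beta_nonexplore"] = cohort["roi_beta_explore"]
            out = group_ancova(cohort)
            dec = out[out.effect == "decision_interaction"]
            below += int((dec.p > 0.05).all())
        assert below >= 0.7 * n_seeds

    def test_matches_statsmodels_reimplementation(self):
        """F statistics agree with an independent statsmodels OLS, including
        after duplicating every subject (df algebra check)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(19)
        cohort = self._cohort(rng, audit_explore_effect=-0.4)

        def oracle(frame):
            X = frame[["audit_rankit_z", "cudit_z", "np_z", "sex"]].copy()
            X["audit_rankit_z_x_np_z"] = frame.audit_rankit_z * frame.np_z
            X["cudit_z_x_np_z"] = frame.cudit_z * frame.np_z
            y = (frame.roi_beta_explore - frame.roi_beta_nonexplore).to_numpy()
            fit = sm.OLS(y, sm.add_constant(X)).fit()
            return fit.tvalues.drop("const") ** 2

        for frame in (cohort, pd.concat([cohort, cohort], ignore_index=True)):
            out = group_ancova(frame)
            ref = oracle(frame)
            dec = out[out.effect == "decision_interaction"].set_index("term")
            for name, f_ref in ref.items():
                assert dec.loc[f"{name}_x_decision", "F"] == pytest.approx(f_ref, rel=1e-8)

    def test_missing_betas_excluded_listwise(self):
        rng = np.random.default_rng(20)
        cohort = self._cohort(rng)
        cohort.loc[:4, "roi_beta_explore"] = np.nan
        out = group_ancova(cohort)
        assert out.attrs["n_excluded"] == 5
        assert out.attrs["n_used"] == len(cohort) - 5
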