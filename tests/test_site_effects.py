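"""Site-effect battery against independent oracles and known limits."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg, stats

from idprel import (
    GeneratorConfig,
    SiteEffectModel,
    SphericityResult,
    apply_gg,
    default_travelling_heads_sessions,
    fdr_adjust,
    friedman_test,
    generate_travelling_heads,
    mauchly_test,
    rm_anova,
    shapiro_residuals,
    site_effect_scan,
    specs_for_icc,
)
from conftest import make_matrix, make_table

INT_4X3 = np.array(
    [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 3.0, 3.0], [4.0, 5.0, 9.0]]
)


def brute_force_anova(y):
    """Sums of squares straight from the definition, by explicit loops."""
    n, k = y.shape
    grand = sum(y[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(y[i]) / k for i in range(n)]
    col = [sum(y[i][j] for i in range(n)) / n for j in range(k)]
    ss_subj = k * sum((r - grand) ** 2 for r in row)
    ss_sess = n * sum((c - grand) ** 2 for c in col)
    ss_err = sum(
        (y[i][j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    f = (ss_sess / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    eta_partial = ss_sess / (ss_sess + ss_err)
    return f, eta_partial, ss_subj, ss_sess, ss_err


class TestRmAnova:
    def test_integer_fixture_matches_brute_force(self):
        res = rm_anova(make_matrix(INT_4X3))
        f, eta, ss_subj, ss_sess, ss_err = brute_force_anova(INT_4X3)
        assert res.F == pytest.approx(f)
        assert res.eta_squared == pytest.approx(eta)
        assert res.ss_subjects == pytest.approx(ss_subj)
        assert res.ss_sessions == pytest.approx(ss_sess)
        assert res.ss_error == pytest.approx(ss_err)
        assert res.p_uncorrected == pytest.approx(
            stats.f.sf(f, 2, 6)
        )

    def test_matches_pingouin(self, fixture_8x4):
        res = rm_anova(fixture_8x4)
        import pandas as pd

        long = pd.DataFrame(
            {
                "y": fixture_8x4.values.ravel(),
                "subj": np.repeat(np.arange(8), 4),
                "sess": np.tile(np.arange(4), 8),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="sess", subject="subj", detailed=False)
        assert res.F == pytest.approx(ref["F"].iloc[0])
        assert res.p_uncorrected == pytest.approx(ref["p_unc"].iloc[0])

    def test_no_session_effect_gives_f_zero(self):
        y = np.tile(np.array([[1.0], [2.5], [4.0]]), (1, 4))
        res = rm_anova(make_matrix(y))
        assert res.F == 0.0 and res.p_reported == 1.0

    def test_additive_limit_is_degenerate(self):
        y = np.add.outer([1.0, 2.0, 5.0, 7.0], [0.0, 1.0, -2.0])
        res = rm_anova(make_matrix(y))
        assert res.degenerate
        assert np.isinf(res.F) and res.p_reported == 0.0

    @given(
        alpha=st.floats(0.1, 10.0),
        beta=st.floats(-50.0, 50.0),
        data_seed=st.integers(0, 10_000),
    )
    @settings(max_examples=25, deadline=None)
    def test_f_invariant_to_affine_and_subject_shifts(self, alpha, beta, data_seed):
        rng = np.random.default_rng(data_seed)
        y = rng.normal(size=(6, 3)) + np.array([0.0, 0.5, 1.0])
        base = rm_anova(make_matrix(y))
        shifted = y * alpha + beta + rng.normal(size=(6, 1))
        res = rm_anova(make_matrix(shifted))
        assert res.F == pytest.approx(base.F, rel=1e-9)
        assert res.eta_squared == pytest.approx(base.eta_squared, rel=1e-9)


class TestMauchly:
    def test_k2_forced_to_unity(self, rng):
        res = mauchly_test(make_matrix(rng.normal(size=(8, 2))))
        assert res.W == 1.0 and res.p == 1.0 and res.epsilon_gg == 1.0

    def test_eigenvalue_oracle(self, fixture_8x4):
        res = mauchly_test(fixture_8x4)
        y = fixture_8x4.values
        k = y.shape[1]
        # independent contrast basis: orthonormal complement of the 1-vector
        c = linalg.null_space(np.ones((1, k))).T
        lam = linalg.eigvalsh(c @ np.cov(y, rowvar=False) @ c.T)
        w = np.prod(lam) / (lam.sum() / (k - 1)) ** (k - 1)
        eps = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
        assert res.W == pytest.approx(w, rel=1e-10)
        assert res.epsilon_gg == pytest.approx(eps, rel=1e-10)

    def test_matches_pingouin(self, fixture_8x4):
        import pandas as pd

        wide = pd.DataFrame(fixture_8x4.values, columns=list("abcd"))
        res = mauchly_test(fixture_8x4)
        spher = pg.sphericity(wide)
        assert res.W == pytest.approx(spher.W)
        assert res.chi_square == pytest.approx(spher.chi2)
        # pingouin adds a second-order term to the chi-square p; the
        # first-order p agrees closely but not exactly
        assert res.p == pytest.approx(spher.pval, abs=0.01)
        assert res.epsilon_gg == pytest.approx(pg.epsilon(wide, correction="gg"))

    def test_singular_covariance_flagged(self, rng):
        res = mauchly_test(make_matrix(rng.normal(size=(3, 4))))
        assert not res.estimable
        assert res.epsilon_gg == pytest.approx(1.0 / 3.0)

    def test_null_rejection_rate_near_alpha_large_n(self):
        # compound-symmetric population: subject effect + iid noise
        rng = np.random.default_rng(31)
        n, k, reps = 60, 4, 400
        rejections = 0
        for _ in range(reps):
            y = rng.normal(0, 1, (n, 1)) + rng.normal(0, 1, (n, k))
            if mauchly_test(make_matrix(y)).p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_unequal_scales_violate_sphericity(self):
        rng = np.random.default_rng(17)
        n, reps = 40, 200
        scales = np.array([1.0, 1.0, 1.0, 3.0])
        hits = sum(
            mauchly_test(
                make_matrix(scales * (rng.normal(0, 1, (n, 1)) + rng.normal(0, 1, (n, 4))))
            ).p
            < 0.05
            for _ in range(reps)
        )
        assert hits / reps > 0.5


class TestGreenhouseGeisser:
    def test_not_applied_when_sphericity_holds(self, fixture_8x4):
        anova = rm_anova(fixture_8x4)
        spher = SphericityResult(W=0.9, chi_square=1.0, df=5, p=0.5, epsilon_gg=0.8)
        out = apply_gg(anova, spher)
        assert not out.gg_applied
        assert out.p_reported == anova.p_uncorrected

    def test_dfs_scaled_and_p_recomputed(self, fixture_8x4):
        anova = rm_anova(fixture_8x4)
        spher = SphericityResult(W=0.2, chi_square=12.0, df=5, p=0.01, epsilon_gg=0.6)
        out = apply_gg(anova, spher)
        assert out.gg_applied
        assert out.df_effect == pytest.approx(3 * 0.6)
        assert out.df_error == pytest.approx(21 * 0.6)
        assert out.F == anova.F
        assert out.p_reported == pytest.approx(stats.f.sf(anova.F, 1.8, 12.6))
        assert out.p_reported >= anova.p_uncorrected

    def test_epsilon_one_is_identity_on_p(self, fixture_8x4):
        anova = rm_anova(fixture_8x4)
        spher = SphericityResult(W=0.2, chi_square=12.0, df=5, p=0.01, epsilon_gg=1.0)
        out = apply_gg(anova, spher)
        assert out.gg_applied
        assert out.p_reported == pytest.approx(anova.p_uncorrected)


class TestFriedman:
    def test_identical_columns_q_zero(self):
        y = np.tile(np.array([[2.0], [3.0], [4.0]]), (1, 3))
        res = friedman_test(make_matrix(y))
        assert res.Q == 0.0 and res.p == 1.0

    def test_strictly_increasing_columns_reach_exhaustive_maximum(self):
        y = np.array([[1.0, 2.0, 3.0], [0.0, 5.0, 9.0], [2.0, 4.0, 8.0]])
        res = friedman_test(make_matrix(y))
        n, k = y.shape
        # exhaustive rank oracle: mid-ranks per subject, definition formula
        rank_sums = np.zeros(k)
        for row in y:
            rank_sums += stats.rankdata(row)
        q = 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3 * n * (k + 1)
        assert res.Q == pytest.approx(q)
        # maximal attainable Q for untied rankings is n(k-1)
        assert res.Q == pytest.approx(n * (k - 1))

    def test_matches_scipy_without_ties(self, rng):
        y = rng.normal(size=(10, 4))
        res = friedman_test(make_matrix(y))
        q_ref, p_ref = stats.friedmanchisquare(*(y[:, j] for j in range(4)))
        assert res.Q == pytest.approx(q_ref)
        assert res.p == pytest.approx(p_ref)

    def test_invariant_to_monotone_transform_where_anova_is_not(self, fixture_8x4):
        y = fixture_8x4.values
        transformed = make_matrix(np.exp(y / 2.0))
        assert friedman_test(fixture_8x4).Q == pytest.approx(
            friedman_test(transformed).Q
        )
        assert rm_anova(fixture_8x4).F != pytest.approx(rm_anova(transformed).F)

    def test_all_tied_rows(self):
        y = np.full((4, 3), 7.0)
        res = friedman_test(make_matrix(y))
        assert res.Q == 0.0 and res.p == 1.0

    def test_null_p_distribution_roughly_uniform(self):
        rng = np.random.default_rng(23)
        ps = [
            friedman_test(make_matrix(rng.normal(size=(12, 4)))).p for _ in range(300)
        ]
        # chi-square approximation is discrete-ish at n=12; coarse check only
        assert 0.3 < np.mean(np.array(ps) < 0.5) < 0.7


class TestShapiro:
    def test_residuals_all_equal_not_estimable(self):
        y = np.add.outer([1.0, 2.0, 3.0, 4.0], [0.0, 2.0, 5.0])
        res = shapiro_residuals(make_matrix(y))
        assert not res.estimable

    def test_matches_direct_shapiro_on_residuals(self, fixture_8x4):
        y = fixture_8x4.values
        resid = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
        stat_ref, p_ref = stats.shapiro(resid.ravel())
        res = shapiro_residuals(fixture_8x4)
        assert res.statistic == pytest.approx(stat_ref)
        assert res.p == pytest.approx(p_ref)

    def test_heavy_tailed_noise_detected_more_often_than_alpha(self):
        rng = np.random.default_rng(7)
        reps, hits = 200, 0
        for _ in range(reps):
            y = rng.normal(0, 1, (8, 1)) + rng.exponential(1.0, (8, 4))
            hits += shapiro_residuals(make_matrix(y)).p < 0.05
        assert hits / reps > 0.15


class TestFdr:
    def test_all_tiny_p_rejected(self):
        reject, p_adj = fdr_adjust([0.001] * 10, ["a"] * 10)
        assert reject.all()
        np.testing.assert_allclose(p_adj, 0.001)

    def test_step_up_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.2])
        reject, p_adj = fdr_adjust(p, q=0.05)
        # step-up enumeration: largest i with p_(i) <= i q / m
        m = len(p)
        order = np.argsort(p)
        thresh = [(i + 1) * 0.05 / m for i in range(m)]
        passing = [i for i in range(m) if p[order[i]] <= thresh[i]]
        expected = np.zeros(m, bool)
        if passing:
            expected[order[: max(passing) + 1]] = True
        np.testing.assert_array_equal(reject, expected)

    def test_within_class_differs_from_pooled(self):
        # one strong class and one weak class: pooled adjustment lets the
        # strong class drag the weak one over the line
        p = np.array([0.001, 0.001, 0.001, 0.001, 0.03, 0.2])
        pooled, _ = fdr_adjust(p, q=0.05)
        split, _ = fdr_adjust(p, ["a"] * 4 + ["b"] * 2, q=0.05)
        assert pooled[4]
        assert not split[4]

    def test_nan_passthrough(self):
        reject, p_adj = fdr_adjust([0.01, np.nan, 0.02], ["a", "a", "a"])
        assert not reject[1] and np.isnan(p_adj[1])


class TestScan:
    def test_offsets_concentrate_in_shifted_class(self):
        config = GeneratorConfig(
            n_subjects=8,
            sessions=default_travelling_heads_sessions(),
            idp_specs=specs_for_icc(30, 0.7, "null_class")
            + specs_for_icc(30, 0.7, "shifted_class", prefix="shift"),
            seed=42,
        )
        table = generate_travelling_heads(config)
        # inject strong per-session offsets into the shifted class only
        rec = table.records
        shift = rec["idp_name"].str.startswith("shift") & (rec["session_label"] == "KCL")
        rec.loc[shift, "value"] += 3.0
        scan = site_effect_scan(table)
        by_class = scan.groupby("class_label")["significant"].mean()
        assert by_class["shifted_class"] > 0.9
        assert by_class["null_class"] < 0.3

    def test_skipped_idps_reported_not_dropped(self, rng):
        values = rng.normal(size=(8, 4))
        bad = values.copy()
        bad[:6, 1] = np.nan
        table = make_table({"good": values, "bad": bad})
        scan = site_effect_scan(table)
        assert len(scan) == 2
        row = scan.set_index("idp_name").loc["bad"]
        assert bool(row["skipped"]) and "complete subjects" in row["skip_reason"]

    def test_ge_site_increases_mean_effect_rejections(self):
        config = GeneratorConfig(
            n_subjects=8,
            sessions=default_travelling_heads_sessions(ge_offset=1.5, ge_scale=1.5),
            idp_specs=specs_for_icc(40, 0.8, "volumes"),
            seed=13,
        )
        table = generate_travelling_heads(config)
        all_sites = site_effect_scan(table)
        siemens = site_effect_scan(table, sessions=table.subset_sessions("SIEMENS"))
        assert all_sites["significant"].sum() > siemens["significant"].sum()


def test_model_results_summary(fixture_8x4):
    res = SiteEffectModel(fixture_8x4).fit()
    text = res.summary()
    assert "RM-ANOVA" in text and "Mauchly" in text and "Friedman" in text


def test_type_one_error_rate_under_null():
    # per-test rejection of the session F under the null generator
    rng = np.random.default_rng(1234)
    reps, hits = 1000, 0
    for _ in range(reps):
        y = rng.normal(0, 1, (8, 1)) + rng.normal(0, 0.7, (8, 4))
        hits += rm_anova(make_matrix(y)).p_uncorrected < 0.05
    rate = hits / reps
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)
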