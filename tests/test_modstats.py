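import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissuespec import modstats


def make_expr(groups):
    """Genes x samples frame from {tissue: per-gene sample lists}."""
    columns = []
    data = []
    for tissue, block in groups.items():
        block = np.asarray(block, dtype=float)
        for j in range(block.shape[1]):
            columns.append(f"{tissue}_{j}")
        data.append(block)
    values = np.concatenate(data, axis=1)
    expr = pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(values.shape[0])], name="Name"),
        columns=columns,
    )
    design = pd.DataFrame(
        {
            "tissue": [c.rsplit("_", 1)[0] for c in columns],
            "donor": columns,
            "rin": 7.0,
        },
        index=expr.columns,
    )
    return expr, design


class TestFit:
    def test_group_means_and_zero_residual(self):
        expr, design = make_expr({"T1": [[0.0, 0.0]], "T2": [[2.0, 2.0]]})
        fit = modstats.fit_tissue_model(expr, design)
        np.testing.assert_allclose(fit.coefficients.loc["g0"], [0.0, 2.0])
        assert fit.s2["g0"] == 0.0

    def test_shift_equivariance(self):
        expr, design = make_expr(
            {"T1": [[1.0, 2.0, 3.0]], "T2": [[4.0, 6.0, 8.0]]}
        )
        fit = modstats.fit_tissue_model(expr, design)
        fit_shift = modstats.fit_tissue_model(expr + 5.0, design)
        np.testing.assert_allclose(
            fit_shift.coefficients.to_numpy(), fit.coefficients.to_numpy() + 5.0
        )
        np.testing.assert_allclose(fit_shift.s2, fit.s2)

    def test_pooled_variance_matches_hand_computation(self):
        # groups (1,2,3), (4,6), (10,10,13): SS = 2 + 2 + 6 = 10, df = 8-3 = 5
        expr, design = make_expr(
            {"T1": [[1.0, 2.0, 3.0]], "T2": [[4.0, 6.0]], "T3": [[10.0, 10.0, 13.0]]}
        )
        fit = modstats.fit_tissue_model(expr, design)
        assert fit.df_residual == 5.0
        np.testing.assert_allclose(fit.s2["g0"], 2.0)

    def test_single_sample_tissue_rejected(self):
        expr, design = make_expr({"T1": [[1.0]], "T2": [[2.0, 3.0]]})
        with pytest.raises(ValueError, match="<2 samples"):
            modstats.fit_tissue_model(expr, design)


class TestEbayes:
    def test_identical_variances_give_infinite_prior_dof(self):
        prior = modstats.ebayes_shrink(np.full(100, 0.3), df=10)
        assert np.isinf(prior.d0)
        np.testing.assert_allclose(prior.s0_2, 0.3)
        np.testing.assert_allclose(prior.s2_post, 0.3)

    def test_zero_prior_dof_means_no_shrinkage(self):
        s2 = np.array([0.1, 0.2, 0.3, 0.4])
        prior = modstats.ebayes_shrink(s2, df=5, d0_override=0.0, s0_2_override=0.2)
        np.testing.assert_allclose(prior.s2_post, s2)

    def test_parameter_recovery_on_scaled_inverse_chi2_draws(self):
        # s2 ~ s0^2 * (chi2_d / d) * (d0 / chi2_d0): a scaled-F marginal
        rng = np.random.default_rng(11)
        d0_true, s0_true, df = 4.0, 0.05, 10
        n = 20000
        s2 = (
            s0_true
            * (rng.chisquare(df, n) / df)
            * (d0_true / rng.chisquare(d0_true, n))
        )
        prior = modstats.ebayes_shrink(s2, df=df)
        assert abs(prior.d0 - d0_true) < 1.0
        assert abs(prior.s0_2 - s0_true) / s0_true < 0.2

    def test_shrinkage_direction_and_bounds(self):
        rng = np.random.default_rng(3)
        s2 = pd.Series(0.05 * rng.chisquare(6, 500) / 6, index=range(500))
        prior = modstats.ebayes_shrink(s2, df=6)
        below = s2 < prior.s0_2
        assert (prior.s2_post[below] > s2[below]).all()
        assert (prior.s2_post[~below] <= s2[~below]).all()
        lo = np.minimum(s2, prior.s0_2)
        hi = np.maximum(s2, prior.s0_2)
        assert ((prior.s2_post >= lo - 1e-12) & (prior.s2_post <= hi + 1e-12)).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 3 genes"):
            modstats.ebayes_shrink(np.array([0.1, 0.2]), df=4)

    def test_trigamma_inverse_round_trips(self):
        from scipy.special import polygamma

        for y in (0.01, 0.5, 2.0, 37.0):
            x = polygamma(1, y)
            np.testing.assert_allclose(modstats.trigamma_inverse(x), y, rtol=1e-8)


class TestContrasts:
    def test_ordinary_pooled_t_recovered_with_zero_prior_dof(self):
        expr, design = make_expr(
            {"T1": [[1.0, 2.0, 3.0]], "T2": [[4.0, 6.0, 5.0]]}
        )
        fit = modstats.fit_tissue_model(expr, design)
        prior = modstats.ebayes_shrink(
            fit.s2, fit.df_residual, d0_override=0.0, s0_2_override=1.0
        )
        contrast = modstats.pairwise_contrasts(fit.tissues, "T1", ["T2"])
        tests = modstats.contrast_tests(fit, contrast, prior)
        t_ref, p_ref = stats.ttest_ind([1.0, 2.0, 3.0], [4.0, 6.0, 5.0])
        np.testing.assert_allclose(tests.t.iloc[0, 0], t_ref, atol=1e-10)
        np.testing.assert_allclose(tests.p.iloc[0, 0], p_ref, atol=1e-10)

    def test_zero_difference_noiseless_gives_t_zero_p_one(self):
        expr, design = make_expr(
            {"T1": [[2.0, 2.0]], "T2": [[2.0, 2.0]], "T3": [[5.0, 5.0]]}
        )
        fit = modstats.fit_tissue_model(expr, design)
        prior = modstats.ebayes_shrink(fit.s2, fit.df_residual)
        contrast = modstats.pairwise_contrasts(fit.tissues, "T1", ["T2", "T3"])
        tests = modstats.contrast_tests(fit, contrast, prior)
        assert tests.t.loc["g0", "T1-vs-T2"] == 0.0
        assert tests.p.loc["g0", "T1-vs-T2"] == 1.0
        assert np.isinf(tests.t.loc["g0", "T1-vs-T3"])
        assert tests.p.loc["g0", "T1-vs-T3"] == 0.0

    def test_single_contrast_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        expr, design = make_expr(
            {"T1": rng.normal(0, 1, (20, 4)), "T2": rng.normal(0.5, 1, (20, 4))}
        )
        fit = modstats.fit_tissue_model(expr, design)
        prior = modstats.ebayes_shrink(fit.s2, fit.df_residual)
        contrast = modstats.pairwise_contrasts(fit.tissues, "T1", ["T2"])
        tests = modstats.contrast_tests(fit, contrast, prior)
        np.testing.assert_allclose(
            tests.f.to_numpy(), tests.t.to_numpy()[:, 0] ** 2, rtol=1e-10
        )
        assert tests.df_numerator == 1

    def test_unknown_tissue_in_contrast_rejected(self):
        expr, design = make_expr({"T1": [[1.0, 2.0]], "T2": [[3.0, 4.0]]})
        fit = modstats.fit_tissue_model(expr, design)
        with pytest.raises(ValueError, match="unknown tissue"):
            modstats.pairwise_contrasts(fit.tissues, "T1", ["T9"])


def bh_step_up(p):
    """Brute-force Benjamini-Hochberg step-up, transcribed from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


class TestGlobalAdjust:
    def test_hand_worked_step_up(self):
        p = pd.DataFrame([[0.01, 0.02], [0.04, 0.05]], index=["g1", "g2"])
        adj = modstats.global_adjust(p)
        # sorted q-values: 0.04, 0.04, 0.0533, 0.05 -> step-up minima from the
        # top give (0.04, 0.04, 0.05, 0.05)
        np.testing.assert_allclose(adj.to_numpy(), [[0.04, 0.04], [0.05, 0.05]])

    def test_matches_brute_force_on_all_orderings(self):
        base = [0.01, 0.02, 0.2, 0.2, 0.5, 0.9]
        for perm in itertools.permutations(base):
            frame = pd.DataFrame(np.array(perm).reshape(2, 3))
            adj = modstats.global_adjust(frame)
            np.testing.assert_allclose(
                adj.to_numpy().ravel(), bh_step_up(list(perm)), atol=1e-12
            )

    def test_degenerate_inputs(self):
        ones = pd.DataFrame(np.ones((3, 2)))
        np.testing.assert_allclose(modstats.global_adjust(ones).to_numpy(), 1.0)
        single = pd.DataFrame([[0.37]])
        np.testing.assert_allclose(modstats.global_adjust(single).iloc[0, 0], 0.37)

    def test_nan_rejected_with_offender(self):
        frame = pd.DataFrame([[0.1, np.nan]], index=["gene7"], columns=["a", "b"])
        with pytest.raises(ValueError, match="gene7"):
            modstats.global_adjust(frame)

    def test_null_simulation_keeps_fdr_call_rate_nominal(self):
        rng = np.random.default_rng(21)
        expr, design = make_expr(
            {
                "T1": rng.normal(5, 1, (2000, 10)),
                "T2": rng.normal(5, 1, (2000, 10)),
                "T3": rng.normal(5, 1, (2000, 10)),
            }
        )
        fit = modstats.fit_tissue_model(expr, design)
        prior = modstats.ebayes_shrink(fit.s2, fit.df_residual)
        contrast = modstats.pairwise_contrasts(fit.tissues, "T1", ["T2", "T3"])
        tests = modstats.contrast_tests(fit, contrast, prior)
        fdr = modstats.global_adjust(tests.p)
        n_tests = fdr.size
        rate = (fdr.to_numpy() < 0.01).mean()
        se = np.sqrt(0.01 * 0.99 / n_tests)
        assert rate <= 0.01 + 3 * se
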