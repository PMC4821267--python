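"""Mixed-model fitting, information criteria and the bias regression."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sharksize.bias_model import (
    DEFAULT_MODEL_SET,
    LMMFit,
    ModelSpec,
    aicc,
    bic,
    comparison_frame,
    fit_lmm,
    ic_weights,
    ols_bias_line,
    r2_nakagawa,
    rank_models,
    spearman_screen,
)
from .conftest import small_lmm_dataset
from .oracles import grid_max_loglik


class TestModelSpec:
    def test_formula_round_trip(self):
        for formula in DEFAULT_MODEL_SET:
            assert ModelSpec.from_formula(formula).formula == formula

    def test_rejects_bad_formulas(self):
        with pytest.raises(ValueError):
            ModelSpec.from_formula("diff ~ TLN")  # no random intercept
        with pytest.raises(ValueError):
            ModelSpec.from_formula("len ~ TLN + (1|ID)")
        with pytest.raises(ValueError):
            ModelSpec(("TLN", "TLN"))
        with pytest.raises(ValueError):
            ModelSpec(("bogus",))

    def test_parameter_count_includes_two_variances(self):
        assert ModelSpec(()).k == 3
        assert ModelSpec(("TLN", "time")).k == 5


class TestInformationCriteria:
    def test_aicc_closed_form(self):
        assert aicc(-10, 2, 10) == pytest.approx(24 + 12 / 7)

    def test_aicc_approaches_aic_for_large_n(self):
        assert aicc(-10, 2, 10**9) == pytest.approx(24, abs=1e-6)

    def test_bic_closed_form(self):
        assert bic(0.0, 1, math.e**2) == pytest.approx(2.0)

    def test_aicc_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10, 4, 5)

    def test_aicc_correction_term_identity(self):
        for k, n in [(3, 20), (5, 123), (2, 10)]:
            assert aicc(-7.0, k, n) - (14.0 + 2 * k) == pytest.approx(
                2 * k * (k + 1) / (n - k - 1)
            )

    def test_weight_examples(self):
        assert ic_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])
        assert ic_weights([0.0, 2.0]) == pytest.approx(
            [1 / (1 + math.exp(-1)), math.exp(-1) / (1 + math.exp(-1))], abs=1e-4
        )

    def test_weights_reject_nonfinite(self):
        with pytest.raises(ValueError):
            ic_weights([1.0, math.inf])
        with pytest.raises(ValueError):
            ic_weights([])

    @given(
        st.lists(st.floats(-500, 500), min_size=1, max_size=8),
        st.floats(-1000, 1000),
    )
    def test_weights_normalised_and_shift_invariant(self, ics, shift):
        w = ic_weights(ics)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert ic_weights([v + shift for v in ics]) == pytest.approx(w, abs=1e-9)
        # monotone: smaller criterion, larger weight
        order = np.argsort(ics)
        assert np.all(np.diff(w[order]) <= 1e-12)


class TestSpearmanScreen:
    def table(self):
        return pd.DataFrame(
            {
                "tln_m": [1, 2, 3, 4.0],
                "time_of_day": [1, 3, 2, 4.0],
                "day": [4, 3, 2, 1],
                "previsual_m": [1.0, 1.0, 1.0, 1.0],
                "diff_m": [0.1] * 4,
                "individual_id": list("abcd"),
            }
        )

    def test_diagonal_is_one_and_matrix_symmetric(self):
        screen = spearman_screen(self.table(), predictors=("TLN", "time", "day"))
        m = screen.matrix
        assert np.allclose(np.diag(m), 1.0)
        assert m.loc["TLN", "day"] == m.loc["day", "TLN"]

    def test_perfect_reversal_is_minus_one_and_flagged(self):
        screen = spearman_screen(self.table(), predictors=("TLN", "day"))
        assert screen.matrix.loc["TLN", "day"] == pytest.approx(-1.0)
        assert screen.flagged == [("TLN", "day", pytest.approx(-1.0))]

    def test_hand_computed_rank_correlation(self):
        # x=(1,2,3,4), y=(1,3,2,4): d^2 = (0,1,1,0) -> rho = 1 - 6*2/(4*15) = 0.8
        screen = spearman_screen(self.table(), predictors=("TLN", "time"), threshold=0.9)
        assert screen.matrix.loc["TLN", "time"] == pytest.approx(0.8)
        assert not screen.flagged

    def test_constant_predictor_reported_undefined(self):
        screen = spearman_screen(self.table(), predictors=("TLN", "previsual"))
        assert ("TLN", "previsual") in screen.undefined
        assert np.isnan(screen.matrix.loc["TLN", "previsual"])


class TestFitLMM:
    def test_constant_response_boundary(self):
        table = pd.DataFrame(
            {"diff_m": 1.0, "individual_id": np.repeat(list("abcd"), 3)}
        )
        fit = fit_lmm(ModelSpec(()), table, "ML")
        assert fit.beta[0] == pytest.approx(1.0)
        assert fit.sigma2_id == pytest.approx(0.0, abs=1e-12)
        assert fit.sigma2_eps <= 1e-12  # boundary

    @pytest.mark.parametrize("criterion", ["ML", "REML"])
    def test_objective_beats_grid_oracle(self, criterion, small_lmm_datasets):
        for table in small_lmm_datasets:
            fit = fit_lmm(ModelSpec(("TLN",)), table, criterion)
            grid = grid_max_loglik(table, ("TLN",), reml=criterion == "REML")
            assert fit.loglik >= grid - 1e-4
            # the optimum can only exceed the grid by the grid's resolution
            assert fit.loglik == pytest.approx(grid, abs=0.01)

    def test_balanced_oneway_matches_anova_closed_form(self):
        rng = np.random.default_rng(8)
        a, m = 6, 4
        groups = np.repeat(np.arange(a), m)
        y = 5 + rng.normal(0, 0.9, a)[groups] + rng.normal(0, 0.7, a * m)
        table = pd.DataFrame({"diff_m": y, "individual_id": groups})
        fit = fit_lmm(ModelSpec(()), table, "REML")
        cell = y.reshape(a, m)
        msw = ((cell - cell.mean(1, keepdims=True)) ** 2).sum() / (a * (m - 1))
        msb = m * ((cell.mean(1) - y.mean()) ** 2).sum() / (a - 1)
        assert fit.sigma2_eps == pytest.approx(msw, rel=1e-6)
        assert fit.sigma2_id == pytest.approx((msb - msw) / m, rel=1e-6)

    def test_matches_independent_mixedlm_implementation(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        table = small_lmm_dataset(42, 8, 3)
        fit = fit_lmm(ModelSpec(("TLN",)), table, "ML")
        ref = smf.mixedlm("diff_m ~ tln_m", table, groups=table.individual_id).fit(
            reml=False
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)
        assert fit.beta == pytest.approx(ref.fe_params.values, abs=1e-5)
        assert fit.sigma2_eps == pytest.approx(ref.scale, rel=1e-4)

    def test_zero_ratio_reproduces_ols(self):
        table = small_lmm_dataset(7, 6, 3)
        fit = fit_lmm(ModelSpec(("TLN",)), table, "ML", fixed_ratio=0.0)
        X = np.column_stack([np.ones(len(table)), table["tln_m"]])
        beta_ols = np.linalg.lstsq(X, table["diff_m"], rcond=None)[0]
        assert fit.beta == pytest.approx(beta_ols, abs=1e-8)
        assert fit.sigma2_id == 0.0

    def test_all_singletons_unidentifiable(self):
        table = pd.DataFrame(
            {"diff_m": [1.0, 2, 3, 4], "individual_id": list("abcd")}
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_lmm(ModelSpec(()), table, "ML")

    def test_too_few_rows(self):
        table = pd.DataFrame(
            {"diff_m": [1.0, 2, 1], "tln_m": [4.0, 5, 6],
             "time_of_day": [10.0, 11, 12], "individual_id": ["a", "a", "b"]}
        )
        with pytest.raises(ValueError, match="fewer"):
            fit_lmm(ModelSpec(("TLN", "time")), table, "ML")


class TestNakagawaR2:
    def make_fit(self, sigma2_f, sigma2_id, sigma2_eps):
        s = math.sqrt(sigma2_f)
        return LMMFit(
            spec=ModelSpec(("TLN",)), beta=np.array([0.0, 1.0]),
            beta_names=("intercept", "TLN"), sigma2_id=sigma2_id,
            sigma2_eps=sigma2_eps, loglik=0.0, criterion_type="ML",
            n_obs=2, k=4, fixed_predictor=np.array([-s, s]),
        )

    def test_component_arithmetic_matches_survey_scale_fit(self):
        # components arranged as in the top-ranked survey model: ~43.2 / 68.3
        rm2, rc2 = r2_nakagawa(self.make_fit(0.527, 0.306, 0.387))
        assert rm2 == pytest.approx(0.432, abs=5e-4)
        assert rc2 == pytest.approx(0.683, abs=5e-4)

    def test_intercept_only_has_zero_marginal_r2(self, default_pairs):
        fit = fit_lmm(ModelSpec(()), default_pairs, "ML")
        rm2, rc2 = r2_nakagawa(fit)
        assert rm2 == pytest.approx(0.0, abs=1e-12)
        assert 0 <= rc2 <= 1

    def test_no_random_variance_equalises_r2(self):
        rm2, rc2 = r2_nakagawa(self.make_fit(0.5, 0.0, 0.4))
        assert rm2 == rc2

    @given(
        st.floats(0.0, 10.0), st.floats(0.0, 10.0), st.floats(1e-6, 10.0)
    )
    def test_r2_ordering_invariant(self, s_f, s_id, s_eps):
        rm2, rc2 = r2_nakagawa(self.make_fit(s_f, s_id, s_eps))
        assert 0 <= rm2 <= rc2 <= 1


class TestRankModels:
    def test_singleton_set_has_weight_one(self, default_pairs):
        rows = rank_models(["diff ~ TLN + (1|ID)"], default_pairs)
        assert rows[0].w_aicc == pytest.approx(1.0)
        assert rows[0].w_bic == pytest.approx(1.0)

    def test_identical_specs_share_weight(self, default_pairs):
        rows = rank_models(["diff ~ TLN + (1|ID)"] * 2, default_pairs)
        assert [r.w_aicc for r in rows] == pytest.approx([0.5, 0.5])

    def test_sorted_by_aicc_weight_and_weights_sum_to_one(self, default_pairs):
        rows = rank_models(table=default_pairs)
        weights = [r.w_aicc for r in rows]
        assert weights == sorted(weights, reverse=True)
        assert sum(weights) == pytest.approx(1.0)
        assert sum(r.w_bic for r in rows) == pytest.approx(1.0)
        for r in rows:
            assert r.rm2 <= r.rc2
        frame = comparison_frame(rows)
        assert list(frame.columns[:5]) == ["model", "wAICc", "wBIC", "Rm2", "Rc2"]

    def test_common_row_set_across_specs(self, default_pairs):
        # previsual is missing on first-of-day rows; every model must be
        # fitted on the same (global-complete) rows
        rows = rank_models(table=default_pairs)
        assert len({r.n_obs for r in rows}) == 1
        assert rows[0].n_obs == len(default_pairs.dropna(subset=["previsual_m"]))


class TestBiasLine:
    def test_exact_line_recovered(self):
        table = pd.DataFrame({"diff_m": [0.0, 1, 2], "tln_m": [0.0, 1, 2]})
        line = ols_bias_line(table)
        assert (line.slope, line.intercept, line.r2) == pytest.approx((1, 0, 1))

    def test_flat_response(self):
        table = pd.DataFrame({"diff_m": [1.0, 1, 1], "tln_m": [4.0, 5, 6]})
        line = ols_bias_line(table)
        assert line.slope == pytest.approx(0.0)
        assert line.r2 == pytest.approx(0.0)

    def test_constant_tln_rejected(self):
        table = pd.DataFrame({"diff_m": [1.0, 2, 3], "tln_m": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="constant"):
            ols_bias_line(table)

    def test_signed_variant_uses_signed_column(self, default_pairs):
        line = ols_bias_line(default_pairs, signed=True)
        assert line.slope > 0  # underestimation grows with size
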