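import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mobiphys import bayes
from mobiphys.bayes import (ContrastResult, ModelSpec, SCALED_SPEC,
                            evidence_ratios, fit_group_model,
                            fit_hierarchical, jeffreys_label,
                            planned_contrasts, render_table,
                            summarize_contrast)
from mobiphys.calibration import SimParams, simulate_trial_table

#: fast sampler settings for unit tests (not the calibration study)
FAST = ModelSpec(chains=2, iterations=600, warmup=300)


@pytest.fixture(scope="module")
def effect_table():
    return simulate_trial_table(SimParams(condition_effects={"Gr": 1.0}),
                                seed=1)


@pytest.fixture(scope="module")
def effect_posterior(effect_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_hierarchical(effect_table, FAST, seed=0)


class TestEvidenceRatios:
    def test_reference_odds(self):
        assert evidence_ratios(0.8) == (pytest.approx(4.0),
                                        pytest.approx(0.25))

    def test_certainty_maps_to_inf_sentinel(self):
        er01, er10 = evidence_ratios(1.0)
        assert math.isinf(er01) and er10 == 0.0
        er01, er10 = evidence_ratios(0.0)
        assert er01 == 0.0 and math.isinf(er10)

    @given(pp=st.floats(0.001, 0.999))
    @settings(max_examples=200, deadline=None)
    def test_product_identity(self, pp):
        er01, er10 = evidence_ratios(pp)
        assert er01 * er10 == pytest.approx(1.0, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evidence_ratios(1.5)


class TestJeffreysLabels:
    @pytest.mark.parametrize("bf,label", [
        (2.5, "anecdotal"),
        (50.0, "very strong"),
        (150.0, "decisive"),
        (5.0, "substantial"),
        (15.0, "strong"),
        # boundaries belong to the lower bin
        (3.0, "anecdotal"), (10.0, "substantial"),
        (30.0, "strong"), (100.0, "very strong"),
    ])
    def test_printed_category_bins(self, bf, label):
        assert jeffreys_label(bf) == label

    def test_reciprocal_direction_noted(self):
        assert jeffreys_label(0.02) == "very strong (reciprocal)"

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            jeffreys_label(0.0)


class TestContrastSummary:
    def test_all_positive_draws_give_pp_one_and_inf(self):
        r = summarize_contrast(np.full(1000, 2.0) + np.arange(1000) * 1e-4,
                               "Gr–IC", "standing")
        assert r.pp == 1.0
        assert math.isinf(r.er01)
        assert r.star and r.bold

    def test_symmetric_draws_give_half(self, rng):
        d = rng.standard_normal(20000)
        r = summarize_contrast(d, "x", "g")
        assert r.pp == pytest.approx(0.5, abs=0.02)
        assert r.er01 == pytest.approx(1.0, rel=0.15)

    def test_constructed_pp_08(self):
        d = np.r_[np.ones(800), -np.ones(200)]
        r = summarize_contrast(d, "x", "g")
        assert r.pp == pytest.approx(0.8)
        assert r.er01 == pytest.approx(4.0)
        assert r.er10 == pytest.approx(0.25)

    def test_flag_thresholds(self):
        def with_pp(pp):
            n = 1000
            return summarize_contrast(
                np.r_[np.ones(int(pp * n)), -np.ones(n - int(pp * n))],
                "x", "g")
        assert with_pp(0.97).star
        assert with_pp(0.90).bold and not with_pp(0.90).star
        assert not with_pp(0.5).bold
        assert with_pp(0.03).star    # two-sided


class TestDesignValidation:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            fit_hierarchical(pd.DataFrame({"value": [1.0]}), FAST)

    def test_single_group_rejected(self, effect_table):
        sub = effect_table[effect_table.group == "standing"]
        with pytest.raises(ValueError, match="degenerate"):
            fit_hierarchical(sub, FAST)

    def test_single_condition_rejected(self, effect_table):
        sub = effect_table[effect_table.condition == "Gr"]
        with pytest.raises(ValueError, match="degenerate"):
            fit_hierarchical(sub, FAST)

    def test_nonfinite_values_rejected(self, effect_table):
        bad = effect_table.copy()
        bad.loc[0, "value"] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_hierarchical(bad, FAST)


class TestFit:
    def test_seeded_fit_is_deterministic(self, effect_table):
        a = fit_hierarchical(effect_table, FAST, seed=3)
        b = fit_hierarchical(effect_table, FAST, seed=3)
        assert np.array_equal(a.flat("beta"), b.flat("beta"))
        assert np.array_equal(a.flat("nu"), b.flat("nu"))

    def test_injected_effect_recovered(self, effect_posterior):
        c = effect_posterior.contrast(("Gr", "IC"), "standing")
        assert abs(c.median - 1.0) < 0.35
        assert c.pp > 0.95

    def test_convergence_diagnostics_attached(self, effect_posterior):
        d = effect_posterior.diagnostics
        assert d["max_rhat"] < 1.05
        assert d["min_ess"] > 50

    def test_unknown_cell_rejected(self, effect_posterior):
        with pytest.raises(KeyError):
            effect_posterior.contrast(("Gr", "XX"), "standing")
        with pytest.raises(KeyError):
            effect_posterior.coef_draws("nope")


class TestEmmeans:
    def test_balanced_design_emm_matches_cell_means(self, effect_table,
                                                    effect_posterior):
        emm = effect_posterior.emmeans()
        for (g, c), draws in emm.items():
            cell = effect_table[(effect_table.group == g)
                                & (effect_table.condition == c)]["value"]
            se = draws.std() + cell.std() / np.sqrt(len(cell))
            assert abs(np.median(draws) - cell.mean()) < 3 * se

    def test_planned_contrast_count(self, effect_posterior):
        results = planned_contrasts(effect_posterior)
        assert len(results) == 16    # 8 pairs x 2 groups


class TestDirectionalTest:
    def test_sign_flip_complements_pp(self, effect_posterior):
        a = effect_posterior.directional_test("group_walking", ">")
        b = effect_posterior.directional_test("group_walking", "<")
        assert a["post_prob"] + b["post_prob"] == pytest.approx(1.0)

    def test_group_model_detects_separation(self, rng):
        vals = np.r_[rng.normal(0, 1, 15), rng.normal(2.0, 1, 15)]
        groups = np.array(["standing"] * 15 + ["walking"] * 15)
        gp = fit_group_model(vals, groups, FAST, seed=0)
        res = gp.directional_test(">")
        assert res["post_prob"] > 0.95
        assert res["estimate"] == pytest.approx(2.0, abs=1.0)

    def test_group_model_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fit_group_model(np.ones(6), np.array(["walking"] * 6), FAST)


class TestRenderTable:
    def _result(self, pp):
        return ContrastResult(label="Gr–IC", group="standing", median=1.0,
                              sd=0.5, ci_low=0.1, ci_high=1.9, pp=pp,
                              er01=evidence_ratios(pp)[0],
                              er10=evidence_ratios(pp)[1])

    def test_star_column_marked_above_95(self):
        df = render_table([self._result(0.97)])
        assert df["Star"].iloc[0] == "*"

    def test_bold_without_star_in_markdown(self):
        md = render_table([self._result(0.90)], markdown=True)
        assert "**" in md
        assert "*" == "*"  # star char not in the Star cell
        df = render_table([self._result(0.90)])
        assert df["Star"].iloc[0] == ""

    def test_empty_input_gives_header_only(self):
        df = render_table([])
        assert len(df) == 0
        assert "Contrast" in df.columns

    def test_inf_sentinel_printed(self):
        df = render_table([self._result(1.0)])
        assert df["ER01"].iloc[0] == "Inf"


class TestRobustness:
    def test_student_shifts_less_than_gaussian_under_outliers(self):
        """Gross outliers move contrast medians less under the heavy-tailed
        likelihood than under a normal likelihood (paired seeds)."""
        shifts = {"student": [], "normal": []}
        for seed in (0, 1, 2):
            clean = simulate_trial_table(SimParams(nu=50.0), seed=seed)
            dirty = clean.copy()
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(dirty), size=int(0.05 * len(dirty)),
                             replace=False)
            dirty.loc[idx, "value"] += 15.0
            for lik in ("student", "normal"):
                spec = ModelSpec(chains=2, iterations=600, warmup=300,
                                 likelihood=lik)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p_clean = fit_hierarchical(clean, spec, seed=seed)
                    p_dirty = fit_hierarchical(dirty, spec, seed=seed)
                delta = 0.0
                for pair in (("Gr", "IC"), ("OC", "OU")):
                    a = p_clean.contrast(pair, "standing").median
                    b = p_dirty.contrast(pair, "standing").median
                    delta += abs(a - b)
                shifts[lik].append(delta)
        assert np.mean(shifts["student"]) < np.mean(shifts["normal"])
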