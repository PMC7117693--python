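"""HOLR nested-model DIF detection and classification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import log_expit
from scipy.stats import chi2

from epicesdif import (DifEffect, classify_dif, detect_dif, fit_nested_models,
                       generate_cohort, lrt, mcfadden_delta, reverse_items)
from epicesdif.dif import fit_logistic

# 8 observations, two groups, no separation: hand dataset for oracle checks
THETA8 = np.array([-1.5, -0.5, 0.5, 1.5, -1.5, -0.5, 0.5, 1.5])
Y8 = np.array([0, 1, 0, 1, 1, 0, 1, 1], dtype=float)
G8 = np.array(["A", "A", "A", "A", "B", "B", "B", "B"])


def grid_search_max_ll(X, y, rounds=7, steps=21, half_width=6.0):
    """Independent oracle: exhaustive grid search with iterative refinement
    for the logistic ML log-likelihood."""
    p = X.shape[1]
    center = np.zeros(p)
    best = -np.inf
    for _ in range(rounds):
        axes = [np.linspace(c - half_width, c + half_width, steps) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        B = np.stack([g.ravel() for g in mesh])  # p x M
        eta = X @ B
        ll = (y[:, None] * log_expit(eta) + (1 - y)[:, None] * log_expit(-eta)).sum(0)
        i = int(ll.argmax())
        best = float(ll[i])
        center = B[:, i]
        half_width = 2.5 * (2 * half_width / (steps - 1))
    return best


class TestLogisticEngine:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(150), rng.normal(size=(150, 2))])
        y = (rng.random(150) < 1 / (1 + np.exp(-(X @ [0.3, 1.0, -0.5])))).astype(float)
        ll, beta, stable = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert stable
        assert ll == pytest.approx(ref.llf, abs=1e-8)
        assert np.allclose(beta, ref.params, atol=1e-6)

    def test_separation_is_flagged(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = (np.arange(10) >= 5).astype(float)
        _, _, stable = fit_logistic(X, y)
        assert not stable


class TestNestedModels:
    def test_loglikelihoods_match_grid_search_oracle(self):
        fits = fit_nested_models(Y8, THETA8, G8)
        D = (G8 == "B").astype(float)
        designs = {
            fits.ll1: np.column_stack([np.ones(8), THETA8]),
            fits.ll2: np.column_stack([np.ones(8), THETA8, D]),
            fits.ll3: np.column_stack([np.ones(8), THETA8, D, THETA8 * D]),
        }
        for ll, X in designs.items():
            assert ll == pytest.approx(grid_search_max_ll(X, Y8), abs=1e-4)

    def test_nesting_order(self):
        fits = fit_nested_models(Y8, THETA8, G8)
        assert fits.ll1 <= fits.ll2 <= fits.ll3
        assert fits.ll_null <= fits.ll1

    def test_null_item_adds_nothing_at_large_n(self, small_sim):
        m, truth = generate_cohort(small_sim(n_per_group=3000, seed=13))
        m = reverse_items(m, [1, 5])
        fits = fit_nested_models(m.responses.iloc[:, 3],
                                 truth.theta.to_numpy(),
                                 m.groups["area"].to_numpy())
        assert 2 * (fits.ll2 - fits.ll1) < chi2.ppf(0.99, 1)

    def test_group_relabelling_invariance(self):
        fits = fit_nested_models(Y8, THETA8, G8)
        relabel = np.where(G8 == "A", "zeta", "alpha")  # flips the reference
        fits2 = fit_nested_models(Y8, THETA8, relabel)
        for attr in ("ll1", "ll2", "ll3", "ll_null"):
            assert getattr(fits, attr) == pytest.approx(getattr(fits2, attr), abs=1e-7)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fit_nested_models(Y8, THETA8, np.repeat("A", 8))


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        stat, p = lrt(-10.0, -10.0, 1)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_quantile_identity(self):
        _, p = lrt(-10.0, -10.0 + 6.635 / 2, 1)
        assert p == pytest.approx(0.01, abs=1e-4)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lrt(-5.0, -6.0, 1)


class TestMcFadden:
    def test_saturated_model_reaches_one(self):
        assert mcfadden_delta(-20.0, -20.0, 0.0) == pytest.approx(1.0)

    def test_equal_models_give_zero(self):
        assert mcfadden_delta(-20.0, -8.0, -8.0) == 0.0

    def test_matches_independent_fits(self):
        """Delta-R2 from the package equals the value recomputed from
        independently maximized statsmodels likelihoods."""
        rng = np.random.default_rng(21)
        n = 200
        th = rng.normal(size=n)
        g = rng.choice(["A", "B"], size=n)
        d = (g == "B").astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + th + 0.8 * d)))).astype(float)
        fits = fit_nested_models(y, th, g)
        delta = mcfadden_delta(fits.ll_null, fits.ll1, fits.ll2)

        X1 = np.column_stack([np.ones(n), th])
        X2 = np.column_stack([X1, d])
        ll_null = sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf
        ll1 = sm.Logit(y, X1).fit(disp=0).llf
        ll2 = sm.Logit(y, X2).fit(disp=0).llf
        ref = (1 - ll2 / ll_null) - (1 - ll1 / ll_null)
        assert delta == pytest.approx(ref, abs=1e-6)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            mcfadden_delta(0.0, -1.0, -0.5)


class TestClassification:
    @pytest.mark.parametrize("p21,p32,d21,d32,expected", [
        # every branch of the decision rule
        (0.5, 0.5, 0.1, 0.1, ("none", "not-assessed")),
        (0.001, 0.5, 0.01, 0.2, ("uniform", "negligible")),
        (0.001, 0.5, 0.035, 0.0, ("uniform", "moderate")),
        (0.001, 0.5, 0.05, 0.0, ("uniform", "moderate")),
        (0.001, 0.5, 0.07, 0.0, ("uniform", "important")),
        (0.001, 0.5, 0.2, 0.0, ("uniform", "important")),
        (0.5, 0.001, 0.2, 0.01, ("non-uniform", "negligible")),
        (0.5, 0.001, 0.0, 0.04, ("non-uniform", "moderate")),
        (0.001, 0.001, 0.0, 0.1, ("non-uniform", "important")),
        (0.02, 0.02, 0.1, 0.1, ("none", "not-assessed")),  # alpha = 0.01 boundary
    ])
    def test_decision_grid(self, p21, p32, d21, d32, expected):
        assert classify_dif(p21, p32, d21, d32) == expected

    @pytest.mark.parametrize("p21,p32,d21,d32,expected", [
        # worked cases from published area comparisons of the questionnaire
        (0.0005, 0.044, 0.172, 0.001, ("uniform", "important")),
        (0.016, 0.0005, 0.02, 0.116, ("non-uniform", "important")),
        (0.448, 0.3, 0.0, 0.0, ("none", "not-assessed")),
    ])
    def test_reference_cases(self, p21, p32, d21, d32, expected):
        assert classify_dif(p21, p32, d21, d32) == expected

    def test_alpha_and_bands_configurable(self):
        assert classify_dif(0.04, 0.5, 0.1, 0.0, alpha=0.05) == ("uniform", "important")
        assert classify_dif(0.001, 0.5, 0.05, 0.0, bands=(0.01, 0.04)) == (
            "uniform", "important")


class TestDetect:
    def test_uniform_dif_recovered(self, small_sim):
        cfg = small_sim(n_per_group=776, seed=42,
                        dif_spec={(6, "B"): DifEffect(delta_b=1.0)})
        m, _ = generate_cohort(cfg)
        res = detect_dif(reverse_items(m, [1, 5]), "area")
        row = res[res.item == "sports"].iloc[0]
        assert row.p_21 < 0.01
        assert row.dif_type == "uniform"
        assert row.flagged

    def test_slope_dif_recovered_as_non_uniform(self, small_sim):
        cfg = small_sim(n_per_group=776, seed=43,
                        dif_spec={(3, "B"): DifEffect(slope_mult=2.0)})
        m, _ = generate_cohort(cfg)
        res = detect_dif(reverse_items(m, [1, 5]), "area")
        row = res[res.item == "couple"].iloc[0]
        assert row.p_32 < 0.01
        assert row.dif_type == "non-uniform"

    def test_pairwise_comparisons_for_three_groups(self, preset_full):
        m, _ = preset_full
        res = detect_dif(m.drop_items(["material_support"]), "area")
        assert set(res.comparison) == {"Dijon vs FG", "Dijon vs FWI", "FG vs FWI"}
        assert len(res) == 30  # 10 items x 3 comparisons
        assert ((res.delta_r2_21 > -1e-8) & (res.delta_r2_32 > -1e-8)).all()
        assert res.p_21.between(0, 1).all() and res.p_32.between(0, 1).all()
        # magnitude is never assessed without a significant LRT
        assert (res.loc[res.dif_type == "none", "magnitude"] == "not-assessed").all()

    def test_purification_agrees_with_single_pass(self, small_sim):
        """With one DIF item among nine clean anchors, purified and
        unpurified McFadden gains agree closely."""
        cfg = small_sim(n_per_group=776, seed=44,
                        dif_spec={(6, "B"): DifEffect(delta_b=1.0)})
        m, _ = generate_cohort(cfg)
        ma = reverse_items(m, [1, 5])
        on = detect_dif(ma, "area", purify=True)
        off = detect_dif(ma, "area", purify=False)
        r = np.corrcoef(on.delta_r2_21, off.delta_r2_21)[0, 1]
        assert r > 0.95

    def test_unknown_covariate_and_single_group_errors(self, small_sim):
        m, _ = generate_cohort(small_sim(seed=1))
        with pytest.raises(KeyError):
            detect_dif(m, "planet")
        solo = m.subset(m.groups["area"] == "A")
        with pytest.raises(ValueError):
            detect_dif(solo, "area")
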