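"""Predictiveness curve: construction, TG/pTG, EF, threshold metrics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predcurve import (
    PredictivenessCurve,
    ScreeningDataset,
    build_curve,
    enrichment_factor,
    fit_logistic,
    flat_curve,
    partial_total_gain,
    ptg_top,
    step_curve,
    threshold_metrics,
    total_gain,
)
from conftest import random_overlapping_dataset


def fitted_curve(dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_logistic(dataset)
    return build_curve(model, dataset)


class TestBuildCurve:
    def test_zero_slope_gives_flat_curve_at_prevalence(self):
        ds = ScreeningDataset(tuple("abcde"), np.full(5, 1.0), [1, 0, 0, 1, 0])
        curve = fitted_curve(ds)
        np.testing.assert_allclose(curve.risk, ds.prevalence, atol=1e-12)

    def test_separated_fit_approximates_step(self):
        labels = (np.arange(200) < 20).astype(int)
        scores = np.where(labels, 10.0, 0.0) + np.linspace(0, 1, 200)
        ds = ScreeningDataset(tuple(f"c{i}" for i in range(200)), scores, labels)
        curve = fitted_curve(ds)
        p = ds.prevalence
        ref = step_curve(p, 200)
        # risk within clipping distance of the step everywhere
        assert np.abs(curve.risk - ref.risk).max() < 0.01

    def test_risk_nondecreasing_and_mean_equals_prevalence(self, overlapping_dataset):
        curve = fitted_curve(overlapping_dataset)
        assert (np.diff(curve.risk) >= -1e-12).all()
        assert curve.risk.mean() == pytest.approx(overlapping_dataset.prevalence, abs=1e-6)

    def test_ties_keep_input_order(self):
        ds = ScreeningDataset(("a", "b", "c", "d"), [1.0, 1.0, 1.0, 2.0], [0, 1, 0, 1])
        curve = fitted_curve(ds)
        np.testing.assert_array_equal(curve.order[:3], [0, 1, 2])


class TestTotalGain:
    def test_flat_curve_is_zero(self):
        for p in (0.027, 0.1):
            assert total_gain(flat_curve(p)) == 0.0

    @pytest.mark.parametrize("p", [0.01, 0.027, 0.1, 0.5])
    def test_step_curve_is_one(self, p):
        assert total_gain(step_curve(p)) == pytest.approx(1.0, abs=1e-12)

    def test_piecewise_hand_integration(self):
        # R = 0 below v = 0.5, R = 0.2 above, p = 0.1:
        # integral |R - p| = 0.5*0.1 + 0.5*0.1 = 0.1; TG = 0.1 / 0.18
        n = 1000
        v = np.arange(1, n + 1) / n
        risk = np.where(v <= 0.5, 0.0, 0.2)
        curve = PredictivenessCurve(prevalence=0.1, v=v, risk=risk)
        assert round(total_gain(curve), 4) == 0.5556

    def test_affine_score_rescaling_leaves_tg_unchanged(self, overlapping_dataset):
        tg0 = total_gain(fitted_curve(overlapping_dataset))
        rescaled = ScreeningDataset(
            overlapping_dataset.compound_ids,
            3.7 * overlapping_dataset.scores - 11.0,
            overlapping_dataset.labels,
        )
        assert total_gain(fitted_curve(rescaled)) == pytest.approx(tg0, abs=1e-9)


class TestPartialTotalGain:
    def test_flat_curve_zero_everywhere(self):
        curve = flat_curve(0.1, 500)
        for v in (0.0, 0.3, 0.9, 0.99):
            assert partial_total_gain(curve, v) == 0.0

    @pytest.mark.parametrize("p", [0.01, 0.027, 0.1, 0.5])
    def test_step_curve_is_one_at_step(self, p):
        assert partial_total_gain(step_curve(p), 1 - p) == pytest.approx(1.0, abs=1e-12)

    def test_identity_with_total_gain(self, overlapping_dataset):
        curve = fitted_curve(overlapping_dataset)
        p = curve.prevalence
        assert partial_total_gain(curve, 0.0) == pytest.approx(2 * p * total_gain(curve), abs=1e-12)

    def test_off_grid_cut_uses_fractional_overlap(self):
        # two-point curve: R = (0, 1), p = 0.5; pTG(0.75) integrates half
        # of the second interval: 0.25*0.5 / (0.25*0.5) = 1
        curve = PredictivenessCurve(prevalence=0.5, v=np.array([0.5, 1.0]), risk=np.array([0.0, 1.0]))
        assert partial_total_gain(curve, 0.75) == pytest.approx(1.0, abs=1e-12)

    def test_ptg_top_convention(self, overlapping_dataset):
        curve = fitted_curve(overlapping_dataset)
        assert ptg_top(curve, 2.0) == partial_total_gain(curve, 0.98)

    def test_domain_errors(self):
        curve = flat_curve(0.1, 100)
        with pytest.raises(ValueError):
            partial_total_gain(curve, 1.0)
        with pytest.raises(ValueError):
            ptg_top(curve, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_and_identity_on_random_fits(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_overlapping_dataset(rng, n_min=20, n_max=200)
        curve = fitted_curve(ds)
        p = curve.prevalence
        tg = total_gain(curve)
        assert 0.0 <= tg <= 1.0
        assert partial_total_gain(curve, 0.0) == pytest.approx(2 * p * tg, abs=1e-12)
        for v in (0.1, 0.5, 0.9):
            assert 0.0 <= partial_total_gain(curve, v) <= 1.0 + 1e-12


class TestEnrichmentFactor:
    def test_whole_dataset_is_one(self, overlapping_dataset):
        assert enrichment_factor(overlapping_dataset, 100.0) == pytest.approx(1.0)

    def test_all_active_top_reaches_inverse_prevalence(self):
        labels = (np.arange(100) < 5).astype(int)
        scores = np.where(labels, 10.0, 0.0) + np.linspace(0, 1, 100)
        ds = ScreeningDataset(
            tuple(f"c{i}" for i in range(100)), scores, labels, orientation="higher_is_better"
        )
        assert enrichment_factor(ds, 5.0) == pytest.approx(1 / ds.prevalence)

    def test_brute_force_count(self):
        # 100 compounds, 5 actives, exactly 2 in the top 10
        scores = -np.arange(100, dtype=float)  # rank = index
        labels = np.zeros(100, dtype=int)
        labels[[3, 7, 40, 60, 80]] = 1
        ds = ScreeningDataset(
            tuple(f"c{i}" for i in range(100)), scores, labels, orientation="higher_is_better"
        )
        assert enrichment_factor(ds, 10.0) == pytest.approx((2 / 10) / (5 / 100))

    def test_ceiling_selection(self):
        # top 1% of 150 compounds selects ceil(1.5) = 2
        scores = -np.arange(150, dtype=float)
        labels = np.zeros(150, dtype=int)
        labels[[0, 1, 100]] = 1
        ds = ScreeningDataset(
            tuple(f"c{i}" for i in range(150)), scores, labels, orientation="higher_is_better"
        )
        assert enrichment_factor(ds, 1.0) == pytest.approx((2 / 2) / (3 / 150))


class TestThresholdMetrics:
    def test_select_everything(self, overlapping_dataset):
        curve = fitted_curve(overlapping_dataset)
        rep = threshold_metrics(curve, overlapping_dataset, 0.0)
        assert rep.TPF == 1.0 and rep.FPF == 1.0
        assert rep.PPV == pytest.approx(overlapping_dataset.prevalence)
        assert np.isnan(rep.NPV)  # nothing rejected: undefined, not 0

    def test_perfectly_separated_toy(self):
        ds = ScreeningDataset(tuple("abcdef"), [6, 5, 4, 3, 2, 1], [1, 1, 1, 0, 0, 0])
        curve = fitted_curve(ds)
        rep = threshold_metrics(curve, ds, 0.5)
        assert (rep.TPF, rep.FPF, rep.PPV, rep.NPV) == (1.0, 0.0, 1.0, 1.0)
        assert np.isnan(rep.pAUC)  # no false positives above the cut

    def test_brute_force_ten_compound_toy(self):
        # top-3 selection contains 1 of the 2 actives
        scores = np.array([10.0, 9, 8, 7, 6, 5, 4, 3, 2, 1])
        labels = np.array([0, 1, 0, 0, 1, 0, 0, 0, 0, 0])
        ds = ScreeningDataset(tuple(f"c{i}" for i in range(10)), scores, labels)
        curve = fitted_curve(ds)
        rep = threshold_metrics(curve, ds, 0.7)
        assert rep.n_selected == 3 and rep.n_actives_selected == 1
        assert rep.TPF == pytest.approx(0.5)
        assert rep.PPV == pytest.approx(1 / 3)
        assert rep.EF == pytest.approx((1 / 3) / (2 / 10))
        assert rep.score_threshold == 8.0

    def test_counts_consistent(self, overlapping_dataset):
        curve = fitted_curve(overlapping_dataset)
        for v in (0.2, 0.5, 0.9):
            rep = threshold_metrics(curve, overlapping_dataset, v)
            assert rep.n_actives_selected <= rep.n_selected <= overlapping_dataset.n
            assert rep.TPF == rep.n_actives_selected / overlapping_dataset.n_actives
            assert rep.PPV == rep.n_actives_selected / rep.n_selected


def test_model_based_ppv_matches_empirical_on_calibrated_data():
    """On well-calibrated synthetic data the empirical PPV above v agrees
    with the model-based value (1/(1-v)) * int_v^1 R du."""
    from predcurve import BinormalSpec, generate_binormal

    spec = BinormalSpec(n_actives=271, decoys_per_active=36, mu_active=2.0, seed=21)
    ds = generate_binormal(spec)  # ~10,000 compounds
    curve = fitted_curve(ds)
    for v in (0.9, 0.97):
        rep = threshold_metrics(curve, ds, v)
        sel = curve.v > v
        model_ppv = curve.risk[sel].mean()
        assert rep.PPV == pytest.approx(model_ppv, abs=0.02)
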