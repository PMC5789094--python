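"""GUM budget tests: model equation, propagation, budget assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanocal as nc
from nanocal import gum


class TestModelEquation:
    def test_projection_without_corrections(self):
        assert nc.project_distance(100.0, 0.6) == pytest.approx(60.0)

    def test_projection_with_negative_correction(self):
        assert nc.project_distance(100.0, 0.6, [-0.01]) == pytest.approx(59.0)

    @given(st.floats(50, 200), st.floats(0.1, 2.0),
           st.lists(st.floats(-0.05, 0.05), max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_projection_matches_direct_evaluation(self, P, d, deltas):
        direct = P * (d + sum(deltas))
        assert nc.project_distance(P, d, deltas) == pytest.approx(
            direct, rel=1e-12, abs=1e-12)


class TestSingleRulerUncertainty:
    def test_pixel_size_exact_reduces_to_scaled_u_d(self):
        u = nc.combine_uncertainty_single(100.0, 0.0, 0.6, u_d=0.05)
        assert u == pytest.approx(100.0 * 0.05)

    def test_all_zero_uncertainties_give_zero(self):
        assert nc.combine_uncertainty_single(100.0, 0.0, 0.6) == 0.0

    def test_matches_monte_carlo_propagation(self):
        """First-order GUM combination agrees with 10^5-sample Monte-Carlo
        propagation of independent Gaussian inputs within 1%."""
        rng = np.random.default_rng(99)
        P0, u_P = 100.0, 0.5
        d0, u_d = 0.6, 0.05
        deltas = [0.0, 0.0]
        u_deltas = [0.009, 0.005]
        n = 100_000
        P = rng.normal(P0, u_P, n)
        d = rng.normal(d0, u_d, n)
        total = d + sum(rng.normal(dl, ul, n)
                        for dl, ul in zip(deltas, u_deltas))
        mc_sd = np.std(P * total, ddof=1)
        analytic = nc.combine_uncertainty_single(
            P0, u_P, d0, deltas, u_deltas, u_d)
        assert analytic == pytest.approx(mc_sd, rel=0.01)


class TestBudget:
    def test_reference_budget_contributions_and_expanded_u(self):
        """The worked 60 nm / n=1000 example budget: the seven contributions
        round to 0.3, 0.16, 0.01, 0.5, 0.1, 0.9, 0.5 nm and U = 2.4 nm."""
        b = nc.example_budget()
        shown = [round(c, 2) for c in b.contributions_nm]
        assert shown == [0.3, 0.16, 0.01, 0.5, 0.1, 0.9, 0.5]
        assert round(b.expanded_nm, 1) == 2.4
        assert b.expanded_nm == pytest.approx(2 * b.combined_nm)

    def test_single_systematic_input_passes_through(self):
        b = nc.build_budget([gum.InputQuantity("dd_env", u=0.005,
                                               kind="systematic")],
                            P=100.0, u_P=0.0, d_bar=0.6, n=1000, k=2.0)
        assert b.expanded_nm == pytest.approx(1.0)

    def test_quadrupling_n_halves_random_contributions_only(self):
        b1 = nc.example_budget(n=1000)
        b4 = nc.example_budget(n=4000)
        # rows: P, d_k (random), dd_fit (random), then 4 systematic
        assert b4.contributions_nm[1] == pytest.approx(
            b1.contributions_nm[1] / 2)
        assert b4.contributions_nm[2] == pytest.approx(
            b1.contributions_nm[2] / 2)
        assert np.allclose(b4.contributions_nm[3:], b1.contributions_nm[3:])
        assert np.allclose(b4.contributions_nm[0], b1.contributions_nm[0])

    @given(st.integers(0, 6), st.floats(1e-4, 0.05))
    @settings(max_examples=40, deadline=None)
    def test_increasing_any_input_increases_expanded_u(self, idx, bump):
        base = nc.example_budget()
        inputs = gum.standard_inputs()
        if idx == 0:
            b = nc.build_budget(inputs, P=100.0, u_P=0.5 + bump,
                                d_bar=0.6, n=1000)
        else:
            inputs[idx - 1].u += bump
            b = nc.build_budget(inputs, P=100.0, u_P=0.5, d_bar=0.6, n=1000)
        assert b.expanded_nm > base.expanded_nm

    def test_quadrature_bounds(self):
        b = nc.example_budget()
        k = b.k
        assert b.expanded_nm <= k * b.contributions_nm.sum() + 1e-12
        assert b.expanded_nm >= k * b.contributions_nm.max() - 1e-12

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(gum.BudgetError, match="negative"):
            gum.InputQuantity("bad", u=-0.1, kind="random")

    def test_unknown_kind_rejected(self):
        with pytest.raises(gum.BudgetError, match="kind"):
            gum.InputQuantity("bad", u=0.1, kind="sideways")

    def test_summary_displays_rounded_but_combines_unrounded(self):
        b = nc.example_budget()
        text = b.summary()
        assert "0.16" in text
        assert "U = 2.4 nm" in text
        exact = math.sqrt(np.sum(b.contributions_nm ** 2)) * 2
        assert b.expanded_nm == pytest.approx(exact, rel=1e-12)


class TestBudgetFromPipeline:
    def test_reproduces_reference_budget_from_equal_inputs(self):
        from nanocal.distfit import EnsembleDistanceResult
        from nanocal.pixelcal import PixelCalibration
        ens = EnsembleDistanceResult(
            mean_nm=60.0, sd_nm=5.0, se_nm=5.0 / math.sqrt(1000), n=1000,
            bin_edges=np.array([0.0]), counts=np.array([], dtype=int))
        cal = PixelCalibration(
            pixel_size=100.0, u_pixel_size=0.5,
            interval_pitches_px=np.array([100.0]),
            interval_pixel_sizes=np.array([100.0]),
            reference_lengths_nm=np.array([10_000.0]),
            reference_U_k2_nm=np.array([30.0]),
            u_reference=0.5, u_field_variation=0.0, u_line_fit=0.0,
            per_interval_reference_contrib=np.array([0.15]))
        b = nc.budget_from_pipeline(ens, cal, u_fp_nm=0.9, u_blink_nm=0.1,
                                    u_env_nm=0.5, u_model_nm=0.5,
                                    mean_u_fit_px=0.0035)
        assert [round(c, 2) for c in b.contributions_nm] == \
            [0.3, 0.16, 0.01, 0.5, 0.1, 0.9, 0.5]
        assert round(b.expanded_nm, 1) == 2.4

    def test_coverage_of_expanded_uncertainty(self):
        """Seeded repeats of the full simulate->measure->budget pipeline:
        the true distance lies inside mean +/- U in at least 95% of runs."""
        from nanocal.pixelcal import PixelCalibration
        cal = PixelCalibration(
            pixel_size=100.0, u_pixel_size=0.5,
            interval_pitches_px=np.array([100.0]),
            interval_pixel_sizes=np.array([100.0]),
            reference_lengths_nm=np.array([10_000.0]),
            reference_U_k2_nm=np.array([30.0]),
            u_reference=0.5, u_field_variation=0.0, u_line_fit=0.0,
            per_interval_reference_contrib=np.array([0.15]))
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = nc.SimConfig(seed=1000 + rep)
            table, _ = nc.generate_nanoruler_field(cfg, 40, (20_000., 20_000.))
            fits, _ = nc.measure_field(table)
            ens = nc.ensemble_stats(fits)
            b = nc.budget_from_pipeline(ens, cal, u_fp_nm=0.5, fits=fits)
            if abs(ens.mean_nm - 60.0) <= b.expanded_nm:
                hits += 1
        assert hits >= math.floor(0.95 * n_rep)

    def test_zero_systematics_shrink_as_one_over_sqrt_n(self):
        from nanocal.distfit import EnsembleDistanceResult
        from nanocal.pixelcal import PixelCalibration
        cal = PixelCalibration(
            pixel_size=100.0, u_pixel_size=0.0,
            interval_pitches_px=np.array([100.0]),
            interval_pixel_sizes=np.array([100.0]),
            reference_lengths_nm=np.array([10_000.0]),
            reference_U_k2_nm=np.array([0.0]),
            u_reference=0.0, u_field_variation=0.0, u_line_fit=0.0,
            per_interval_reference_contrib=np.array([0.0]))
        def U(n):
            ens = EnsembleDistanceResult(
                mean_nm=60.0, sd_nm=5.0, se_nm=5.0 / math.sqrt(n), n=n,
                bin_edges=np.array([0.0]), counts=np.array([], dtype=int))
            return nc.budget_from_pipeline(ens, cal, u_fp_nm=0.0,
                                           u_blink_nm=0.0, u_env_nm=0.0,
                                           u_model_nm=0.0).expanded_nm
        assert U(4000) == pytest.approx(U(1000) / 2, rel=1e-9)
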