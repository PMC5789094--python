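"""Simulator unit tests: kinetics, localization noise, merging, rendering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nanocal as nc
from nanocal import sim
from nanocal.config import ConfigError


def full_frame_events(n_frames, frame_time, site=0):
    """One bright event covering the whole acquisition."""
    return pd.DataFrame({"site": [site], "t_start": [0.0],
                         "t_end": [n_frames * frame_time]})


class TestBindingEvents:
    def test_zero_sites_yield_empty_event_list(self, default_config):
        ev = sim.simulate_binding_events(default_config, np.empty((0, 2)))
        assert len(ev) == 0

    def test_event_count_matches_renewal_process(self):
        """Over T = 1000 renewal periods, the number of binding events per
        site matches the T/(t_on+t_off) renewal rate; the scatter across
        independent sites bounds the Monte-Carlo error."""
        t_on, t_off = 0.5, 9.5
        n_periods = 1000
        cfg = nc.SimConfig(t_on=t_on, t_off=t_off, frame_time=1.0,
                           n_frames=int(n_periods * (t_on + t_off)), seed=8)
        n_sites = 50
        ev = sim.simulate_binding_events(cfg, np.zeros((n_sites, 2)))
        counts = ev.groupby("site").size().to_numpy()
        expected = n_periods
        # renewal-count SD per site is ~sqrt(n_periods) for exponential dwells
        se_mean = math.sqrt(n_periods / n_sites)
        assert abs(counts.mean() - expected) < 5 * se_mean

    def test_on_fraction_matches_duty_cycle(self):
        t_on, t_off = 1.0, 9.0
        cfg = nc.SimConfig(t_on=t_on, t_off=t_off, frame_time=1.0,
                           n_frames=40_000, seed=9)
        ev = sim.simulate_binding_events(cfg, np.zeros((5, 2)))
        on_frac = (ev["t_end"] - ev["t_start"]).sum() / (5 * cfg.total_time)
        duty = t_on / (t_on + t_off)
        # MC error shrinks as 1/sqrt(total simulated periods)
        n_periods = 5 * cfg.total_time / (t_on + t_off)
        assert abs(on_frac - duty) < 5 * duty / math.sqrt(n_periods)

    def test_events_truncated_to_acquisition(self, default_config):
        ev = sim.simulate_binding_events(default_config, np.zeros((3, 2)))
        assert (ev["t_start"] >= 0).all()
        assert (ev["t_end"] <= default_config.total_time + 1e-9).all()
        assert (ev["t_end"] > ev["t_start"]).all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="t_on"):
            nc.SimConfig(t_on=-1.0)
        with pytest.raises(ConfigError, match="site_activity_prob"):
            nc.SimConfig(site_activity_prob=1.5)


class TestLocalizations:
    def test_noise_free_limit_hits_site_exactly(self):
        cfg = nc.SimConfig(photons_per_frame=math.inf, n_frames=100, seed=0)
        site = np.array([[123.4, 567.8]])
        ev = full_frame_events(cfg.n_frames, cfg.frame_time)
        df = sim.events_to_localizations(ev, cfg, site)
        assert len(df) == cfg.n_frames
        assert np.allclose(df["x_nm"], 123.4)
        assert np.allclose(df["y_nm"], 567.8)

    @pytest.mark.parametrize("photons", [100.0, 400.0, 1600.0])
    def test_localization_sd_follows_sigma_psf_over_sqrt_n(self, photons):
        """Empirical localization SD matches sigma_psf/sqrt(N) within 3
        Monte-Carlo standard errors of the SD."""
        cfg = nc.SimConfig(photons_per_frame=photons, sigma_psf=100.0,
                           n_frames=4000, frame_time=0.1, min_photons=10,
                           seed=13)
        site = np.array([[5000.0, 5000.0]])
        ev = full_frame_events(cfg.n_frames, cfg.frame_time)
        df = sim.events_to_localizations(ev, cfg, site)
        expected = 100.0 / math.sqrt(photons)
        for col, c0 in (("x_nm", 5000.0), ("y_nm", 5000.0)):
            emp = (df[col] - c0).std(ddof=1)
            se_sd = expected / math.sqrt(2 * len(df))
            # small upward allowance for Poisson variation of N around its mean
            assert abs(emp - expected) < 3 * se_sd + 0.01 * expected

    def test_simultaneous_close_sites_merge_at_midpoint(self):
        cfg = nc.SimConfig(photons_per_frame=math.inf, n_frames=1,
                           sigma_psf=100.0, seed=0)
        sites = np.array([[0.0, 0.0], [30.0, 0.0]])
        ev = pd.DataFrame({"site": [0, 1], "t_start": [0.0, 0.0],
                           "t_end": [0.1, 0.1]})
        df = sim.events_to_localizations(ev, cfg, sites)
        assert len(df) == 1
        assert df.loc[0, "source"] == "merged"
        assert df.loc[0, "x_nm"] == pytest.approx(15.0)
        assert df.loc[0, "y_nm"] == pytest.approx(0.0)

    def test_distant_simultaneous_sites_stay_separate(self):
        cfg = nc.SimConfig(photons_per_frame=math.inf, n_frames=1, seed=0)
        sites = np.array([[0.0, 0.0], [5000.0, 0.0]])
        ev = pd.DataFrame({"site": [0, 1], "t_start": [0.0, 0.0],
                           "t_end": [0.1, 0.1]})
        df = sim.events_to_localizations(ev, cfg, sites)
        assert len(df) == 2
        assert set(df["source"]) == {"site"}


class TestNanorulerField:
    def test_fixed_distance_truth(self):
        cfg = nc.SimConfig(true_distance_sd=0.0, seed=2)
        _, truth = nc.generate_nanoruler_field(cfg, 1, (5000.0, 5000.0))
        assert truth.distances[0] == cfg.true_distance_mean

    def test_every_localization_has_one_source_label(self, small_field):
        table, _ = small_field
        assert table.df["source"].isin(["site", "merged",
                                        "false_positive"]).all()

    def test_field_too_small_raises(self):
        cfg = nc.SimConfig(seed=0)
        with pytest.raises(ConfigError):
            nc.generate_nanoruler_field(cfg, 500, (2000.0, 2000.0))

    def test_determinism_byte_identical_serialization(self, tmp_path):
        from nanocal import io as nio
        cfg = nc.SimConfig(seed=77)
        for name in ("a.csv", "b.csv"):
            table, _ = nc.generate_nanoruler_field(cfg, 10, (10_000., 10_000.))
            nio.write_localizations(table, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_existing_rulers_stable_under_n_rulers_change(self):
        """Per-ruler substreams: adding rulers must not reshuffle ruler 0."""
        cfg = nc.SimConfig(seed=5)
        t1, _ = nc.generate_nanoruler_field(cfg, 2, (20_000., 20_000.))
        t2, _ = nc.generate_nanoruler_field(cfg, 6, (20_000., 20_000.))
        a = t1.df[t1.df.ruler == 0].reset_index(drop=True)
        b = t2.df[t2.df.ruler == 0].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestMicrometreImage:
    def test_noiseless_centers_exact(self):
        img, truth = sim.generate_micrometre_image(noise=0.0, edge_blur_nm=0.0)
        # rendered profile is symmetric around each configured centre
        from nanocal.pixelcal import locate_lines
        centers = locate_lines(img)
        assert np.allclose(centers, truth["centers_px"], atol=1e-6)

    def test_pitch_in_pixels_is_pitch_over_pixel_size(self):
        img, truth = sim.generate_micrometre_image(
            pitch_nm=10_000.0, pixel_size=100.0, noise=0.0, edge_blur_nm=0.0)
        assert np.allclose(np.diff(truth["centers_px"]), 100.0)

    def test_distortion_scales_interval_scatter(self):
        _, truth = sim.generate_micrometre_image(distortion=0.005, noise=0.0)
        assert np.std(truth["interval_scale"]) == pytest.approx(0.005)


class TestBeadsRenderDesign:
    def test_identity_transform_zero_noise_pairs_identical(self):
        g, r = sim.generate_bead_pairs(15, nc.ChannelTransform.identity(),
                                       0.0, seed=3)
        assert np.array_equal(g, r)

    def test_pure_shift_recovered_by_solver(self):
        t = nc.ChannelTransform.shift(90.0, -30.0)
        g, r = sim.generate_bead_pairs(12, t, 0.0, seed=4)
        sol, rms = nc.solve_channel_transform(g, r)
        assert np.allclose(sol.coefficients(), [1, 0, 90.0, 0, 1, -30.0],
                           atol=1e-9)
        assert rms < 1e-9

    def test_three_noiseless_beads_exact_recovery(self):
        t = nc.ChannelTransform(a=1.001, b=0.002, c=50.0,
                                d=-0.001, e=0.999, f=20.0)
        green = np.array([[0.0, 0.0], [1000.0, 100.0], [300.0, 2000.0]])
        red = t.apply(green)
        sol, _ = nc.solve_channel_transform(green, red)
        assert np.allclose(sol.coefficients(), t.coefficients(), atol=1e-9)

    def test_render_single_localization_sums_to_one(self, make_one=None):
        from .conftest import make_table
        table = make_table([[55.0, 25.0]], field_size=(100.0, 100.0))
        img = nc.render_sr_image(table, bin_nm=10.0)
        assert img.sum() == 1
        assert img[2, 5] == 1

    def test_bin_boundary_goes_to_higher_bin(self):
        from .conftest import make_table
        table = make_table([[20.0, 0.0]], field_size=(100.0, 100.0))
        img = nc.render_sr_image(table, bin_nm=10.0)
        assert img[0, 2] == 1  # not bin 1

    def test_uniform_table_passes_chi_square_uniformity(self):
        from .conftest import make_table
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 1000.0, size=(20_000, 2))
        img = nc.render_sr_image(make_table(pts, field_size=(1000., 1000.)),
                                 bin_nm=100.0)
        chi2, p = stats.chisquare(img.ravel())
        assert p > 0.01

    @pytest.mark.parametrize("helices,bases,expected", [
        (0, 100, 34.0),
        (10, 0, 30.0),
        (3, 40, math.hypot(9.0, 13.6)),   # 16.308...
    ])
    def test_design_distance(self, helices, bases, expected):
        assert nc.design_distance(helices, bases) == pytest.approx(expected)
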