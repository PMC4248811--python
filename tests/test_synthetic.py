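"""Generator physics: amplitudes, count rates, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from ribbonflux import correlation as corr
from ribbonflux import synthetic as syn


def fast_config(seed=0, **kw):
    """Fast species (tau_d = 2 ms) at desk scale: 2 s of 50 us bins."""
    sp = syn.SpeciesSpec(n_mean=5, D=5.0, brightness_g=1.0)
    defaults = dict(species=(sp,), dt=5e-5, duration=2.0, seed=seed)
    defaults.update(kw)
    return syn.FcsSimConfig(**defaults)


class TestFcsValidation:
    def test_empty_config_rejected_unless_allowed(self):
        with pytest.raises(ValueError, match="all-zero"):
            syn.FcsSimConfig(species=())

    def test_empty_config_gives_zero_traces_when_allowed(self):
        cfg = syn.FcsSimConfig(species=(), allow_empty=True, dt=1e-3,
                               duration=0.1)
        g, r, _ = syn.simulate_fcs_trace(cfg)
        assert not g.values.any() and not r.values.any()

    @pytest.mark.parametrize("bad", [dict(dt=0.0), dict(duration=-1.0)])
    def test_nonpositive_timing_rejected(self, bad):
        with pytest.raises(ValueError):
            fast_config(**bad)

    def test_box_must_cover_beam(self):
        with pytest.raises(ValueError, match="half-widths"):
            fast_config(box_half_widths=(0.3, 0.6, 3.0))

    def test_species_needs_a_bright_channel(self):
        with pytest.raises(ValueError, match="brightness"):
            syn.SpeciesSpec(n_mean=1, D=1.0)


@pytest.fixture(scope="module")
def batch():
    """Ten seeded fast-species runs shared across the physics checks."""
    out = []
    for seed in range(10):
        g, r, truth = syn.simulate_fcs_trace(fast_config(seed=seed))
        out.append((g, truth))
    return out


class TestFcsPhysics:
    def test_amplitude_number_relation(self, batch):
        """G(0+) ~= gamma / n_mean: the correlation amplitude is the
        reciprocal apparent molecule number (gamma = 1 convention)."""
        amps = []
        for g, truth in batch:
            cur = corr.autocorrelate(g, max_lag=0.05)
            fit = corr.fit_correlation(
                cur, init=corr.DiffusionModelParams(N=5, tau_d=2e-3))
            amps.append(1.0 / fit.N)
        amps = np.asarray(amps)
        n_eff = batch[0][1].species_table.n_eff.iloc[0]
        se = amps.std(ddof=1) / np.sqrt(len(amps))
        assert abs(amps.mean() - 1.0 / n_eff) < 3 * se

    def test_mean_count_rate_matches_monte_carlo_detection_average(self, batch):
        """Independent oracle: brute-force average of the detection weight
        over uniform positions in the box gives the expected counts/bin."""
        cfg = fast_config()
        rng = np.random.default_rng(987654)
        hw = np.asarray(cfg.box_half_widths)
        pos = rng.uniform(-hw, hw, size=(200000, 3))
        w = np.exp(-2 * (pos[:, 0]**2 + pos[:, 1]**2) / cfg.beam.r0**2
                   - 2 * pos[:, 2]**2 / cfg.beam.z**2)
        n_particles = batch[0][1].species_table.n_particles.iloc[0]
        expected = n_particles * 1.0 * w.mean()   # brightness_g = 1
        means = np.asarray([g.mean for g, _ in batch])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expected) < 3 * se

    def test_trace_mean_scales_with_n_mean(self):
        # seed-averaged: beam occupancy relaxes slowly along the optical
        # axis, so single-run means scatter by several percent
        means = []
        for n_mean in (2.0, 8.0):
            per_seed = []
            for seed in (11, 21, 31, 41):
                sp = syn.SpeciesSpec(n_mean=n_mean, D=5.0, brightness_g=1.0)
                cfg = fast_config(species=(sp,), duration=1.0, seed=seed)
                g, _, _ = syn.simulate_fcs_trace(cfg)
                per_seed.append(g.mean)
            means.append(np.mean(per_seed))
        assert means[1] / means[0] == pytest.approx(4.0, rel=0.15)

    def test_crosstalk_feeds_red_channel(self):
        cfg = fast_config(seed=5, crosstalk_q=0.25)
        g, r, _ = syn.simulate_fcs_trace(cfg)
        assert r.mean == pytest.approx(0.25 * g.mean, rel=0.1)
        cur = corr.crosscorrelate(g, r, max_lag=0.02)
        assert cur.g[:5].mean() > 0.05    # bleed-through cross-correlates

    def test_triplet_fraction_recovered_by_fit(self):
        sp = syn.SpeciesSpec(n_mean=5, D=5.0, brightness_g=2.0,
                             triplet_fraction=0.3, triplet_tau=3e-4)
        cfg = fast_config(species=(sp,), seed=3, duration=2.0)
        g, _, _ = syn.simulate_fcs_trace(cfg)
        cur = corr.autocorrelate(g, max_lag=0.05)
        fit = corr.fit_correlation(
            cur, init=corr.DiffusionModelParams(N=5, tau_d=2e-3, T=0.1,
                                                tau_t=1e-4),
            fixed=("s_ratio", "a", "gamma", "baseline"))
        assert 0.1 < fit.T < 0.5           # blinking component present
        assert fit.tau_t == pytest.approx(3e-4, rel=0.6)


class TestDeterminism:
    def test_fcs_same_seed_bit_identical(self):
        g1, r1, _ = syn.simulate_fcs_trace(fast_config(seed=9, duration=0.5))
        g2, r2, _ = syn.simulate_fcs_trace(fast_config(seed=9, duration=0.5))
        assert np.array_equal(g1.values, g2.values)
        assert np.array_equal(r1.values, r2.values)

    def test_fcs_different_seeds_differ(self):
        g1, _, _ = syn.simulate_fcs_trace(fast_config(seed=1, duration=0.5))
        g2, _, _ = syn.simulate_fcs_trace(fast_config(seed=2, duration=0.5))
        assert not np.array_equal(g1.values, g2.values)

    def test_movie_same_seed_bit_identical(self):
        cfg = syn.MovieSimConfig(seed=4)
        m1, _, _ = syn.simulate_tirf_movie(cfg)
        m2, _, _ = syn.simulate_tirf_movie(cfg)
        assert np.array_equal(m1.stack, m2.stack)

    def test_movie_different_seeds_differ(self):
        m1, _, _ = syn.simulate_tirf_movie(syn.MovieSimConfig(seed=4))
        m2, _, _ = syn.simulate_tirf_movie(syn.MovieSimConfig(seed=5))
        assert not np.array_equal(m1.stack, m2.stack)


class TestFrapGenerator:
    def test_noiseless_endpoints(self):
        tr = syn.simulate_frap_trace(tau=7.1, mobile_fraction=0.6,
                                     noise_sigma=0.0, dt=0.1, duration=40.0)
        assert tr.f[0] == 0.0
        assert tr.f[-1] == pytest.approx(0.6, abs=5e-3)   # ~5.6 tau elapsed

    def test_immobile_pool_gives_flat_zero(self):
        tr = syn.simulate_frap_trace(tau=5.0, mobile_fraction=0.0,
                                     noise_sigma=0.0, duration=20.0)
        assert not tr.f.any()

    def test_mobile_fraction_range_enforced(self):
        with pytest.raises(ValueError, match="mobile_fraction"):
            syn.simulate_frap_trace(tau=5.0, mobile_fraction=1.2)

    def test_duration_must_span_recovery(self):
        with pytest.raises(ValueError, match="duration"):
            syn.simulate_frap_trace(tau=10.0, mobile_fraction=0.5,
                                    duration=20.0)


class TestMovieGenerator:
    def test_zero_event_movie_matches_noise_model(self):
        cfg = syn.MovieSimConfig(
            seed=8, fusion=syn.FusionEventSpec(count=0),
            clathrin=syn.ClathrinEventSpec(count=0, loss_count=0))
        movie, _, truth = syn.simulate_tirf_movie(cfg)
        assert len(truth.events) == 0
        inside = movie.stack[:, 40:56, 40:56]
        sd = inside.std(axis=0).mean()
        assert sd == pytest.approx(truth.noise_sd, rel=0.05)

    def test_event_count_conservation(self):
        cfg = syn.MovieSimConfig(seed=2)
        _, _, truth = syn.simulate_tirf_movie(cfg)
        classes = truth.to_frame().event_class.value_counts()
        assert classes["fusion"] == 6
        assert classes["accumulation"] == 4
        assert classes["loss"] == 3
        assert len(truth.events) == 13

    def test_planted_distances_follow_radial_spec(self):
        cfg = syn.MovieSimConfig(seed=6)
        _, _, truth = syn.simulate_tirf_movie(cfg)
        df = truth.to_frame()
        fus = df[df.event_class == "fusion"].distance_um
        cla = df[df.event_class != "fusion"].distance_um
        assert abs(fus.mean() - 0.4) < 0.1
        assert abs(cla.mean() - 0.8) < 0.1

    def test_ribbon_outside_footprint_rejected(self):
        with pytest.raises(ValueError, match="footprint"):
            syn.simulate_tirf_movie(
                syn.MovieSimConfig(seed=0, ribbon_centers=((0.1, 0.1),)))

    def test_movie_must_cover_recovery(self):
        with pytest.raises(ValueError, match="recovery"):
            syn.MovieSimConfig(shape=(100, 96, 96))

    def test_loss_events_are_negative_going(self):
        cfg = syn.MovieSimConfig(seed=3)
        movie, _, truth = syn.simulate_tirf_movie(cfg)
        base = movie.stack[:20].mean(axis=0)
        for ev in truth.events:
            if ev.event_class != "loss":
                continue
            row = int(round(ev.y_um / cfg.pixel_size - 0.5))
            col = int(round(ev.x_um / cfg.pixel_size - 0.5))
            peak_win = movie.stack[35:80, row, col].mean()
            assert peak_win < base[row, col]


class TestGroundTruthRoundTrip:
    def test_movie_events_csv_round_trip(self, tmp_path):
        _, _, truth = syn.simulate_tirf_movie(syn.MovieSimConfig(seed=1))
        path = tmp_path / "gt.csv"
        truth.to_frame().to_csv(path, index=False)
        back = syn.MovieGroundTruth.events_from_frame(pd.read_csv(path))
        for a, b in zip(truth.events, back):
            assert a.event_class == b.event_class
            assert a.x_um == pytest.approx(b.x_um)
            assert a.distance_um == pytest.approx(b.distance_um)
            assert a.onset_frame == b.onset_frame

    def test_fcs_truth_csv_round_trip(self, tmp_path):
        _, _, truth = syn.simulate_fcs_trace(fast_config(seed=3, duration=0.2))
        path = tmp_path / "gt.csv"
        truth.to_frame().to_csv(path, index=False)
        back = syn.FcsGroundTruth.from_frame(pd.read_csv(path))
        assert back.seed == truth.seed
        assert back.dt == truth.dt
        for col in ("n_mean", "D", "brightness_g", "brightness_r",
                    "n_particles", "n_eff", "tau_d"):
            assert np.allclose(back.species_table[col],
                               truth.species_table[col])
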