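import numpy as np
import pandas as pd
import pytest

from mobiphys import synth
from mobiphys.design import Block, DesignSpec, FORWARD_ORDER
from mobiphys.synth import (EDAGenParams, EEGGenParams, GainRule,
                            SAMGenParams, bateman, bandlimited_noise,
                            generate_eda, generate_sam, generate_session,
                            trial_blocks)


class TestDeterminism:
    def test_same_seed_identical_session(self, short_design):
        a, _ = generate_session(short_design, "walking", seed=7)
        b, _ = generate_session(short_design, "walking", seed=7)
        assert np.array_equal(a.eeg.samples, b.eeg.samples)
        assert np.array_equal(a.eda.samples, b.eda.samples)
        assert a.sam.equals(b.sam)
        assert list(a.markers.labels) == list(b.markers.labels)

    def test_different_seed_differs(self, short_design):
        a, _ = generate_session(short_design, "walking", seed=7)
        b, _ = generate_session(short_design, "walking", seed=8)
        assert not np.array_equal(a.eeg.samples, b.eeg.samples)


def test_six_videos_of_printed_duration_and_order():
    design = DesignSpec(order="forward")
    sess, _ = generate_session(design, "standing", seed=3)
    from mobiphys.io import blocks_from_markers
    videos = [b for b in blocks_from_markers(sess.markers)
              if b.role == "video"]
    assert len(videos) == 6
    assert all(b.duration == pytest.approx(64.0) for b in videos)
    assert tuple(b.condition for b in videos) == FORWARD_ORDER


def test_montage_missing_gain_channel_rejected():
    with pytest.raises(ValueError, match="missing from montage"):
        EEGGenParams(montage=("Fz", "Cz"),
                     condition_gains=(GainRule("Gr", "alpha", ("F3",), 1.2),))


def test_nonpositive_gain_rejected():
    with pytest.raises(ValueError):
        GainRule("Gr", "alpha", ("F3",), 0.0)


class TestOscillatorCalibration:
    def test_single_oscillator_variance_follows_sinusoid_identity(self, rng):
        """Zero background, one 10 Hz-band oscillator of amplitude A:
        channel variance approximates A^2/2."""
        amp = 10.0
        params = EEGGenParams(montage=("Fz",), background_scale_uv=0.0,
                              sensor_noise_uv=0.0, line_noise_uv=0.0,
                              osc_amplitude_uv={"alpha": amp},
                              condition_gains=())
        blocks = [Block(role="baseline_reading", start=0.0, duration=120.0)]
        rec, _, _ = synth.generate_eeg(params, blocks, "standing", rng)
        assert rec.samples.var() == pytest.approx(amp ** 2 / 2, rel=0.1)

    def test_no_effect_gains_give_unit_video_isi_ratio(self, rng):
        params = EEGGenParams(montage=("Fz",), background_scale_uv=0.0,
                              sensor_noise_uv=0.0, line_noise_uv=0.0,
                              osc_amplitude_uv={"alpha": 4.0},
                              condition_gains=())
        rec, gt, _ = synth.generate_eeg(params, trial_blocks(20, "Gr"),
                                        "standing", rng)
        piv = gt[gt.band == "alpha"].pivot_table(
            index=["trial", "channel"], columns="role", values="power")
        ratio = (piv.video / piv.isi).mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_amplitude_gain_squares_into_power(self, rng):
        """A 1.2 amplitude gain must yield a ~1.44 video/ISI power ratio."""
        rules = (GainRule("Gr", "alpha", ("Fz",), 1.2),)
        params = EEGGenParams(montage=("Fz",), background_scale_uv=0.0,
                              sensor_noise_uv=0.0, line_noise_uv=0.0,
                              osc_amplitude_uv={"alpha": 4.0},
                              condition_gains=rules)
        rec, gt, _ = synth.generate_eeg(params, trial_blocks(40, "Gr"),
                                        "standing", rng)
        piv = gt[gt.band == "alpha"].pivot_table(
            index=["trial", "channel"], columns="role", values="power")
        ratios = piv.video / piv.isi
        se = ratios.std() / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.44) < 3 * se + 0.02

    def test_bandlimited_noise_unit_variance(self, rng):
        x = bandlimited_noise(200_000, 500.0, (8.0, 12.5), rng)
        assert x.var() == pytest.approx(1.0, rel=0.05)


class TestArtifacts:
    def test_walking_only_gets_gait_bursts(self, short_design):
        rngs = np.random.default_rng(5), np.random.default_rng(5)
        blocks = short_design.blocks("walking")
        _, _, segs_w = synth.generate_eeg(EEGGenParams(), blocks, "walking",
                                          rngs[0], fade_s=short_design.fade_s)
        _, _, segs_s = synth.generate_eeg(EEGGenParams(), blocks, "standing",
                                          rngs[1], fade_s=short_design.fade_s)
        assert len(segs_w) > 0
        assert segs_s == []

    def test_bursts_follow_step_cadence(self, short_session):
        _, gt = short_session
        onsets = np.array([s[0] for s in gt.artifact_segments])
        gaps = np.diff(onsets)
        cadence_gap = 1.0 / EEGGenParams().artifact.cadence_hz
        # most consecutive steps are one cadence period apart
        assert np.median(gaps[gaps < 2]) == pytest.approx(cadence_gap, rel=0.05)


class TestEDAGeneration:
    def test_zero_rate_flat_tonic_gives_constant_trace(self, rng):
        params = EDAGenParams(drift_scale_us=0.0, noise_sd_us=0.0,
                              scr_rate_per_min={"baseline": 0.0})
        blocks = [Block(role="baseline_reading", start=0.0, duration=60.0)]
        rec, ev, tonic, clean = generate_eda(params, blocks, "standing", rng)
        assert len(ev) == 0
        assert np.allclose(rec.samples, 2.0)

    def test_single_event_peak_equals_amplitude(self, rng):
        """Unit-maximum kernel: max(trace - tonic) matches the event size."""
        params = EDAGenParams(drift_scale_us=0.0, noise_sd_us=0.0,
                              scr_rate_per_min={"baseline": 0.5})
        blocks = [Block(role="baseline_reading", start=0.0, duration=240.0)]
        for seed in range(5):
            r = np.random.default_rng(seed)
            rec, ev, tonic, clean = generate_eda(params, blocks, "standing", r)
            if len(ev) == 1:
                peak = (clean - tonic).max()
                assert peak == pytest.approx(ev.amplitude_us.iloc[0], rel=0.01)
                return
        pytest.fail("no single-event realization found")

    def test_poisson_event_count_mean(self):
        """Rate 4/min over 60 s: mean count near 4 across 200 seeds."""
        params = EDAGenParams(scr_rate_per_min={"baseline": 4.0})
        blocks = [Block(role="baseline_reading", start=0.0, duration=60.0)]
        counts = []
        for seed in range(200):
            _, ev, _, _ = generate_eda(params, blocks, "standing",
                                       np.random.default_rng(seed))
            counts.append(len(ev))
        counts = np.asarray(counts)
        se = counts.std() / np.sqrt(len(counts))
        assert abs(counts.mean() - 4.0) < 3 * se

    def test_ground_truth_reconstructs_noiseless_trace(self, rng):
        params = EDAGenParams(noise_sd_us=0.0)
        blocks = [Block(role="baseline_reading", start=0.0, duration=120.0)]
        rec, ev, tonic, clean = generate_eda(params, blocks, "standing", rng)
        n = clean.size
        recon = tonic.copy()
        kt = np.arange(int(10 * params.tau1_s * params.rate)) / params.rate
        kernel = bateman(kt, params.tau1_s, params.tau2_s)
        for r in ev.itertuples():
            i0 = int(np.floor(r.time_s * params.rate))
            m = min(kernel.size, n - i0)
            recon[i0:i0 + m] += r.amplitude_us * kernel[:m]
        assert np.allclose(recon, clean, atol=1e-12)

    def test_conductance_nonnegative(self, short_session):
        session, _ = short_session
        assert (session.eda.samples >= 0).all()

    def test_walking_offset_raises_tonic(self, short_design, rng):
        blocks = short_design.blocks("standing")
        p = EDAGenParams(drift_scale_us=0.0, noise_sd_us=0.0)
        _, _, tonic_s, _ = generate_eda(p, blocks, "standing",
                                        np.random.default_rng(1))
        _, _, tonic_w, _ = generate_eda(p, blocks, "walking",
                                        np.random.default_rng(1))
        assert tonic_w.mean() - tonic_s.mean() == pytest.approx(
            p.walking_offset_us)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            EDAGenParams(tau1_s=1.0, tau2_s=1.0)
        with pytest.raises(ValueError):
            EDAGenParams(rate=8.0)


class TestSAM:
    def test_zero_noise_returns_latent_mean(self, rng):
        params = SAMGenParams(noise_sd=0.0)
        out = generate_sam([(1, "Gr")], params, rng)
        assert out.arousal.iloc[0] == round(params.latent_arousal["Gr"])

    def test_ratings_clamped_to_scale(self):
        params = SAMGenParams(latent_arousal={"Gr": 9.0}, noise_sd=5.0,
                              latent_valence={"Gr": 1.0})
        for seed in range(30):
            out = generate_sam([(1, "Gr")], params,
                               np.random.default_rng(seed))
            assert 1 <= out.arousal.iloc[0] <= 9
            assert 1 <= out.valence.iloc[0] <= 9

    def test_latent_ordering_preserved_in_sample_means(self):
        """Crowded conditions keep lower calmness ratings on average."""
        params = SAMGenParams()
        ar = {c: [] for c in ("Gr", "IC")}
        for seed in range(200):
            out = generate_sam([(1, "Gr"), (2, "IC")], params,
                               np.random.default_rng(seed))
            ar["Gr"].append(out.arousal.iloc[0])
            ar["IC"].append(out.arousal.iloc[1])
        assert np.mean(ar["Gr"]) > np.mean(ar["IC"])

    def test_latent_mean_outside_scale_rejected(self):
        with pytest.raises(ValueError):
            SAMGenParams(latent_arousal={"Gr": 11.0})


def test_ground_truth_band_power_complete(short_session):
    _, gt = short_session
    # 12 epochs x 27 channels x 3 bands
    assert len(gt.band_power) == 12 * 27 * 3
    assert (gt.band_power["power"] >= 0).all()
    assert set(gt.band_power["band"]) == {"theta", "alpha", "beta"}
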