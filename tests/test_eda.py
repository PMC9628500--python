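import warnings

import numpy as np
import pandas as pd
import pytest

from mobiphys import eda, synth
from mobiphys.design import Block, DesignSpec
from mobiphys.eda import (BatemanIRF, analyze_eda, deconvolve,
                          eda_trial_measures, optimize_tau, preprocess_eda,
                          reconvolve, split_tonic_phasic, _fft_convolve)
from mobiphys.io import Epoch, Recording

RATE = 16.0


def _irf(tau1=2.0, tau2=0.7):
    return BatemanIRF(tau1, tau2, RATE)


class TestBatemanIRF:
    def test_unit_maximum_and_nonnegative(self):
        k = _irf().kernel
        assert k.max() == pytest.approx(1.0)
        assert (k >= 0).all()

    def test_equal_or_nonpositive_taus_rejected(self):
        with pytest.raises(ValueError):
            BatemanIRF(1.0, 1.0, RATE)
        with pytest.raises(ValueError):
            BatemanIRF(-1.0, 0.5, RATE)


class TestPreprocess:
    def test_constant_input_preserved(self):
        rec = Recording(np.full((1, 128 * 64), 2.0), rate=128.0,
                        labels=("EDA",), unit="uS")
        out = preprocess_eda(rec)
        assert out.rate == 16.0
        assert np.allclose(out.samples, 2.0, atol=1e-6)

    def test_output_length_64s_at_16hz(self):
        rec = Recording(np.zeros((1, 128 * 64)), rate=128.0, labels=("EDA",))
        assert preprocess_eda(rec).n_samples == 1024

    def test_high_frequency_attenuated_more_than_low(self):
        t = np.arange(0, 64, 1 / 128)
        hi = Recording(np.sin(2 * np.pi * 7 * t)[None], 128.0, ("EDA",))
        lo = Recording(np.sin(2 * np.pi * 0.5 * t)[None], 128.0, ("EDA",))
        gain_hi = preprocess_eda(hi).samples.std()
        gain_lo = preprocess_eda(lo).samples.std()
        assert gain_hi < gain_lo

    def test_rate_below_16_rejected(self):
        rec = Recording(np.zeros((1, 100)), rate=8.0, labels=("EDA",))
        with pytest.raises(ValueError):
            preprocess_eda(rec)


class TestDeconvolve:
    def test_kernel_deconvolves_to_impulse_at_zero(self):
        irf = _irf()
        n = int(300 * RATE)
        sc = np.zeros(n)
        sc[:irf.kernel.size] = irf.kernel
        d = deconvolve(sc, irf)
        total = np.abs(d).sum()
        near0 = np.abs(d[:3]).sum() + np.abs(d[-2:]).sum()
        assert near0 / total >= 0.9

    def test_shifted_scaled_event_recovered(self):
        irf = _irf()
        n = int(300 * RATE)
        i0 = int(100 * RATE)
        sc = np.zeros(n)
        m = min(irf.kernel.size, n - i0)
        sc[i0:i0 + m] = 0.5 * irf.kernel[:m]
        d = deconvolve(sc, irf)
        assert abs(int(np.argmax(d)) - i0) <= 2
        mass = d[i0 - 8:i0 + 8].sum() / RATE
        assert mass == pytest.approx(0.5, rel=0.1)

    def test_reconvolution_round_trip_under_one_percent(self, rng):
        irf = _irf()
        n = int(600 * RATE)
        d_true = np.zeros(n)
        for _ in range(20):
            d_true[rng.integers(0, n - 200)] += 0.4 * RATE
        sc = 2.0 + _fft_convolve(d_true, irf.kernel, RATE)
        d = deconvolve(sc, irf)
        recon = reconvolve(d, irf)
        rmse = np.sqrt(np.mean((recon - sc) ** 2))
        assert rmse < 0.01 * np.ptp(sc)

    def test_kernel_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            deconvolve(np.zeros(10), _irf())


class TestSplitTonicPhasic:
    def test_zero_event_trace_has_tiny_phasic_driver(self, rng):
        params = synth.EDAGenParams(scr_rate_per_min={"baseline": 0.0},
                                    noise_sd_us=0.002)
        blocks = [Block(role="baseline_reading", start=0.0, duration=300.0)]
        rec, _, _, _ = synth.generate_eda(params, blocks, "standing", rng)
        comps = analyze_eda(rec, optimize=False, tau_init=(2.0, 0.7))
        assert np.sqrt(np.mean(comps.phasic_driver ** 2)) \
            < 0.05 * comps.tonic.mean()

    def test_single_event_tonic_recovered_away_from_event(self):
        irf = _irf()
        n = int(300 * RATE)
        i0 = int(150 * RATE)
        sc = np.full(n, 2.0)
        m = min(irf.kernel.size, n - i0)
        sc[i0:i0 + m] += 0.5 * irf.kernel[:m]
        d = deconvolve(sc, irf)
        comps = split_tonic_phasic(sc, d, irf)
        away = np.ones(n, dtype=bool)
        away[i0 - int(5 * RATE):i0 + int(30 * RATE)] = False
        assert np.abs(comps.tonic[away][8:-8] - 2.0).max() < 0.05

    def test_reconstruction_tonic_plus_phasic(self, rng):
        blocks = DesignSpec().blocks("standing")
        rec, *_ = synth.generate_eda(synth.EDAGenParams(), blocks,
                                     "standing", rng)
        comps = analyze_eda(rec, optimize=False, tau_init=(2.0, 0.7))
        resid = comps.tonic + comps.phasic_sc - comps.sc
        assert np.sqrt(np.mean(resid ** 2)) < 0.02 * np.ptp(comps.sc)


class TestOptimizeTau:
    @staticmethod
    def _train(seed, noise=0.0):
        blocks = [Block(role="baseline_reading", start=0.0, duration=600.0)]
        p = synth.EDAGenParams(rate=128.0, drift_scale_us=0.0,
                               noise_sd_us=noise,
                               scr_rate_per_min={"baseline": 2.0})
        rec, *_ = synth.generate_eda(p, blocks, "standing",
                                     np.random.default_rng(seed))
        return preprocess_eda(rec).samples[0]

    def test_recovery_from_misspecified_start(self):
        """Generated with (2.0, 0.7); search starts at (3.75, 1.0)."""
        taus = optimize_tau(self._train(1), RATE, initial=(3.75, 1.0))
        assert abs(taus[0] - 2.0) / 2.0 < 0.25
        assert abs(taus[1] - 0.7) / 0.7 < 0.25

    def test_never_worse_than_initial_criterion(self):
        sc = self._train(2, noise=0.005)
        init = (3.75, 1.0)
        taus = optimize_tau(sc, RATE, initial=init)
        c_init = eda._criterion(sc, BatemanIRF(*init, RATE))
        c_final = eda._criterion(sc, BatemanIRF(*taus, RATE))
        assert c_final <= c_init + 1e-9

    def test_flat_signal_returns_initial_with_warning(self):
        with pytest.warns(RuntimeWarning, match="flat"):
            taus = optimize_tau(np.full(2000, 2.0), RATE)
        assert taus == (3.75, 1.0)


class TestTrialMeasures:
    @staticmethod
    def _components(tonic, phasic_driver, rate=RATE, events=None):
        n = tonic.size
        ev = events if events is not None else pd.DataFrame(
            columns=["onset_s", "peak_s", "amplitude_us"])
        return eda.EDAComponents(
            sc=tonic.copy(), tonic=tonic, phasic_sc=np.zeros(n),
            driver=phasic_driver, phasic_driver=phasic_driver,
            scr_events=ev, taus=(2.0, 0.7), rate=rate)

    @staticmethod
    def _epoch(role, start, dur=60.0, trial=1):
        return Epoch(participant="P", group="standing", condition="Gr",
                     occurrence="G1", trial=trial, role=role, start=start,
                     duration=dur)

    def test_constant_tonic_scl(self):
        comps = self._components(np.full(int(120 * RATE), 2.0),
                                 np.zeros(int(120 * RATE)))
        out = eda_trial_measures(comps, [self._epoch("video", 0.0)])
        assert out[out.role == "video"].SCL.iloc[0] == pytest.approx(2.0)

    def test_constant_driver_iscr_is_integral(self):
        """0.1 uS/s over 60 s integrates to 6 uS*s."""
        comps = self._components(np.full(int(120 * RATE), 2.0),
                                 np.full(int(120 * RATE), 0.1))
        out = eda_trial_measures(comps, [self._epoch("video", 0.0)])
        assert out[out.role == "video"].ISCR.iloc[0] == pytest.approx(6.0)

    def test_iscr_additive_over_window_partition(self, rng):
        driver = np.abs(rng.standard_normal(int(120 * RATE)))
        comps = self._components(np.full(int(120 * RATE), 2.0), driver)
        whole = eda_trial_measures(comps, [self._epoch("video", 0.0, 60.0)])
        halves = eda_trial_measures(comps, [
            self._epoch("video", 0.0, 30.0, trial=1),
            self._epoch("video", 30.0, 30.0, trial=2)])
        total = halves[halves.role == "video"].ISCR.sum()
        assert total == pytest.approx(
            whole[whole.role == "video"].ISCR.iloc[0])

    def test_nscr_counts_ground_truth_events(self):
        ev = pd.DataFrame({"onset_s": [5.0, 20.0, 40.0],
                           "peak_s": [6.0, 21.0, 41.0],
                           "amplitude_us": [0.2, 0.3, 0.15]})
        comps = self._components(np.full(int(120 * RATE), 2.0),
                                 np.zeros(int(120 * RATE)), events=ev)
        out = eda_trial_measures(comps, [self._epoch("video", 0.0)],
                                 amp_threshold_us=0.05)
        assert out[out.role == "video"].nSCR.iloc[0] == 3

    def test_video_minus_isi_difference_row(self):
        n = int(240 * RATE)
        tonic = np.full(n, 2.0)
        tonic[:int(60 * RATE)] = 1.5     # ISI window lower
        comps = self._components(tonic, np.zeros(n))
        out = eda_trial_measures(comps, [
            self._epoch("isi", 0.0), self._epoch("video", 60.0)])
        diff = out[out.role == "video_minus_isi"]
        assert diff.SCL.iloc[0] == pytest.approx(0.5)

    def test_window_outside_recording_rejected(self):
        comps = self._components(np.full(int(30 * RATE), 2.0),
                                 np.zeros(int(30 * RATE)))
        with pytest.raises(ValueError, match="outside"):
            eda_trial_measures(comps, [self._epoch("video", 0.0, 60.0)])


class TestAmplitudeRecovery:
    def test_median_absolute_relative_error_within_ten_percent(self):
        """Full-session CDA at the generator's default noise recovers SCR
        amplitudes within 10% median relative error (correct kernel)."""
        blocks = DesignSpec().blocks("standing")
        rec, ev, _, _ = synth.generate_eda(synth.EDAGenParams(), blocks,
                                           "standing",
                                           np.random.default_rng(3))
        comps = analyze_eda(rec, optimize=False, tau_init=(2.0, 0.7))
        det = comps.scr_events.sort_values("onset_s").reset_index(drop=True)
        used, errs = set(), []
        for r in ev.itertuples():
            c = det[(det.onset_s > r.time_s - 1.5)
                    & (det.onset_s < r.time_s + 1.5)
                    & (~det.index.isin(used))]
            if len(c):
                i = c.index[0]
                used.add(i)
                errs.append(abs(c.amplitude_us.loc[i] - r.amplitude_us)
                            / r.amplitude_us)
        assert len(errs) > 0.5 * len(ev)
        assert np.median(errs) < 0.10


def test_walking_scl_offset_recovered_in_group_direction(short_design):
    """The generator's walking SCL offset survives the CDA chain."""
    means = {}
    for group in ("standing", "walking"):
        blocks = short_design.blocks(group)
        rec, *_ = synth.generate_eda(synth.EDAGenParams(), blocks, group,
                                     np.random.default_rng(10))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            comps = analyze_eda(rec, optimize=False, tau_init=(2.0, 0.7))
        means[group] = comps.tonic.mean()
    assert means["walking"] > means["standing"]
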