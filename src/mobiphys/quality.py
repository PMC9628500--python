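"""EEG cleaning and signal-to-noise quality scoring.

The cleaning chain mirrors common mobile-EEG practice in simplified,
fully-specified form: zero-phase 1-40 Hz band-pass, mains-line removal by
per-window sinusoidal regression (avoids notch distortion around the line
frequency), and a sliding-window robust-z artifact suppressor that
attenuates flagged windows toward the channel's clean baseline via spline
interpolation.

Quality is summarized per channel as

    SNR = 10 * log10( sum(clean^2) / sum((filtered - clean)^2) )  [dB]

i.e. the power of the cleaned signal over the power removed by cleaning.
Per participant, the channel-mean SNR of the 60 s sitting baseline minus
each of the six inter-stimulus intervals yields six difference scores
(positive = ISI noisier than baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .io import Recording, Session, EpochSet


@dataclass
class CleaningReport:
    """Bookkeeping of what the artifact suppressor changed."""

    fraction_modified: dict        # channel -> fraction of samples modified
    flagged_windows: dict          # channel -> boolean array per window
    window_s: float
    z_thresh: float
    bad_channels: tuple[str, ...] = ()
    filter_settings: dict = field(default_factory=dict)


def bandpass(recording: Recording, low: float = 1.0, high: float = 40.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass; removes DC by construction."""
    nyq = recording.rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) for rate {recording.rate}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.rate,
                     output="sos")
    out = sps.sosfiltfilt(sos, recording.samples, axis=-1)
    return recording.copy_with(out)


def remove_line(recording: Recording, line_freq: float = 50.0,
                window_s: float = 4.0, n_harmonics: int = 1) -> Recording:
    """Subtract the mains component by sinusoidal regression per window.

    In each non-overlapping window the least-squares sine/cosine pair at the
    line frequency (and harmonics below Nyquist) is fitted and removed,
    leaving neighbouring frequencies untouched.
    """
    rate = recording.rate
    n = recording.n_samples
    nw = max(int(round(window_s * rate)), 8)
    out = recording.samples.copy()
    freqs = [line_freq * h for h in range(1, n_harmonics + 1)
             if line_freq * h < rate / 2]
    for start in range(0, n, nw):
        stop = min(start + nw, n)
        t = np.arange(start, stop) / rate
        cols = []
        for f in freqs:
            cols.append(np.sin(2 * np.pi * f * t))
            cols.append(np.cos(2 * np.pi * f * t))
        if not cols:
            continue
        X = np.column_stack(cols)
        seg = out[:, start:stop]
        coef, *_ = np.linalg.lstsq(X, seg.T, rcond=None)
        out[:, start:stop] = seg - (X @ coef).T
    return recording.copy_with(out)


def suppress_artifacts(recording: Recording, z_thresh: float = 4.0,
                       window_s: float = 0.5,
                       calibration: tuple[float, float] | None = None,
                       ) -> tuple[Recording, CleaningReport]:
    """Attenuate high-amplitude windows by robust z-score on window RMS.

    Per channel, the RMS of consecutive windows is scored with a
    median/MAD z; windows exceeding ``z_thresh`` are replaced by a cubic
    spline drawn through the window-median anchor points of the surrounding
    clean data.  Channels with zero variance are flagged bad and left
    untouched.

    ``calibration`` optionally gives a (start, end) session-time window of
    known-clean data (e.g. a seated baseline) from which the reference
    median/MAD are taken — necessary when persistent artifacts (such as
    gait) would otherwise dominate the recording's own statistics.
    """
    rate = recording.rate
    nw = int(round(window_s * rate))
    n = recording.n_samples
    n_win = n // nw
    calib = np.ones(n_win, dtype=bool)
    if calibration is not None:
        w0 = int(np.floor((calibration[0] - recording.start_time) * rate)) // nw
        w1 = int(np.ceil((calibration[1] - recording.start_time) * rate)) // nw
        calib[:] = False
        calib[max(w0, 0):min(w1, n_win)] = True
        if not calib.any():
            raise ValueError("calibration window outside the recording")
    out = recording.samples.copy()
    frac: dict[str, float] = {}
    flags: dict[str, np.ndarray] = {}
    bad: list[str] = []
    for ci, ch in enumerate(recording.labels):
        x = out[ci, :n_win * nw].reshape(n_win, nw)
        rms = np.sqrt((x ** 2).mean(axis=1))
        med = np.median(rms[calib])
        mad = np.median(np.abs(rms[calib] - med))
        if mad == 0 and np.ptp(out[ci]) == 0:
            bad.append(ch)
            frac[ch] = 0.0
            flags[ch] = np.zeros(n_win, dtype=bool)
            continue
        scale = 1.4826 * mad if mad > 0 else rms[calib].std() or 1.0
        z = (rms - med) / scale
        flagged = z > z_thresh
        flags[ch] = flagged
        if flagged.any():
            centers = (np.arange(n_win) + 0.5) * nw
            clean_idx = ~flagged
            level = float(np.median(np.median(x[clean_idx], axis=1))) \
                if clean_idx.any() else 0.0
            if clean_idx.sum() >= 4:
                anchors = np.median(x[clean_idx], axis=1)
                spline = CubicSpline(centers[clean_idx], anchors,
                                     extrapolate=False)
                for w in np.flatnonzero(flagged):
                    lo, hi = w * nw, (w + 1) * nw
                    vals = spline(np.arange(lo, hi))
                    out[ci, lo:hi] = np.where(np.isfinite(vals), vals, level)
            else:
                for w in np.flatnonzero(flagged):
                    out[ci, w * nw:(w + 1) * nw] = level
        frac[ch] = float(flagged.mean())
    report = CleaningReport(fraction_modified=frac, flagged_windows=flags,
                            window_s=window_s, z_thresh=z_thresh,
                            bad_channels=tuple(bad))
    return recording.copy_with(out), report


def compute_snr(clean: np.ndarray, filtered: np.ndarray) -> np.ndarray:
    """Per-channel SNR in dB: 10*log10(sum clean^2 / sum residual^2).

    Zero residual yields +inf ("infinite SNR"); zero clean power -inf.
    """
    clean = np.atleast_2d(clean)
    filtered = np.atleast_2d(filtered)
    if clean.shape != filtered.shape:
        raise ValueError("clean and filtered segments must have equal shape")
    p_clean = (clean ** 2).sum(axis=-1)
    p_resid = ((filtered - clean) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(p_clean / p_resid)


def clean_eeg(recording: Recording, low: float = 1.0, high: float = 40.0,
              line_freq: float = 50.0, z_thresh: float = 4.0,
              window_s: float = 0.5,
              calibration: tuple[float, float] | None = None,
              ) -> tuple[Recording, Recording, CleaningReport]:
    """Full chain filter -> line removal -> artifact suppression.

    Returns ``(clean, filtered, report)`` where ``filtered`` is the
    band-passed recording (the SNR reference) and ``clean`` additionally
    has line noise and artifact windows removed.
    """
    filtered = bandpass(recording, low, high)
    clean, report = suppress_artifacts(remove_line(filtered, line_freq),
                                       z_thresh, window_s,
                                       calibration=calibration)
    report.filter_settings = {"low": low, "high": high, "line_freq": line_freq}
    return clean, filtered, report


def snr_table(clean: Recording, filtered: Recording, epochs: EpochSet,
              participant: str = "", exclude: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per (segment, channel) SNR for the sitting baseline and the six ISIs."""
    rows = []
    segments = [(f"isi{e.trial}", e) for e in epochs.isis()]
    segments += [("baseline_sitting", e) for e in epochs.baselines()
                 if e.occurrence == "baseline_sitting"]
    for name, e in segments:
        c = clean.slice(e.start, e.end)
        f = filtered.slice(e.start, e.end)
        snr = compute_snr(c, f)
        for ch, val in zip(clean.labels, snr):
            if ch in exclude:
                continue
            rows.append((participant or e.participant, name, ch, float(val)))
    return pd.DataFrame(rows, columns=["participant", "segment", "channel", "snr_db"])


def snr_baseline_diff(table: pd.DataFrame) -> pd.DataFrame:
    """Channel-mean SNR difference baseline - ISI, six values per participant."""
    out = []
    for pid, sub in table.groupby("participant"):
        means = sub.groupby("segment")["snr_db"].mean()
        if "baseline_sitting" not in means.index:
            raise ValueError(f"participant {pid}: missing sitting baseline segment")
        missing = [i for i in range(1, 7) if f"isi{i}" not in means.index]
        if missing:
            raise ValueError(f"participant {pid}: missing ISI segments {missing}")
        base = means["baseline_sitting"]
        for i in range(1, 7):
            out.append((pid, i, float(base - means[f"isi{i}"])))
    return pd.DataFrame(out, columns=["participant", "isi_index", "snr_diff_db"])


def session_snr(session: Session, epochs: EpochSet, **clean_kwargs) -> pd.DataFrame:
    """Convenience: clean a session's EEG (artifact thresholds calibrated on
    the seated fixation baseline) and return the 6 baseline-diff scores."""
    sitting = [e for e in epochs.baselines()
               if e.occurrence == "baseline_sitting"]
    if sitting and "calibration" not in clean_kwargs:
        clean_kwargs["calibration"] = (sitting[0].start, sitting[0].end)
    clean, filtered, report = clean_eeg(session.require("eeg"), **clean_kwargs)
    tab = snr_table(clean, filtered, epochs,
                    participant=str(session.meta.get("participant", "")),
                    exclude=report.bad_channels)
    return snr_baseline_diff(tab)
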