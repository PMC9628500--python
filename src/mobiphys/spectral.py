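"""Epoch power spectra, band powers, baseline correction and the four EEG indices.

Spectra are averaged modified (Welch) periodograms on a 0.5 Hz zero-padded
grid with 250 ms window overlap, normalized as power spectral density so
that the integral of density over frequency equals signal variance
(Parseval, within windowing tolerance).

Baseline correction expresses video-epoch band power as a percentage of the
preceding inter-stimulus interval:

    corrected = 100 + 100 * (P_video - P_isi) / P_isi

so 100 means "no change", 120 a +20% power increase, and the value is
invariant to common rescaling of both powers.

Indices (computed from baseline-corrected band powers per trial):

* FA  - frontal alpha: mean corrected alpha over the frontal set.
* FMT - frontal midline theta: mean corrected theta at Fz and AFz.
* TBR - theta/beta ratio: mean frontal corrected theta / mean frontal
  corrected beta.
* FAA - frontal alpha asymmetry: ln(corrected alpha at F4) - ln(at F3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EpochSet, Recording, Session
from .design import DesignSpec

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.5),
    "beta": (13.0, 24.5),
}

FRONTAL_SET = ("F3", "F4", "F7", "F8", "FP1", "FP2", "AFz", "Fz")
FMT_SET = ("Fz", "AFz")
FAA_PAIR = ("F4", "F3")  # right minus left

#: corrected values below this are treated as undefined for log-based indices
FAA_EPS = 1e-6


@dataclass
class Spectrum:
    """Power spectral density on a uniform frequency grid."""

    freqs: np.ndarray            # Hz
    density: np.ndarray          # (channels, freqs), uV^2/Hz
    labels: tuple[str, ...]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def compute_psd(samples: np.ndarray, rate: float, window_s: float = 1.0,
                overlap_s: float = 0.25, resolution_hz: float = 0.5,
                labels: tuple[str, ...] = ()) -> Spectrum:
    """Welch PSD of an epoch (channels x time) with Hann windows.

    Windows are zero-padded to reach ``resolution_hz`` grid spacing.  The
    epoch must contain at least one full window.
    """
    samples = np.atleast_2d(samples)
    nperseg = int(round(window_s * rate))
    noverlap = int(round(overlap_s * rate))
    if samples.shape[1] < nperseg:
        raise ValueError("epoch shorter than one analysis window")
    nfft = int(round(rate / resolution_hz))
    if nfft < nperseg:
        nfft = nperseg
    freqs, density = sps.welch(samples, fs=rate, window="hann",
                               nperseg=nperseg, noverlap=noverlap, nfft=nfft,
                               detrend="constant", scaling="density", axis=-1)
    if not labels:
        labels = tuple(f"ch{i}" for i in range(samples.shape[0]))
    return Spectrum(freqs=freqs, density=density, labels=labels)


def band_power(spectrum: Spectrum, band: tuple[float, float] | str) -> np.ndarray:
    """Integrated density over a closed band [low, high], per channel (uV^2).

    A bin belongs to the band if its center frequency lies in the interval;
    the integral is a simple bin-sum times the bin width.
    """
    if isinstance(band, str):
        band = BANDS[band]
    low, high = band
    mask = (spectrum.freqs >= low) & (spectrum.freqs <= high)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return spectrum.density[..., mask].sum(axis=-1) * spectrum.df


def baseline_correct(p_video, p_isi):
    """Percent-of-baseline band power: ``100 + 100 * (Pv - Pi) / Pi``.

    Raises ``ValueError`` when any ISI power is nonpositive (undefined
    baseline).  Accepts scalars or arrays.
    """
    p_video = np.asarray(p_video, dtype=float)
    p_isi = np.asarray(p_isi, dtype=float)
    if np.any(p_isi <= 0):
        raise ValueError("undefined baseline: ISI power must be positive")
    out = 100.0 + 100.0 * (p_video - p_isi) / p_isi
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def band_power_table(recording: Recording, epochs: EpochSet,
                     window_s: float = 1.0, overlap_s: float = 0.25,
                     resolution_hz: float = 0.5) -> pd.DataFrame:
    """Raw band power per (trial, role, channel, band) for all paired epochs."""
    rows = []
    for epoch in epochs.videos() + epochs.isis():
        seg = recording.slice(epoch.start, epoch.end)
        spec = compute_psd(seg, recording.rate, window_s, overlap_s,
                           resolution_hz, labels=recording.labels)
        for band in BANDS:
            bp = band_power(spec, band)
            for ch, val in zip(recording.labels, bp):
                rows.append((epoch.participant, epoch.group, epoch.condition,
                             epoch.occurrence, epoch.trial, epoch.role,
                             ch, band, float(val)))
    return pd.DataFrame(rows, columns=["participant", "group", "condition",
                                       "occurrence", "trial", "role",
                                       "channel", "band", "power"])


def corrected_band_power(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline-corrected (percent) band power per trial/channel/band."""
    wide = table.pivot_table(
        index=["participant", "group", "condition", "occurrence", "trial",
               "channel", "band"],
        columns="role", values="power").reset_index()
    if {"video", "isi"} - set(wide.columns):
        raise ValueError("table must contain paired video and isi powers")
    wide = wide.dropna(subset=["video", "isi"])
    wide["corrected"] = baseline_correct(wide["video"].to_numpy(),
                                         wide["isi"].to_numpy())
    return wide.drop(columns=["video", "isi"])


def _mean_over(sub: pd.DataFrame, band: str, electrodes: tuple[str, ...]) -> float:
    rows = sub[(sub["band"] == band) & (sub["channel"].isin(electrodes))]
    present = set(rows["channel"])
    missing = set(electrodes) - present
    if missing:
        raise KeyError(f"electrodes absent from data: {sorted(missing)}")
    return float(rows["corrected"].mean())


def index_fa(trial_corrected: pd.DataFrame,
             electrodes: tuple[str, ...] = FRONTAL_SET) -> float:
    """Frontal alpha: mean corrected alpha power over the frontal set."""
    return _mean_over(trial_corrected, "alpha", electrodes)


def index_fmt(trial_corrected: pd.DataFrame,
              electrodes: tuple[str, ...] = FMT_SET) -> float:
    """Frontal midline theta: mean corrected theta at the midline pair."""
    return _mean_over(trial_corrected, "theta", electrodes)


def index_tbr(trial_corrected: pd.DataFrame,
              electrodes: tuple[str, ...] = FRONTAL_SET) -> float:
    """Theta/beta ratio of frontal means; beta mean must be positive."""
    theta = _mean_over(trial_corrected, "theta", electrodes)
    beta = _mean_over(trial_corrected, "beta", electrodes)
    if beta <= 0:
        raise ValueError("theta/beta ratio undefined: frontal beta mean <= 0")
    return theta / beta


def index_faa(trial_corrected: pd.DataFrame,
              pair: tuple[str, str] = FAA_PAIR) -> float:
    """Frontal alpha asymmetry ln(right) - ln(left) of corrected alpha.

    Returns NaN (trial invalid) when either value falls below ``FAA_EPS``
    rather than clamping.
    """
    right = _mean_over(trial_corrected, "alpha", (pair[0],))
    left = _mean_over(trial_corrected, "alpha", (pair[1],))
    if right < FAA_EPS or left < FAA_EPS:
        return float("nan")
    return float(np.log(right) - np.log(left))


def index_table(corrected: pd.DataFrame,
                frontal: tuple[str, ...] = FRONTAL_SET,
                fmt_set: tuple[str, ...] = FMT_SET,
                faa_pair: tuple[str, str] = FAA_PAIR) -> pd.DataFrame:
    """Per-trial FA, FMT, TBR and FAA from corrected band powers."""
    rows = []
    keys = ["participant", "group", "condition", "occurrence", "trial"]
    for vals, sub in corrected.groupby(keys):
        rows.append((*vals,
                     index_fa(sub, frontal), index_fmt(sub, fmt_set),
                     index_tbr(sub, frontal), index_faa(sub, faa_pair)))
    return pd.DataFrame(rows, columns=keys + ["FA", "FMT", "TBR", "FAA"])


def eeg_indices(session: Session, design: DesignSpec, epochs: EpochSet,
                **psd_kwargs) -> pd.DataFrame:
    """Convenience chain: band powers -> Eq.-style correction -> index table."""
    raw = band_power_table(session.require("eeg"), epochs, **psd_kwargs)
    return index_table(corrected_band_power(raw))
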