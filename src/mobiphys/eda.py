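"""Electrodermal preprocessing and continuous deconvolution analysis (CDA).

Skin conductance is modelled as a sudomotor driver convolved with a Bateman
impulse response ``b(t) = exp(-t/tau1) - exp(-t/tau2)`` (normalized to unit
maximum, so an event of amplitude ``a`` microsiemens produces an SCR peaking
at ``a``).  Conventions:

* the driver has units uS/s and satisfies ``sc = conv(driver, kernel) / rate``,
  so a discrete impulse of time-integral ``a`` reproduces ``a * b(t - t0)``;
* deconvolution is frequency-domain division with Tikhonov regularization,
  on a constant-extended signal to suppress boundary transients;
* the tonic driver is interpolated across inter-impulse sections on a 10 s
  grid and smoothed; tonic skin conductance is its re-convolution, the
  phasic component the remainder.

Trial measures: SCL (mean tonic, uS), ISCR (time integral of the phasic
driver, uS*s), and nSCR (count of phasic driver impulses whose recovered
amplitude exceeds a threshold, default 0.05 uS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .io import Recording, Epoch

DEFAULT_TAU_INIT = (3.75, 1.0)   # seconds: (decay, rise)
NSCR_THRESHOLD_US = 0.05
DRIVER_NEG_TOL = 0.01            # fraction of max driver before a warning


@dataclass
class BatemanIRF:
    """Unit-maximum Bateman kernel sampled at a working rate."""

    tau1: float
    tau2: float
    rate: float
    kernel: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0 or self.tau1 == self.tau2:
            raise ValueError("taus must be positive and distinct")
        if self.kernel is None:
            dur = 10.0 * max(self.tau1, self.tau2)
            t = np.arange(int(dur * self.rate)) / self.rate
            k = np.exp(-t / self.tau1) - np.exp(-t / self.tau2)
            self.kernel = k / k.max()


@dataclass
class EDAComponents:
    """Tonic/phasic decomposition of a preprocessed conductance series."""

    sc: np.ndarray               # preprocessed conductance, uS
    tonic: np.ndarray            # tonic conductance, uS
    phasic_sc: np.ndarray        # phasic conductance, uS
    driver: np.ndarray           # raw deconvolved driver, uS/s
    phasic_driver: np.ndarray    # driver minus tonic driver, uS/s
    scr_events: pd.DataFrame     # onset_s, peak_s, amplitude_us
    taus: tuple[float, float]
    rate: float
    start_time: float = 0.0


def preprocess_eda(recording: Recording, target_rate: float = 16.0,
                   cutoff_hz: float = 5.0) -> Recording:
    """Anti-aliased decimation to 16 Hz, then first-order 5 Hz Butterworth."""
    if recording.rate < target_rate:
        raise ValueError(f"input rate {recording.rate} Hz below {target_rate} Hz")
    x = recording.samples
    if recording.rate != target_rate:
        frac = Fraction(target_rate / recording.rate).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1,
                              padtype="line")
    sos = sps.butter(1, cutoff_hz, btype="lowpass", fs=target_rate, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)
    return Recording(samples=x, rate=target_rate, labels=recording.labels,
                     unit=recording.unit, start_time=recording.start_time)


def _fft_convolve(driver: np.ndarray, kernel: np.ndarray, rate: float) -> np.ndarray:
    """sc = conv(driver, kernel)/rate, truncated to the driver's length."""
    n = driver.size
    out = sps.fftconvolve(driver, kernel)[:n] / rate
    return out


def reconvolve(driver: np.ndarray, irf: BatemanIRF) -> np.ndarray:
    """Forward model ``conv(driver, kernel)/rate`` with steady-state history.

    The driver is constant-extended by one kernel length before onset, so a
    nonzero baseline driver reproduces the corresponding steady tonic level
    instead of a spurious rise from zero (the inverse convention of
    :func:`deconvolve`).
    """
    driver = np.asarray(driver, dtype=float)
    npad = irf.kernel.size
    # robust history level: the first couple of samples can carry the
    # deconvolution's onset transient
    hist = float(np.median(driver[:max(int(irf.rate), 4)]))
    ext = np.concatenate([np.full(npad, hist), driver])
    return _fft_convolve(ext, irf.kernel, irf.rate)[npad:]


def deconvolve(sc: np.ndarray, irf: BatemanIRF, regularization: float = 1e-8,
               ) -> np.ndarray:
    """Recover the driver by regularized frequency-domain division.

    The signal is constant-extended by one kernel length on both sides so
    onset transients and circular wrap-around land outside the returned
    segment.
    """
    sc = np.asarray(sc, dtype=float).ravel()
    kernel = irf.kernel
    if kernel.size >= sc.size:
        raise ValueError("kernel must be shorter than the signal")
    npad = kernel.size
    ext = np.concatenate([np.full(npad, sc[0]), sc, np.full(npad, sc[-1])])
    nfft = int(2 ** np.ceil(np.log2(ext.size + kernel.size)))
    K = np.fft.rfft(kernel, nfft)
    S = np.fft.rfft(ext, nfft)
    denom = np.abs(K) ** 2 + regularization * np.max(np.abs(K)) ** 2
    D = S * np.conj(K) / denom
    d_ext = np.fft.irfft(D, nfft) * irf.rate
    return d_ext[npad:npad + sc.size]


def _impulse_mask(driver: np.ndarray, rate: float) -> np.ndarray:
    """Boolean mask of impulse (phasic burst) regions of the driver."""
    med = np.median(driver)
    mad = np.median(np.abs(driver - med))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = driver.std() or 1.0
    mask = driver > med + 3.0 * scale
    # widen each burst by ~1 s to cover rise and recovery
    halo = max(int(round(1.0 * rate)), 1)
    return ndimage.binary_dilation(mask, iterations=halo)


def split_tonic_phasic(sc: np.ndarray, driver: np.ndarray, irf: BatemanIRF,
                       grid_s: float = 10.0, smooth_s: float = 4.0,
                       amp_threshold_us: float = NSCR_THRESHOLD_US,
                       start_time: float = 0.0) -> EDAComponents:
    """Split the deconvolved driver into tonic and phasic components.

    The tonic driver is a Pchip interpolation through inter-impulse medians
    on a ``grid_s``-spaced grid, lightly Gaussian-smoothed; tonic skin
    conductance is its re-convolution with the kernel.  SCRs are contiguous
    suprathreshold segments of the phasic driver; their amplitude is the
    segment's time integral (equal to the generating event amplitude for a
    unit-maximum kernel).
    """
    sc = np.asarray(sc, dtype=float).ravel()
    rate = irf.rate
    n = sc.size
    t = np.arange(n) / rate
    mask = _impulse_mask(driver, rate)

    step = max(int(round(grid_s * rate)), 1)
    half = step // 2
    anchors_t, anchors_v = [], []
    for center in range(0, n, step):
        lo, hi = max(center - half, 0), min(center + half + 1, n)
        free = ~mask[lo:hi]
        if free.sum() >= max(int(0.5 * rate), 2):
            anchors_t.append(t[lo:hi][free].mean())
            anchors_v.append(np.median(driver[lo:hi][free]))
    if len(anchors_t) < 2:
        tonic_driver = np.full(n, np.median(driver[~mask]) if (~mask).any()
                               else np.median(driver))
    else:
        interp = PchipInterpolator(anchors_t, anchors_v, extrapolate=True)
        tonic_driver = interp(t)
    if smooth_s > 0:
        tonic_driver = ndimage.gaussian_filter1d(tonic_driver, smooth_s * rate / 4)

    phasic_driver = driver - tonic_driver
    neg = phasic_driver.min()
    if phasic_driver.max() > 0 and -neg > DRIVER_NEG_TOL * phasic_driver.max():
        warnings.warn(
            f"phasic driver negativity {-neg:.3g} exceeds "
            f"{DRIVER_NEG_TOL:.0%} of its maximum", RuntimeWarning)

    tonic_sc = _fft_convolve(np.concatenate(
        [np.full(irf.kernel.size, tonic_driver[0]), tonic_driver]),
        irf.kernel, rate)[irf.kernel.size:]
    phasic_sc = sc - tonic_sc

    events = _detect_scrs(phasic_driver, rate, amp_threshold_us, start_time)
    return EDAComponents(sc=sc, tonic=tonic_sc, phasic_sc=phasic_sc,
                         driver=driver, phasic_driver=phasic_driver,
                         scr_events=events, taus=(irf.tau1, irf.tau2),
                         rate=rate, start_time=start_time)


def _detect_scrs(phasic_driver: np.ndarray, rate: float,
                 amp_threshold_us: float, start_time: float) -> pd.DataFrame:
    """Contiguous suprathreshold driver segments as SCR events.

    Detection uses a floor of 5% of the driver maximum; each event's
    amplitude is the driver mass integrated from its onset to the next
    onset (capturing the subthreshold tail of isolated responses).
    """
    peak_floor = 0.05 * max(phasic_driver.max(), 0.0)
    rows = []
    idx = np.flatnonzero(phasic_driver > peak_floor)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        seg_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        seg_ends = np.concatenate([idx[breaks], [idx[-1]]])
        bounds = np.append(seg_starts[1:], phasic_driver.size)
        for s, e, b in zip(seg_starts, seg_ends, bounds):
            seg = phasic_driver[s:e + 1]
            amp = float(np.clip(phasic_driver[s:b], 0, None).sum() / rate)
            if amp >= amp_threshold_us:
                rows.append((start_time + s / rate,
                             start_time + (s + int(np.argmax(seg))) / rate,
                             amp))
    return pd.DataFrame(rows, columns=["onset_s", "peak_s", "amplitude_us"])


def _criterion(sc: np.ndarray, irf: BatemanIRF, smooth_s: float = 0.25,
               baseline_s: float = 20.0) -> float:
    """Tau-optimization objective: driver negativity + indistinctness.

    Negativity is the fraction of driver mass below the slow baseline.
    Indistinctness is measured as the failure of a *distinct-impulse*
    representation: the driver's suprathreshold bursts are collapsed to
    single impulses at their center of mass and re-convolved; the residual
    against the observed conductance (relative to its range) is large
    exactly when the driver is not a train of distinct impulses.  A
    correctly specified kernel drives both terms to zero on clean data.
    """
    rate = irf.rate
    d = deconvolve(sc, irf, regularization=1e-6)
    ds = ndimage.gaussian_filter1d(d, smooth_s * rate) if smooth_s else d
    base = ndimage.median_filter(ds, size=int(baseline_s * rate) | 1,
                                 mode="nearest")
    r = ds - base
    tot = np.abs(r).sum()
    if tot <= 0:
        return 0.0
    negativity = -np.clip(r, None, 0).sum() / tot

    floor = 0.1 * max(r.max(), 0.0)
    sparse = np.zeros_like(r)
    idx = np.flatnonzero(r > floor)
    if idx.size:
        brk = np.flatnonzero(np.diff(idx) > 1)
        seg_starts = np.concatenate([[idx[0]], idx[brk + 1]])
        seg_ends = np.concatenate([idx[brk], [idx[-1]]])
        for a, b in zip(seg_starts, seg_ends):
            seg = r[a:b + 1]
            com = a + int(round(np.sum(np.arange(seg.size) * seg) / seg.sum()))
            sparse[com] = seg.sum()
    npad = irf.kernel.size
    tonic_sc = _fft_convolve(np.concatenate([np.full(npad, base[0]), base]),
                             irf.kernel, rate)[npad:]
    recon = tonic_sc + _fft_convolve(sparse, irf.kernel, rate)
    indistinctness = float(np.sqrt(np.mean((recon - sc) ** 2)) / np.ptp(sc))
    return indistinctness + 0.5 * float(negativity)


#: coarse log-space lattice used to seed the simplex search
_TAU_STARTS = tuple((t1, t2) for t1 in (1.0, 2.0, 4.0, 8.0)
                    for t2 in (0.25, 0.5, 1.0, 2.0) if t2 < t1)


def optimize_tau(sc: np.ndarray, rate: float,
                 initial: tuple[float, float] = DEFAULT_TAU_INIT,
                 maxiter: int = 150) -> tuple[float, float]:
    """Refine Bateman taus by downhill-simplex search on the CDA criterion.

    The criterion surface can hold spurious local minima, so the simplex is
    started from the best point of a coarse log-spaced lattice (always
    including ``initial``); the result never scores worse than the initial
    taus.  Flat input returns ``initial`` with a warning.
    """
    sc = np.asarray(sc, dtype=float).ravel()
    if np.ptp(sc) < 1e-12:
        warnings.warn("flat signal: tau optimization skipped", RuntimeWarning)
        return tuple(initial)

    def objective(log_taus: np.ndarray) -> float:
        tau1, tau2 = np.exp(log_taus)
        if not (0.05 < tau2 < tau1 < 60.0):
            return 1e6
        return _criterion(sc, BatemanIRF(tau1, tau2, rate))

    starts = [np.log(initial)] + [np.log(t) for t in _TAU_STARTS]
    best = min(starts, key=objective)
    res = optimize.minimize(objective, best, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-3,
                                     "fatol": 1e-7})
    f0 = objective(np.log(initial))
    if res.fun > f0 + 1e-12:
        warnings.warn("tau optimization did not improve; keeping initial taus",
                      RuntimeWarning)
        return tuple(initial)
    tau1, tau2 = np.exp(res.x)
    return float(tau1), float(tau2)


def analyze_eda(recording: Recording, optimize: bool = True,
                tau_init: tuple[float, float] = DEFAULT_TAU_INIT,
                amp_threshold_us: float = NSCR_THRESHOLD_US,
                driver_smooth_s: float = 0.25) -> EDAComponents:
    """Full chain: preprocess -> (optional) tau refinement -> CDA split.

    The deconvolved driver is lightly Gaussian-smoothed (mass-preserving,
    so ISCR and amplitude estimates are unaffected) before the tonic/phasic
    split to keep deconvolution noise out of SCR detection.
    """
    pre = preprocess_eda(recording)
    sc = pre.samples[0]
    taus = optimize_tau(sc, pre.rate, tau_init) if optimize else tau_init
    irf = BatemanIRF(taus[0], taus[1], pre.rate)
    driver = deconvolve(sc, irf)
    if driver_smooth_s:
        driver = ndimage.gaussian_filter1d(driver, driver_smooth_s * pre.rate)
    return split_tonic_phasic(sc, driver, irf, start_time=pre.start_time,
                              amp_threshold_us=amp_threshold_us)


def eda_trial_measures(components: EDAComponents, epochs: list[Epoch],
                       amp_threshold_us: float = NSCR_THRESHOLD_US) -> pd.DataFrame:
    """SCL, ISCR and nSCR per epoch window, plus video-minus-ISI differences.

    Raises ``ValueError`` for windows outside the analysed recording.
    """
    rate = components.rate
    n = components.sc.size
    t0 = components.start_time
    rows = []
    for e in epochs:
        i0 = int(np.floor((e.start - t0) * rate))
        i1 = i0 + int(round(e.duration * rate))
        if i0 < 0 or i1 > n:
            raise ValueError(f"window [{e.start}, {e.end}) outside recording")
        scl = float(components.tonic[i0:i1].mean())
        iscr = float(components.phasic_driver[i0:i1].sum() / rate)
        ev = components.scr_events
        nscr = int(((ev["peak_s"] >= e.start) & (ev["peak_s"] < e.end)
                    & (ev["amplitude_us"] >= amp_threshold_us)).sum())
        rows.append((e.participant, e.group, e.condition, e.occurrence,
                     e.trial, e.role, scl, iscr, nscr))
    df = pd.DataFrame(rows, columns=["participant", "group", "condition",
                                     "occurrence", "trial", "role",
                                     "SCL", "ISCR", "nSCR"])
    video = df[df.role == "video"].set_index("trial")
    isi = df[df.role == "isi"].set_index("trial")
    common = video.index.intersection(isi.index)
    diffs = video.loc[common, ["participant", "group", "condition",
                               "occurrence"]].copy()
    for m in ("SCL", "ISCR", "nSCR"):
        diffs[m] = video.loc[common, m] - isi.loc[common, m]
    diffs["role"] = "video_minus_isi"
    return pd.concat([df, diffs.reset_index()], ignore_index=True)
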