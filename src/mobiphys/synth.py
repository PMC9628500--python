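"""Synthetic mobile EEG/EDA session generator with full ground-truth bookkeeping.

The generator emulates the statistical structure the downstream analysis
assumes, so every estimator in the pipeline can be checked against recorded
truth:

* EEG: per-channel 1/f^beta background (plus white sensor noise and a 50 Hz
  mains component) and narrowband oscillators in the theta, alpha and beta
  bands.  Oscillators are band-limited Gaussian processes scaled by a
  per-band amplitude A following the sinusoid convention: the component
  contributes ``A**2 / 2`` of variance in expectation.  Condition-dependent
  multiplicative amplitude gains act inside video blocks (power therefore
  scales as gain squared).  The walking group receives periodic gait-locked
  artifact bursts while on the treadmill.
* EDA: slowly drifting tonic level (plus a group offset for walking) with
  sparse Bateman-shaped phasic responses at condition-dependent Poisson
  rates, log-normal amplitudes, and additive measurement noise.
* SAM: integer 1-9 ratings from latent per-condition affect means with
  Gaussian noise, rounded half-up and clamped.

A single master seed is expanded into per-stream substreams so adding a
stream does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, Block, GROUPS
from .io import Recording, MarkerStream, Session, markers_from_blocks

# The 24 recording electrodes of the mobile 10-20 cap (reference/ground
# positions excluded), augmented with F3, F4 and AFz which the frontal
# index definitions require.
DEFAULT_MONTAGE = (
    "FP1", "FP2", "F7", "F8", "Fz", "FC1", "FC2", "Cz", "C3", "C4",
    "T7", "T8", "CPz", "CP1", "CP2", "CP5", "CP6", "TP9", "TP10",
    "Pz", "P3", "P4", "O1", "O2",
    "F3", "F4", "AFz",
)

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.5),
    "beta": (13.0, 24.5),
}

FRONTAL_SET = ("F3", "F4", "F7", "F8", "FP1", "FP2", "AFz", "Fz")


@dataclass(frozen=True)
class GainRule:
    """Multiplicative band-amplitude gain for a condition at given channels."""

    condition: str
    band: str
    channels: tuple[str, ...]
    gain: float

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gains must be strictly positive")


def default_gain_rules() -> tuple[GainRule, ...]:
    """Condition effects mirroring the qualitative direction of the study:
    green raises frontal alpha (attention restoration), crowding raises
    frontal theta (cognitive load), and green slightly favours right-frontal
    alpha (approach affect).  Effect sizes are free generator parameters.
    """
    return (
        GainRule("Gr", "alpha", FRONTAL_SET, 1.10),
        GainRule("IC", "theta", FRONTAL_SET, 1.10),
        GainRule("OC", "theta", FRONTAL_SET, 1.08),
        GainRule("Gr", "alpha", ("F4",), 1.05),
    )


@dataclass(frozen=True)
class ArtifactParams:
    """Gait-locked burst artifacts for the walking group."""

    cadence_hz: float = 1.85     # step rate at 4 km/h
    burst_amplitude_uv: float = 30.0
    burst_duration_s: float = 0.15
    n_harmonics: int = 2


@dataclass(frozen=True)
class EEGGenParams:
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    rate: float = 500.0
    background_exponent: float = 1.0
    background_scale_uv: float = 8.0     # std of the 1/f background
    sensor_noise_uv: float = 2.0         # white measurement noise (std)
    line_noise_uv: float = 1.5           # mains interference amplitude
    line_freq_hz: float = 50.0
    osc_amplitude_uv: dict = field(default_factory=lambda: {
        "theta": 3.0, "alpha": 4.0, "beta": 2.0})
    condition_gains: tuple[GainRule, ...] = field(default_factory=default_gain_rules)
    artifact: ArtifactParams = field(default_factory=ArtifactParams)

    def __post_init__(self) -> None:
        if self.background_scale_uv < 0:
            raise ValueError("background scale must be nonnegative")
        for band, amp in self.osc_amplitude_uv.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}")
            if amp < 0:
                raise ValueError("oscillator amplitudes must be nonnegative")
        missing = {ch for r in self.condition_gains for ch in r.channels} \
            - set(self.montage)
        if missing:
            raise ValueError(
                f"condition_gains reference channels missing from montage: "
                f"{sorted(missing)}")


@dataclass(frozen=True)
class EDAGenParams:
    rate: float = 128.0
    tonic_level_us: float = 2.0
    drift_scale_us: float = 0.25
    drift_timescale_s: float = 60.0
    walking_offset_us: float = 0.35
    scr_rate_per_min: dict = field(default_factory=lambda: {
        "baseline": 4.0, "isi": 4.0,
        "Gr": 4.0, "IU": 5.0, "OU": 5.0, "IC": 8.0, "OC": 8.0})
    walking_rate_factor: float = 1.5
    amp_median_us: float = 0.3
    amp_sigma: float = 0.5
    tau1_s: float = 2.0
    tau2_s: float = 0.7
    noise_sd_us: float = 0.005

    def __post_init__(self) -> None:
        if self.rate < 16:
            raise ValueError("EDA rate must be at least 16 Hz")
        if self.tau1_s <= 0 or self.tau2_s <= 0 or self.tau1_s == self.tau2_s:
            raise ValueError("Bateman taus must be positive and distinct")


@dataclass(frozen=True)
class SAMGenParams:
    """Latent affect means per condition (SAM convention: arousal 9 = calm,
    valence 9 = negative), plus rating noise."""

    latent_arousal: dict = field(default_factory=lambda: {
        "Gr": 7.5, "OU": 5.5, "IU": 5.0, "OC": 3.5, "IC": 3.0})
    latent_valence: dict = field(default_factory=lambda: {
        "Gr": 2.0, "OU": 4.0, "IU": 4.5, "OC": 5.5, "IC": 6.0})
    noise_sd: float = 1.2

    def __post_init__(self) -> None:
        for d in (self.latent_arousal, self.latent_valence):
            for cond, mu in d.items():
                if not 1 <= mu <= 9:
                    raise ValueError(f"latent mean for {cond} outside [1, 9]")


@dataclass
class GroundTruth:
    """Everything random the generator produced, for parameter recovery."""

    band_power: pd.DataFrame       # trial, role, condition, channel, band, power
    scr_events: pd.DataFrame       # time_s, amplitude_us, role, trial
    eda_tonic: np.ndarray          # noiseless tonic series
    eda_noiseless: np.ndarray      # tonic + phasic, no measurement noise
    sam_latent: pd.DataFrame       # trial, condition, arousal, valence
    artifact_segments: list[tuple[float, float]]
    condition_gains: tuple[GainRule, ...]


# ---------------------------------------------------------------------------
# elementary signal builders
# ---------------------------------------------------------------------------

def pink_noise(n: int, rate: float, exponent: float, scale: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent Gaussian noise with standard deviation ``scale``."""
    if scale == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / rate)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping, n)
    sd = shaped.std()
    return shaped * (scale / sd) if sd > 0 else shaped


def bandlimited_noise(n: int, rate: float, band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian process band-limited to ``band`` with unit variance in
    expectation (constructed in the frequency domain, zero leakage)."""
    f = np.fft.rfftfreq(n, 1 / rate)
    mask = (f >= band[0]) & (f <= band[1])
    nbins = int(mask.sum())
    if nbins == 0:
        raise ValueError(f"band {band} contains no frequency bins for n={n}")
    spec = np.zeros(f.shape, dtype=complex)
    spec[mask] = rng.standard_normal(nbins) + 1j * rng.standard_normal(nbins)
    x = np.fft.irfft(spec, n)
    # E[sum x^2] = 2 * nbins * sigma^2 / n with sigma^2 = 2 here
    x *= n / math.sqrt(4.0 * nbins)
    return x


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _gain_envelope(block: Block, params: EEGGenParams, band: str, channel: str,
                   rate: float, n_total: int, fade_s: float) -> tuple[slice, np.ndarray] | None:
    """Gain profile (with fade ramps) for one video block, or None if unity."""
    gain = 1.0
    for rule in params.condition_gains:
        if rule.condition == block.condition and rule.band == band \
                and channel in rule.channels:
            gain *= rule.gain
    if gain == 1.0:
        return None
    i0 = int(np.floor(block.start * rate))
    n = int(round(block.duration * rate))
    i1 = min(i0 + n, n_total)
    env = np.full(i1 - i0, gain)
    nf = int(round(fade_s * rate))
    if nf > 0 and 2 * nf < env.size:
        ramp = np.linspace(1.0, gain, nf)
        env[:nf] = ramp
        env[-nf:] = ramp[::-1]
    return slice(i0, i1), env


def generate_eeg(params: EEGGenParams, blocks: list[Block], group: str,
                 rng: np.random.Generator, fade_s: float = 2.0,
                 analysis_window_s: float = 60.0,
                 ) -> tuple[Recording, pd.DataFrame, list[tuple[float, float]]]:
    """Synthesize the EEG stream for a laid-out block timeline.

    Returns the recording, a tidy table of realized oscillator band power
    (variance of the stored oscillator component) per analysis epoch, and
    the injected artifact segment boundaries.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rate = params.rate
    duration = blocks[-1].end
    n = int(round(duration * rate))
    signal = np.zeros((len(params.montage), n))

    # analysis epochs used for ground-truth power bookkeeping
    epochs = []
    for b in blocks:
        if b.role == "video":
            epochs.append((b.trial, "video", b.condition, b.occurrence,
                           b.start + fade_s, analysis_window_s))
        elif b.role == "isi":
            epochs.append((b.trial, "isi", b.condition, b.occurrence,
                           b.start, analysis_window_s))

    gt_rows = []
    video_blocks = [b for b in blocks if b.role == "video"]
    t_grid = np.arange(n) / rate
    for ci, ch in enumerate(params.montage):
        total = pink_noise(n, rate, params.background_exponent,
                           params.background_scale_uv, rng)
        if params.sensor_noise_uv > 0:
            total += params.sensor_noise_uv * rng.standard_normal(n)
        if params.line_noise_uv > 0:
            amp = params.line_noise_uv * (0.5 + rng.random())
            total += amp * np.sin(2 * np.pi * params.line_freq_hz * t_grid
                                  + rng.uniform(0, 2 * np.pi))
        for band, amp in params.osc_amplitude_uv.items():
            if amp == 0:
                continue
            # amplitude follows the sinusoid convention: variance = A^2/2
            comp = (amp / math.sqrt(2)) * bandlimited_noise(n, rate,
                                                            BANDS[band], rng)
            for b in video_blocks:
                mod = _gain_envelope(b, params, band, ch, rate, n, fade_s)
                if mod is not None:
                    sl, env = mod
                    comp[sl] *= env
            for trial, role, cond, occ, t0, dur in epochs:
                i0 = int(np.floor(t0 * rate))
                i1 = i0 + int(round(dur * rate))
                gt_rows.append((trial, role, cond, occ, ch, band,
                                float(comp[i0:i1].var())))
            total += comp
        signal[ci] = total

    artifact_segments: list[tuple[float, float]] = []
    if group == "walking":
        artifact_segments = _inject_gait_artifacts(signal, blocks, params, rng)

    gt = pd.DataFrame(gt_rows, columns=["trial", "role", "condition",
                                        "occurrence", "channel", "band", "power"])
    rec = Recording(samples=signal, rate=rate, labels=params.montage,
                    unit="uV", start_time=0.0)
    return rec, gt, artifact_segments


def _inject_gait_artifacts(signal: np.ndarray, blocks: list[Block],
                           params: EEGGenParams, rng: np.random.Generator,
                           ) -> list[tuple[float, float]]:
    """Periodic step-locked bursts (cadence + harmonics) during treadmill
    blocks of the walking group.  Mutates ``signal`` in place."""
    art = params.artifact
    rate = params.rate
    n = signal.shape[1]
    weights = 0.5 + rng.random(signal.shape[0])  # per-channel susceptibility
    segments: list[tuple[float, float]] = []
    treadmill_roles = ("baseline_walking", "isi", "video")
    nb = int(round(art.burst_duration_s * rate))
    t_b = np.arange(nb) / rate
    window = np.hanning(nb)
    for b in blocks:
        if b.role not in treadmill_roles:
            continue
        step_period = 1.0 / art.cadence_hz
        t_step = b.start + rng.uniform(0, step_period)
        while t_step + art.burst_duration_s < b.end:
            i0 = int(np.floor(t_step * rate))
            if i0 + nb > n:
                break
            phase = rng.uniform(0, 2 * np.pi)
            burst = np.zeros(nb)
            for h in range(1, art.n_harmonics + 1):
                burst += np.sin(2 * np.pi * h * art.cadence_hz * t_b + phase) / h
            burst += 0.5 * rng.standard_normal(nb)
            burst *= window * art.burst_amplitude_uv
            signal[:, i0:i0 + nb] += weights[:, None] * burst[None, :]
            segments.append((t_step, t_step + art.burst_duration_s))
            t_step += step_period
    return segments


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def bateman(t: np.ndarray, tau1: float, tau2: float,
            normalize: str = "max") -> np.ndarray:
    """Bateman impulse response ``exp(-t/tau1) - exp(-t/tau2)`` for t >= 0.

    With ``normalize="max"`` the kernel peaks at 1, so an event of amplitude
    ``a`` produces an SCR whose peak height is ``a``.
    """
    if tau1 <= 0 or tau2 <= 0 or tau1 == tau2:
        raise ValueError("taus must be positive and distinct")
    b = np.exp(-t / tau1) - np.exp(-t / tau2)
    b[t < 0] = 0.0
    if normalize == "max":
        peak = b.max()
        if peak > 0:
            b = b / peak
    return b


def generate_eda(params: EDAGenParams, blocks: list[Block], group: str,
                 rng: np.random.Generator,
                 ) -> tuple[Recording, pd.DataFrame, np.ndarray, np.ndarray]:
    """Synthesize the EDA stream.

    Returns (recording, scr_events, tonic, noiseless) where ``tonic`` and
    ``noiseless`` allow exact reconstruction checks: ``noiseless`` equals
    ``tonic + sum_i a_i b(t - t_i)`` to machine precision.
    """
    rate = params.rate
    duration = blocks[-1].end
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    level = params.tonic_level_us
    if group == "walking":
        level = level + params.walking_offset_us
    # slow tonic drift: one Gaussian node per drift_timescale_s, smoothed,
    # cubic-interpolated to the sampling grid and scaled to drift_scale
    n_nodes = max(int(duration / params.drift_timescale_s), 4)
    raw = np.convolve(rng.standard_normal(n_nodes + 4), np.ones(3) / 3,
                      mode="valid")
    drift = np.interp(np.linspace(0, 1, n),
                      np.linspace(0, 1, raw.size), raw)
    sd = drift.std()
    drift = drift * (params.drift_scale_us / sd) if sd > 0 else drift * 0
    tonic = level + drift - drift.mean()

    kern_dur = 10.0 * max(params.tau1_s, params.tau2_s)
    kt = np.arange(int(kern_dur * rate)) / rate
    kernel = bateman(kt, params.tau1_s, params.tau2_s)

    factor = params.walking_rate_factor if group == "walking" else 1.0
    events = []
    phasic = np.zeros(n)
    for b in blocks:
        if b.role == "video":
            rate_min = params.scr_rate_per_min.get(b.condition, 4.0)
        elif b.role == "isi":
            rate_min = params.scr_rate_per_min.get("isi", 4.0)
        else:
            rate_min = params.scr_rate_per_min.get("baseline", 4.0)
        lam = rate_min * factor * b.duration / 60.0
        k = rng.poisson(lam)
        times = np.sort(b.start + rng.random(k) * b.duration)
        amps = params.amp_median_us * np.exp(params.amp_sigma
                                             * rng.standard_normal(k))
        for ti, ai in zip(times, amps):
            i0 = int(np.floor(ti * rate))
            m = min(kernel.size, n - i0)
            if m > 0:
                phasic[i0:i0 + m] += ai * kernel[:m]
            events.append((float(ti), float(ai), b.role, b.trial))

    noiseless = tonic + phasic
    trace = noiseless + params.noise_sd_us * rng.standard_normal(n)
    np.maximum(trace, 0.0, out=trace)
    ev = pd.DataFrame(events, columns=["time_s", "amplitude_us", "role", "trial"])
    rec = Recording(samples=trace[None, :], rate=rate, labels=("EDA",),
                    unit="uS", start_time=0.0)
    return rec, ev, tonic, noiseless


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def generate_sam(conditions: list[tuple[int, str]], params: SAMGenParams,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Integer SAM ratings (arousal + valence) for each presented video.

    ``conditions`` is a list of (trial, condition-label).  Ratings are the
    latent condition mean plus Gaussian noise, rounded half-up and clamped
    to the 1-9 scale.
    """
    rows = []
    for trial, cond in conditions:
        ar = params.latent_arousal[cond] + params.noise_sd * rng.standard_normal()
        va = params.latent_valence[cond] + params.noise_sd * rng.standard_normal()
        rows.append((trial, cond,
                     int(np.clip(_round_half_up(np.asarray(ar)), 1, 9)),
                     int(np.clip(_round_half_up(np.asarray(va)), 1, 9))))
    return pd.DataFrame(rows, columns=["trial", "condition", "arousal", "valence"])


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

def generate_session(design: DesignSpec, group: str,
                     eeg: EEGGenParams | None = None,
                     eda: EDAGenParams | None = None,
                     sam: SAMGenParams | None = None,
                     seed: int = 0, participant: str = "P01",
                     ) -> tuple[Session, GroundTruth]:
    """Generate one complete synchronized session plus its ground truth.

    Identical ``(design, group, params, seed)`` yield bit-identical output.
    """
    design.validate()
    eeg = eeg or EEGGenParams()
    eda = eda or EDAGenParams()
    sam = sam or SAMGenParams()
    ss = np.random.SeedSequence(seed)
    rng_eeg, rng_eda, rng_sam, rng_misc = (np.random.default_rng(s)
                                           for s in ss.spawn(4))

    blocks = design.blocks(group)
    eeg_rec, gt_power, art_segs = generate_eeg(
        eeg, blocks, group, rng_eeg, fade_s=design.fade_s,
        analysis_window_s=design.video_duration_s - 2 * design.fade_s)
    eda_rec, scr_events, tonic, noiseless = generate_eda(eda, blocks, group, rng_eda)

    videos = [(b.trial, b.condition) for b in blocks if b.role == "video"]
    sam_df = generate_sam(videos, sam, rng_sam)
    sam_df.insert(2, "occurrence",
                  [b.occurrence for b in blocks if b.role == "video"])

    latent_rows = [(tr, c, sam.latent_arousal[c], sam.latent_valence[c])
                   for tr, c in videos]
    presence = float(3.5 + 0.5 * rng_misc.standard_normal())

    markers = markers_from_blocks(blocks)
    meta = {"participant": participant, "group": group,
            "schedule": design.order, "seed": int(seed),
            "presence_score": presence}
    session = Session(eeg=eeg_rec, eda=eda_rec, markers=markers,
                      sam=sam_df, meta=meta)
    gt = GroundTruth(
        band_power=gt_power, scr_events=scr_events, eda_tonic=tonic,
        eda_noiseless=noiseless,
        sam_latent=pd.DataFrame(latent_rows,
                                columns=["trial", "condition", "arousal", "valence"]),
        artifact_segments=art_segs, condition_gains=eeg.condition_gains)
    return session, gt


def trial_blocks(n_trials: int, condition: str = "Gr",
                 isi_s: float = 60.0, video_s: float = 64.0) -> list[Block]:
    """A minimal timeline of ``n_trials`` ISI+video pairs of one condition
    (calibration experiments; no baselines)."""
    out: list[Block] = []
    t = 0.0
    for i in range(1, n_trials + 1):
        out.append(Block(role="isi", start=t, duration=isi_s,
                         condition=condition, trial=i, occurrence=condition))
        t += isi_s
        out.append(Block(role="video", start=t, duration=video_s,
                         condition=condition, trial=i, occurrence=condition))
        t += video_s
    return out
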