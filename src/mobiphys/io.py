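"""Session containers, native fixture-format I/O, and design-defined epoching.

A session bundles synchronized multi-stream recordings (EEG in microvolts,
EDA in microsiemens), an event-marker stream, per-trial SAM self-reports and
participant metadata on one common clock.  The native on-disk format is a
directory of plain-text files: ``session.json`` (metadata + stream info) and
one CSV per stream.  XDF import is available when the optional ``pyxdf``
package is installed.

Time convention: half-open intervals ``[start, end)`` in seconds on the
session clock; sample index of time ``t`` in a stream starting at
``start_time`` is ``floor((t - start_time) * rate)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec, Block

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


class MissingStreamError(KeyError):
    """A stream required by the analysis is absent from the session."""


@dataclass
class Recording:
    """A uniformly sampled multichannel time series."""

    samples: np.ndarray        # (channels, time)
    rate: float                # Hz
    labels: tuple[str, ...]
    unit: str = ""             # "uV" (EEG) or "uS" (EDA)
    start_time: float = 0.0    # seconds on the session clock

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = tuple(self.labels)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def sample_index(self, t: float) -> int:
        """Index of the sample covering session time ``t`` (floor convention)."""
        return int(np.floor((t - self.start_time) * self.rate))

    def slice(self, start: float, end: float) -> np.ndarray:
        """Samples in the half-open window ``[start, end)`` seconds.

        Raises ``ValueError`` if the window is not fully covered.
        """
        i0 = self.sample_index(start)
        n = int(round((end - start) * self.rate))
        if i0 < 0 or i0 + n > self.n_samples:
            raise ValueError(
                f"window [{start}, {end}) outside recording "
                f"[{self.start_time}, {self.start_time + self.duration})")
        return self.samples[:, i0:i0 + n]

    def copy_with(self, samples: np.ndarray, rate: float | None = None) -> "Recording":
        return Recording(samples=samples, rate=self.rate if rate is None else rate,
                         labels=self.labels, unit=self.unit, start_time=self.start_time)


@dataclass
class MarkerStream:
    """Timestamped string events on the session clock."""

    times: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = tuple(self.labels)
        if self.times.shape[0] != len(self.labels):
            raise ValueError("one label per timestamp required")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("marker timestamps must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "label": self.labels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerStream":
        return cls(times=df["time_s"].to_numpy(), labels=tuple(df["label"]))


@dataclass
class Session:
    """Synchronized streams + markers + self-reports + metadata."""

    eeg: Recording | None
    eda: Recording | None
    markers: MarkerStream
    sam: pd.DataFrame          # columns: trial, condition, occurrence, arousal, valence
    meta: dict = field(default_factory=dict)

    def require(self, stream: str) -> Recording:
        rec = getattr(self, stream, None)
        if rec is None:
            raise MissingStreamError(f"missing {stream.upper()} stream")
        return rec


# ---------------------------------------------------------------------------
# Native fixture format
# ---------------------------------------------------------------------------

def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to ``path`` in the native text format.

    Layout: ``session.json`` with metadata and per-stream info, one CSV per
    numeric stream (wide, one column per channel), ``markers.csv`` and
    ``sam.csv``.  Floats are written with shortest round-trip repr, so a
    read-back reproduces the samples exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    info: dict = {"format_version": FORMAT_VERSION, "meta": session.meta, "streams": {}}
    for name in ("eeg", "eda"):
        rec = getattr(session, name)
        if rec is None:
            continue
        info["streams"][name] = {
            "rate": rec.rate, "unit": rec.unit, "start_time": rec.start_time,
            "labels": list(rec.labels), "file": f"{name}.csv",
        }
        pd.DataFrame(rec.samples.T, columns=list(rec.labels)).to_csv(
            path / f"{name}.csv", index=False)
    session.markers.to_frame().to_csv(path / "markers.csv", index=False)
    session.sam.to_csv(path / "sam.csv", index=False)
    (path / "session.json").write_text(json.dumps(info, indent=1))
    return path


def _read_native(path: Path, require: tuple[str, ...]) -> Session:
    info = json.loads((path / "session.json").read_text())
    streams: dict[str, Recording | None] = {"eeg": None, "eda": None}
    for name, s in info.get("streams", {}).items():
        df = pd.read_csv(path / s["file"], float_precision="round_trip")
        streams[name] = Recording(
            samples=df.to_numpy().T, rate=float(s["rate"]),
            labels=tuple(s["labels"]), unit=s.get("unit", ""),
            start_time=float(s.get("start_time", 0.0)))
    for name in require:
        if streams.get(name) is None:
            raise MissingStreamError(f"missing {name.upper()} stream")
    markers = MarkerStream.from_frame(pd.read_csv(path / "markers.csv"))
    sam = pd.read_csv(path / "sam.csv")
    return Session(eeg=streams["eeg"], eda=streams["eda"], markers=markers,
                   sam=sam, meta=info.get("meta", {}))


def _read_xdf(path: Path, require: tuple[str, ...]) -> Session:
    """Read an XDF file (regular-rate numeric streams + string markers).

    Requires the optional ``pyxdf`` dependency.  Streams are expressed on one
    clock by honouring the per-stream recorded timestamps (nearest-sample, no
    resampling): a stream's ``start_time`` is its first timestamp.
    """
    try:
        import pyxdf  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("XDF input requires the optional 'pyxdf' package "
                          "(pip install mobiphys[xdf])") from exc
    xstreams, _ = pyxdf.load_xdf(str(path))  # pragma: no cover
    eeg = eda = None
    mk_t: list[float] = []
    mk_l: list[str] = []
    for s in xstreams:  # pragma: no cover
        stype = s["info"]["type"][0].lower()
        rate = float(s["info"]["nominal_srate"][0])
        if stype == "markers" or rate == 0:
            mk_t.extend(float(t) for t in s["time_stamps"])
            mk_l.extend(str(v[0]) for v in s["time_series"])
            continue
        labels = tuple(
            ch["label"][0]
            for ch in s["info"]["desc"][0]["channels"][0]["channel"])
        rec = Recording(samples=np.asarray(s["time_series"]).T, rate=rate,
                        labels=labels, start_time=float(s["time_stamps"][0]))
        if stype == "eeg":
            eeg = rec
        else:
            eda = rec
    order = np.argsort(mk_t, kind="stable")  # pragma: no cover
    markers = MarkerStream(np.asarray(mk_t)[order],
                           tuple(mk_l[i] for i in order))  # pragma: no cover
    sess = Session(eeg=eeg, eda=eda, markers=markers,
                   sam=pd.DataFrame(columns=["trial", "condition", "occurrence",
                                             "arousal", "valence"]))  # pragma: no cover
    for name in require:  # pragma: no cover
        sess.require(name)
    return sess  # pragma: no cover


def read_session(path: str | Path, format: str = "native",
                 require: tuple[str, ...] = ()) -> Session:
    """Load a session from disk.

    Parameters
    ----------
    path
        Session directory (native format) or ``.xdf`` file.
    format
        ``"native"`` or ``"xdf"``.
    require
        Stream names (``"eeg"``, ``"eda"``) that must be present; a missing
        required stream raises :class:`MissingStreamError`.
    """
    path = Path(path)
    if format == "native":
        return _read_native(path, require)
    if format == "xdf":
        return _read_xdf(path, require)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Markers and epochs
# ---------------------------------------------------------------------------

def markers_from_blocks(blocks: list[Block]) -> MarkerStream:
    """Start/end markers for every block, labelled ``role:occurrence:trial``."""
    times: list[float] = []
    labels: list[str] = []
    for b in blocks:
        tag = f"{b.role}:{b.occurrence or '-'}:{b.trial}"
        times.append(b.start)
        labels.append(tag + ":start")
        times.append(b.end)
        labels.append(tag + ":end")
    order = np.argsort(times, kind="stable")
    return MarkerStream(np.asarray(times)[order], tuple(labels[i] for i in order))


def blocks_from_markers(markers: MarkerStream) -> list[Block]:
    """Reconstruct the block list from start/end markers."""
    open_blocks: dict[tuple, float] = {}
    out: list[Block] = []
    for t, label in zip(markers.times, markers.labels):
        parts = label.split(":")
        if len(parts) != 4:
            continue
        role, occ, trial, edge = parts
        key = (role, occ, int(trial))
        if edge == "start":
            open_blocks[key] = t
        elif edge == "end" and key in open_blocks:
            start = open_blocks.pop(key)
            cond = "Gr" if occ.startswith("G") and occ not in ("Gr",) else occ
            out.append(Block(role=role, start=start, duration=t - start,
                             condition="" if occ == "-" else cond,
                             trial=int(trial), occurrence="" if occ == "-" else occ))
    out.sort(key=lambda b: b.start)
    return out


@dataclass(frozen=True)
class Epoch:
    """One analysis window cut from the session timeline."""

    participant: str
    group: str
    condition: str       # pooled label (Gr for both green trials)
    occurrence: str      # G1/G2 for the greens, else == condition
    trial: int           # 1-based video trial index, 0 for baselines
    role: str            # "video", "isi" or "baseline"
    start: float
    duration: float

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class EpochSet:
    """Paired video/ISI epochs plus baseline epochs and logged exclusions."""

    epochs: list[Epoch]
    exclusions: list[dict] = field(default_factory=list)

    def videos(self) -> list[Epoch]:
        return [e for e in self.epochs if e.role == "video"]

    def isis(self) -> list[Epoch]:
        return [e for e in self.epochs if e.role == "isi"]

    def baselines(self) -> list[Epoch]:
        return [e for e in self.epochs if e.role == "baseline"]

    def pairs(self) -> list[tuple[Epoch, Epoch]]:
        """(video, isi) epoch pairs matched by trial index."""
        isi_by_trial = {e.trial: e for e in self.isis()}
        return [(v, isi_by_trial[v.trial]) for v in self.videos()
                if v.trial in isi_by_trial]


def extract_epochs(session: Session, design: DesignSpec,
                   analysis_window_s: float | None = None) -> EpochSet:
    """Cut design-defined epochs from a session's marker stream.

    Per video trial: one video epoch of ``analysis_window_s`` seconds
    starting ``fade_s`` after video onset (the fade-in/fade-out periods are
    excluded) and one ISI epoch of the same length starting at the preceding
    fixation onset.  Baseline blocks become ``role="baseline"`` epochs.
    Trials whose blocks are missing or truncated (relative to the recorded
    stream extents) are excluded with a logged reason.
    """
    win = (design.video_duration_s - 2 * design.fade_s
           if analysis_window_s is None else analysis_window_s)
    blocks = blocks_from_markers(session.markers)
    meta = session.meta
    pid = str(meta.get("participant", "P00"))
    group = str(meta.get("group", ""))

    # extent actually covered by all present streams
    extents = []
    for name in ("eeg", "eda"):
        rec = getattr(session, name)
        if rec is not None:
            extents.append((rec.start_time, rec.start_time + rec.duration))
    t_lo = max(e[0] for e in extents) if extents else -np.inf
    t_hi = min(e[1] for e in extents) if extents else np.inf

    epochs: list[Epoch] = []
    exclusions: list[dict] = []

    def covered(start: float, dur: float) -> bool:
        return start >= t_lo - 1e-9 and start + dur <= t_hi + 1e-9

    videos = {b.trial: b for b in blocks if b.role == "video"}
    isis = {b.trial: b for b in blocks if b.role == "isi"}
    for trial in range(1, 7):
        v, i = videos.get(trial), isis.get(trial)
        if v is None or i is None:
            exclusions.append({"trial": trial, "reason": "missing block markers"})
            logger.warning("trial %d excluded: missing block markers", trial)
            continue
        v_start = v.start + design.fade_s
        if v.duration + 1e-9 < design.video_duration_s or not covered(v_start, win):
            exclusions.append({"trial": trial, "reason": "truncated video block"})
            logger.warning("trial %d excluded: truncated video block", trial)
            continue
        if i.duration + 1e-9 < win or not covered(i.start, win):
            exclusions.append({"trial": trial, "reason": "truncated isi block"})
            logger.warning("trial %d excluded: truncated isi block", trial)
            continue
        common = dict(participant=pid, group=group, condition=v.condition,
                      occurrence=v.occurrence, trial=trial)
        epochs.append(Epoch(role="video", start=v_start, duration=win, **common))
        epochs.append(Epoch(role="isi", start=i.start, duration=win, **common))

    for b in blocks:
        if b.role.startswith("baseline") and covered(b.start, b.duration):
            epochs.append(Epoch(participant=pid, group=group, condition="",
                                occurrence=b.role, trial=0, role="baseline",
                                start=b.start, duration=b.duration))
    return EpochSet(epochs=epochs, exclusions=exclusions)
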