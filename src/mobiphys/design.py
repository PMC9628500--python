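"""Experimental block design: conditions, counterbalancing, and session timeline.

The paradigm is a 2 (group: walking vs standing, between subjects) x 5
(environment: green Gr, indoor crowded IC, indoor uncrowded IU, outdoor
crowded OC, outdoor uncrowded OU, within subjects) design.  Six one-minute
walk-through videos are shown (the green space twice, G1/G2), each preceded
by a 60 s fixation-cross inter-stimulus interval that serves as the
per-trial baseline.  Before the main phase every participant provides a
180 s seated reading baseline and a 60 s seated fixation baseline; the
walking group additionally provides a 180 s walking fixation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

CONDITIONS = ("Gr", "IC", "IU", "OC", "OU")
GROUPS = ("walking", "standing")

#: Forward counterbalance order of the six videos (Gr shown twice).
FORWARD_ORDER = ("Gr", "IC", "OU", "Gr", "OC", "IU")
REVERSE_ORDER = tuple(reversed(FORWARD_ORDER))

#: Roles a block can play in the timeline.
ROLES = ("baseline_reading", "baseline_sitting", "baseline_walking", "isi", "video")


@dataclass(frozen=True)
class Block:
    """One contiguous segment of the session timeline.

    ``condition`` is the environment label for video/isi blocks (the ISI
    carries the condition of the video it precedes); ``trial`` is the 1-based
    video trial index (0 for baselines).  ``occurrence`` distinguishes the
    two green presentations (G1/G2); it equals the condition label for the
    non-repeated conditions.
    """

    role: str
    start: float          # seconds on the session clock
    duration: float       # seconds
    condition: str = ""
    trial: int = 0
    occurrence: str = ""

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DesignSpec:
    """Timing parameters and counterbalance order of a session."""

    video_duration_s: float = 64.0
    fade_s: float = 2.0
    isi_duration_s: float = 60.0
    reading_baseline_s: float = 180.0
    sitting_baseline_s: float = 60.0
    walking_baseline_s: float = 180.0
    order: str = "forward"  # "forward" or "reverse"

    def __post_init__(self) -> None:
        if self.order not in ("forward", "reverse"):
            raise ValueError(f"unknown counterbalance order {self.order!r}")
        for name in ("video_duration_s", "isi_duration_s", "reading_baseline_s",
                     "sitting_baseline_s", "walking_baseline_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fade_s < 0 or 2 * self.fade_s >= self.video_duration_s:
            raise ValueError("fades must be nonnegative and shorter than the video")

    @property
    def sequence(self) -> tuple[str, ...]:
        return FORWARD_ORDER if self.order == "forward" else REVERSE_ORDER

    def blocks(self, group: str) -> list[Block]:
        """Lay out the session timeline for ``group`` as contiguous blocks.

        Blocks tile the timeline without gaps or overlap; every video block
        is immediately preceded by its ISI fixation block.
        """
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        out: list[Block] = []
        t = 0.0

        def push(role: str, dur: float, condition: str = "", trial: int = 0,
                 occurrence: str = "") -> None:
            nonlocal t
            out.append(Block(role=role, start=t, duration=dur,
                             condition=condition, trial=trial,
                             occurrence=occurrence))
            t += dur

        push("baseline_reading", self.reading_baseline_s)
        push("baseline_sitting", self.sitting_baseline_s)
        if group == "walking":
            push("baseline_walking", self.walking_baseline_s)

        n_green = 0
        for i, cond in enumerate(self.sequence, start=1):
            if cond == "Gr":
                n_green += 1
                occ = f"G{n_green}"
            else:
                occ = cond
            push("isi", self.isi_duration_s, condition=cond, trial=i, occurrence=occ)
            push("video", self.video_duration_s, condition=cond, trial=i, occurrence=occ)
        return out

    def total_duration(self, group: str) -> float:
        return self.blocks(group)[-1].end

    def validate(self) -> None:
        """Check the design invariants; raise ``ValueError`` on violation."""
        seq = self.sequence
        if len(seq) != 6:
            raise ValueError("exactly 6 video presentations required")
        if seq.count("Gr") != 2:
            raise ValueError("the green condition must appear exactly twice")
        if seq not in (FORWARD_ORDER, REVERSE_ORDER):
            raise ValueError("sequence must be the printed order or its exact reverse")
        for group in GROUPS:
            blocks = self.blocks(group)
            for a, b in zip(blocks, blocks[1:]):
                if abs(a.end - b.start) > 1e-9:
                    raise ValueError("blocks must tile the timeline without gaps")
            videos = [b for b in blocks if b.role == "video"]
            for v in videos:
                i = blocks.index(v)
                prev = blocks[i - 1]
                if prev.role != "isi" or abs(prev.duration - self.isi_duration_s) > 1e-9:
                    raise ValueError("every video must follow a full ISI fixation block")


def scaled_design(scale: float = 1.0, **overrides) -> DesignSpec:
    """A DesignSpec with all durations multiplied by ``scale`` (test helper).

    Fades scale too, so the analysed video window remains
    ``video_duration_s - 2*fade_s``.
    """
    base = DesignSpec()
    spec = DesignSpec(
        video_duration_s=base.video_duration_s * scale,
        fade_s=base.fade_s * scale,
        isi_duration_s=base.isi_duration_s * scale,
        reading_baseline_s=base.reading_baseline_s * scale,
        sitting_baseline_s=base.sitting_baseline_s * scale,
        walking_baseline_s=base.walking_baseline_s * scale,
    )
    return replace(spec, **overrides) if overrides else spec
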