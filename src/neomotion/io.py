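"""Frame-sequence ingestion and arousal-state segment screening.

Overhead recordings of a supine infant arrive either as a directory of
numbered grayscale images or as a multi-page TIFF stack.  Alongside the
pixels there is a manual annotation track: half-open frame intervals
labelled ``awake`` or ``sleep``, with an exclusion flag for stretches that
must not enter the analysis (crying/fussing, deep sleep, nurse
intervention, abrupt-onset noise).  This module reads both, validates
them, and produces the clean per-state frame runs that the motion layer
consumes.

Conventions
-----------
* Frame indices are 0-based; intervals are half-open ``[start, end)``.
* Unlabeled frames are dropped, never imputed.
* Exclusion labels are consumed as given — arousal state and exclusion
  decisions are made by a human rater, not inferred from pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "AnnotationTrack",
    "StateSegments",
    "read_frame_sequence",
    "load_annotations",
    "screen_segments",
    "STATES",
    "EXCLUSION_REASONS",
]

STATES = ("awake", "sleep")
EXCLUSION_REASONS = ("cry_fuss", "deep_sleep", "intervention", "noise_onset", "none")

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Default minimum retained run length in frames (3 s at 30 fps), so the
#: spectral windows of the feature layer fit inside a run.
DEFAULT_MIN_RUN = 90


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with its frame rate.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Grayscale intensities.
    fps : float
        Frames per second (nominal 30 for the recording setup emulated here).
    max_intensity : float
        Declared top of the intensity range (255 for 8-bit input).
    """

    frames: np.ndarray
    fps: float = 30.0
    max_intensity: float = 255.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, height, width), got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class Interval:
    """One annotated half-open frame interval."""

    start: int
    end: int
    state: str
    excluded: bool = False
    reason: str = "none"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationTrack:
    """Validated, sorted, non-overlapping annotation intervals."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals [{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def n_labeled_frames(self) -> int:
        return sum(iv.n_frames for iv in self.intervals)

    @property
    def n_excluded_frames(self) -> int:
        return sum(iv.n_frames for iv in self.intervals if iv.excluded)


@dataclass
class StateSegments:
    """Retained frame runs per arousal state after screening."""

    runs: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {s: [] for s in STATES}
    )

    def n_frames(self, state: str) -> int:
        return sum(e - s for s, e in self.runs[state])

    def has_state(self, state: str) -> bool:
        return bool(self.runs[state])


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame.astype(np.float64)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return frame[..., :3].astype(np.float64) @ _LUMA
    raise ValueError(f"cannot interpret frame of shape {frame.shape} as an image")


def read_frame_sequence(
    path: str | Path,
    *,
    fps: float | None = None,
    max_intensity: float = 255.0,
) -> FrameSequence:
    """Read a frame sequence from a directory of numbered images or an image stack.

    Color frames are converted to grayscale with fixed Rec. 601 luma
    weights.  The frame rate is taken, in order of precedence, from the
    ``fps`` argument, a JSON sidecar (``<stem>.json`` next to a stack, or
    ``meta.json`` inside a directory) with an ``fps`` key, or the default
    of 30.

    Raises
    ------
    FileNotFoundError
        If the path does not exist or a directory holds no images.
    ValueError
        If frames disagree in size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    sidecar: Path
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in directory {path}")
        raw = [iio.imread(f) for f in files]
        sidecar = path / "meta.json"
    else:
        stack = iio.imread(path)
        raw = [stack] if stack.ndim == 2 else list(stack)
        sidecar = path.with_suffix(".json")

    gray = [_to_gray(np.asarray(f)) for f in raw]
    shapes = {g.shape for g in gray}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame sizes: {sorted(shapes)}")

    if fps is None:
        fps = 30.0
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fps = float(meta.get("fps", fps))

    return FrameSequence(np.stack(gray), fps=fps, max_intensity=max_intensity)


_REQUIRED_COLUMNS = ["start_frame", "end_frame", "state", "excluded", "reason"]


def load_annotations(path: str | Path, n_frames: int | None = None) -> AnnotationTrack:
    """Load an annotation CSV into a validated :class:`AnnotationTrack`.

    The CSV carries the manual labels (columns ``start_frame, end_frame,
    state, excluded, reason``).  Intervals are sorted and, when the
    sequence length is known, clipped to ``[0, n_frames)``.

    Raises
    ------
    ValueError
        On missing columns, malformed rows (``end <= start``, unknown
        state/reason), or overlapping intervals; the message lists the
        offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV missing columns: {missing}")

    intervals, bad_rows = [], []
    for idx, row in df.iterrows():
        start, end = int(row.start_frame), int(row.end_frame)
        if n_frames is not None:
            start, end = max(start, 0), min(end, n_frames)
            if end <= start:
                continue  # interval entirely outside the sequence
        try:
            intervals.append(
                Interval(start, end, str(row.state).strip(),
                         bool(int(row.excluded)), str(row.reason).strip())
            )
        except ValueError as exc:
            bad_rows.append(f"row {idx}: {exc}")
    if bad_rows:
        raise ValueError("invalid annotation rows:\n" + "\n".join(bad_rows))
    return AnnotationTrack(intervals)


def screen_segments(
    track: AnnotationTrack,
    min_run: int = DEFAULT_MIN_RUN,
) -> StateSegments:
    """Apply the segment-screening rules to an annotation track.

    Excluded intervals (crying/fussing, deep sleep, intervention,
    abrupt-onset noise) are removed; the remaining intervals are split by
    arousal state, contiguous same-state intervals are merged, and runs
    shorter than ``min_run`` frames are dropped.  An empty retained set for
    a state is not an error — that state is simply absent for the infant.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    segs = StateSegments()
    for state in STATES:
        kept = [(iv.start, iv.end) for iv in track.intervals
                if iv.state == state and not iv.excluded]
        merged: list[tuple[int, int]] = []
        for start, end in kept:
            if merged and start == merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
            else:
                merged.append((start, end))
        segs.runs[state] = [(s, e) for s, e in merged if e - s >= min_run]
    return segs
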