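"""Silhouette extraction, iCOG trajectories and regional motion magnitudes.

Two classic computer-vision primitives drive the whole feature set:

* **Background subtraction.**  A per-pixel temporal median over the run
  gives a background estimate that is robust to the moving infant.
  Thresholding ``|frame - background|`` (plus one morphological opening
  to suppress speckle) yields a binary body silhouette, and the mean
  foreground coordinate is the image centre of gravity (iCOG).  From the
  iCOG trajectory we derive per-axis velocities ``G^v`` (first
  differences) and fluctuations ``G^d`` (deviation from a centred moving
  average, i.e. the detrended wobble about the slow postural drift).

* **Interframe differencing.**  For each analysis region ``A_k`` —
  upper body ``A5``, lower body ``A6``, whole body ``A9`` — the motion
  magnitude ``M^(Ak)(t)`` is the fraction of region pixels whose
  intensity changed by more than a threshold between consecutive frames.

Axis convention: image ``x`` (columns) is the infant's longitudinal
head–foot axis; the region builder and the synthetic renderer both
enforce this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_opening

from .io import FrameSequence

__all__ = [
    "RegionSpec",
    "MotionTimeSeries",
    "estimate_background",
    "extract_silhouette",
    "compute_icog",
    "icog_series",
    "motion_series",
    "build_regions",
    "REGION_IDS",
    "DEFAULT_BIN_THRESHOLD",
    "DEFAULT_DIFF_THRESHOLD",
    "DEFAULT_DETREND_WINDOW_S",
]

REGION_IDS = ("A5_upper", "A6_lower", "A9_whole")

# Binarization thresholds on a 0-255 intensity scale; config values, not
# physical constants.
DEFAULT_BIN_THRESHOLD = 15.0
DEFAULT_DIFF_THRESHOLD = 10.0
#: Width in seconds of the centred moving average defining the iCOG trend.
DEFAULT_DETREND_WINDOW_S = 2.0
#: Width in seconds of the flicker-suppression smoothing of M^(Ak).
DEFAULT_MOTION_SMOOTH_S = 0.2
#: Runs with more than this fraction of empty-silhouette frames are rejected.
MAX_MISSING_FRACTION = 0.20


@dataclass
class RegionSpec:
    """Binary pixel masks for the three analysis regions.

    ``A5`` (upper body) and ``A6`` (lower body) are disjoint halves of the
    body bounding box split along its long axis; ``A9`` (whole body) is
    the full box, so ``A5 ∪ A6 ⊆ A9``.
    """

    masks: dict[str, np.ndarray]
    split_fraction: float = 0.5

    def __post_init__(self) -> None:
        for rid in REGION_IDS:
            if rid not in self.masks:
                raise ValueError(f"missing region mask {rid}")
        a5, a6, a9 = (self.masks[r].astype(bool) for r in REGION_IDS)
        if a5.shape != a6.shape or a5.shape != a9.shape:
            raise ValueError("region masks disagree in shape")
        if np.any(a5 & a6):
            raise ValueError("A5 and A6 overlap")
        if np.any((a5 | a6) & ~a9):
            raise ValueError("A5 ∪ A6 must lie inside A9")

    def mask(self, region_id: str) -> np.ndarray:
        return self.masks[region_id]

    def area(self, region_id: str) -> int:
        return int(self.masks[region_id].sum())


@dataclass
class MotionTimeSeries:
    """Per-frame motion observables for one screened run.

    ``icog_x/icog_y`` have length ``n_frames``; the velocities are first
    differences (length ``n_frames - 1``), as are the interframe motion
    magnitudes ``motion[region_id]`` which live in [0, 1].
    """

    fps: float
    icog_x: np.ndarray | None = None
    icog_y: np.ndarray | None = None
    icog_v_x: np.ndarray | None = None
    icog_v_y: np.ndarray | None = None
    icog_d_x: np.ndarray | None = None
    icog_d_y: np.ndarray | None = None
    motion: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        if self.icog_x is not None:
            return len(self.icog_x)
        if self.motion:
            return len(next(iter(self.motion.values()))) + 1
        return 0

    def merged_with(self, other: "MotionTimeSeries") -> "MotionTimeSeries":
        """Combine iCOG fields of ``self`` with motion fields of ``other``."""
        return MotionTimeSeries(
            fps=self.fps,
            icog_x=self.icog_x, icog_y=self.icog_y,
            icog_v_x=self.icog_v_x, icog_v_y=self.icog_v_y,
            icog_d_x=self.icog_d_x, icog_d_y=self.icog_d_y,
            motion=dict(other.motion),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-frame table (velocity/motion rows padded with NaN at t=0)."""
        n = self.n_frames

        def pad(a):
            if a is None:
                return np.full(n, np.nan)
            if len(a) == n - 1:
                return np.concatenate([[np.nan], a])
            return np.asarray(a, dtype=float)

        cols = {
            "frame": np.arange(n),
            "icog_x": pad(self.icog_x), "icog_y": pad(self.icog_y),
            "gv_x": pad(self.icog_v_x), "gv_y": pad(self.icog_v_y),
            "gd_x": pad(self.icog_d_x), "gd_y": pad(self.icog_d_y),
        }
        for rid in REGION_IDS:
            if rid in self.motion:
                cols[f"m_{rid.split('_')[0].lower()}"] = pad(self.motion[rid])
        return pd.DataFrame(cols)


def estimate_background(seq: FrameSequence, min_frames: int = 3) -> np.ndarray:
    """Per-pixel temporal median of a run — the static-background estimate.

    The median is robust to the infant occupying any given pixel in fewer
    than half of the frames.
    """
    if seq.n_frames < min_frames:
        raise ValueError(
            f"run of {seq.n_frames} frames is too short for background "
            f"estimation (need >= {min_frames}; increase min_run upstream)"
        )
    return np.median(seq.frames, axis=0)


def extract_silhouette(
    frame: np.ndarray,
    background: np.ndarray,
    bin_threshold: float = DEFAULT_BIN_THRESHOLD,
) -> np.ndarray:
    """Binary body mask: ``|frame - background| > threshold``, then one opening."""
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    mask = np.abs(frame.astype(float) - background) > bin_threshold
    # 3x3 square kernel: removes speckle, leaves solid blocks intact
    return binary_opening(mask, structure=np.ones((3, 3), dtype=bool))


def compute_icog(mask: np.ndarray) -> tuple[float, float]:
    """Image centre of gravity of a binary mask, in image coordinates.

    Returns the arithmetic mean of foreground pixel coordinates
    ``(x, y)`` with x rightward (columns) and y downward (rows); an empty
    mask yields ``(nan, nan)`` — a missing sample for the caller to
    interpolate.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return (np.nan, np.nan)
    return (float(cols.mean()), float(rows.mean()))


def _interpolate_nan(values: np.ndarray) -> np.ndarray:
    s = pd.Series(values)
    return s.interpolate(method="linear", limit_direction="both").to_numpy()


def icog_series(
    seq: FrameSequence,
    background: np.ndarray,
    bin_threshold: float = DEFAULT_BIN_THRESHOLD,
    detrend_window: float = DEFAULT_DETREND_WINDOW_S,
) -> MotionTimeSeries:
    """iCOG trajectory of a screened run with velocities and fluctuations.

    Empty-silhouette frames become missing samples; a run with more than
    20% missing is rejected.  Remaining gaps are linearly interpolated
    before differencing.  ``G^v`` is the per-frame displacement;
    ``G^d`` is the trajectory minus its centred moving average of width
    ``detrend_window`` seconds (the slow postural drift), so it captures
    the fast wobble and has near-zero mean over the run.
    """
    xs = np.empty(seq.n_frames)
    ys = np.empty(seq.n_frames)
    for t in range(seq.n_frames):
        xs[t], ys[t] = compute_icog(
            extract_silhouette(seq.frames[t], background, bin_threshold)
        )
    n_missing = int(np.isnan(xs).sum())
    if n_missing > MAX_MISSING_FRACTION * seq.n_frames:
        raise ValueError(
            f"{n_missing}/{seq.n_frames} frames have an empty silhouette "
            f"(> {MAX_MISSING_FRACTION:.0%}); run rejected"
        )
    if np.isnan(xs).all():
        raise ValueError("no frame yielded a silhouette; run rejected")
    xs, ys = _interpolate_nan(xs), _interpolate_nan(ys)

    win = max(3, int(round(detrend_window * seq.fps)) | 1)  # odd, centred
    trend_x = pd.Series(xs).rolling(win, center=True, min_periods=1).mean().to_numpy()
    trend_y = pd.Series(ys).rolling(win, center=True, min_periods=1).mean().to_numpy()

    return MotionTimeSeries(
        fps=seq.fps,
        icog_x=xs, icog_y=ys,
        icog_v_x=np.diff(xs), icog_v_y=np.diff(ys),
        icog_d_x=xs - trend_x, icog_d_y=ys - trend_y,
    )


def motion_series(
    seq: FrameSequence,
    regions: RegionSpec,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    smooth_s: float = DEFAULT_MOTION_SMOOTH_S,
) -> MotionTimeSeries:
    """Interframe-difference motion magnitude ``M^(Ak)`` per region.

    ``M^(Ak)(t)`` is the fraction of pixels of region ``A_k`` whose
    intensity changed by more than ``diff_threshold`` between frames
    ``t-1`` and ``t``; normalizing by region area makes values comparable
    across regions.  A centred moving average of width ``smooth_s``
    seconds suppresses pixel-quantization flicker of the changed-pixel
    count (set 0 to disable); it leaves constant series untouched and
    preserves the [0, 1] range.
    """
    masks, areas = {}, {}
    for rid in REGION_IDS:
        m = regions.mask(rid)
        areas[rid] = int(m.sum())
        if areas[rid] == 0:
            raise ValueError(f"region {rid} has an empty mask")
        masks[rid] = m
    motion = {rid: np.empty(seq.n_frames - 1) for rid in REGION_IDS}
    prev = seq.frames[0].astype(float)
    for t in range(1, seq.n_frames):  # frame pair at a time: bounded memory
        cur = seq.frames[t].astype(float)
        changed = np.abs(cur - prev) > diff_threshold
        for rid in REGION_IDS:
            motion[rid][t - 1] = changed[masks[rid]].sum() / areas[rid]
        prev = cur
    if smooth_s > 0:
        win = max(1, int(round(smooth_s * seq.fps)) | 1)
        for rid in REGION_IDS:
            motion[rid] = (
                pd.Series(motion[rid])
                .rolling(win, center=True, min_periods=1).mean().to_numpy()
            )
    return MotionTimeSeries(fps=seq.fps, motion=motion)


def reference_silhouette(
    seq: FrameSequence,
    background: np.ndarray,
    bin_threshold: float = DEFAULT_BIN_THRESHOLD,
) -> np.ndarray:
    """Temporal OR of per-frame silhouettes — the body's overall footprint."""
    ref = np.zeros(seq.frames.shape[1:], dtype=bool)
    for t in range(seq.n_frames):
        ref |= extract_silhouette(seq.frames[t], background, bin_threshold)
    return ref


def build_regions(
    silhouette: np.ndarray,
    split_fraction: float = 0.5,
) -> RegionSpec:
    """Split the body bounding box into upper/lower/whole analysis regions.

    The bounding box of the reference silhouette is split along its long
    axis at ``split_fraction`` of its extent, measured from the low-index
    (head) end: the first part is ``A5`` (head to waist), the rest
    ``A6``; ``A9`` is the full box.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    rows, cols = np.nonzero(silhouette)
    if len(rows) == 0:
        raise ValueError("empty reference silhouette; cannot build regions")
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    if r1 - r0 < 2 or c1 - c0 < 2:
        raise ValueError("degenerate bounding box; cannot split body axis")

    shape = silhouette.shape
    a9 = np.zeros(shape, dtype=bool)
    a9[r0:r1, c0:c1] = True
    a5 = np.zeros(shape, dtype=bool)
    a6 = np.zeros(shape, dtype=bool)
    if (c1 - c0) >= (r1 - r0):  # long axis = image x (longitudinal)
        cut = c0 + int(round(split_fraction * (c1 - c0)))
        a5[r0:r1, c0:cut] = True
        a6[r0:r1, cut:c1] = True
    else:
        cut = r0 + int(round(split_fraction * (r1 - r0)))
        a5[r0:cut, c0:c1] = True
        a6[cut:r1, c0:c1] = True
    return RegionSpec(
        masks={"A5_upper": a5, "A6_lower": a6, "A9_whole": a9},
        split_fraction=split_fraction,
    )
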