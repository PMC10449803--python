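"""The 26 movement evaluation indices, pooled per infant per arousal state.

The indices summarise one infant's screened runs in four families:

a. *Movement magnitude* — per region (upper ``A5``, lower ``A6``):
   ``i1`` movement frequency (% of 1-s analysis windows with
   above-threshold motion), ``i2`` movement strength (mean motion
   magnitude over motion-active frames), ``i3`` movement count (motion
   bouts per minute).
b. *Movement balance* — ``i4 = i1_a5/i1_a6``, ``i5 = i2_a5/i2_a6``, and a
   symmetry score ``i6`` in [0, 1] (Jaccard overlap of the upper- and
   lower-body active-window sets).
c. *Movement rhythm* — power-weighted central frequency and spectral SD
   of the regional motion series (``i7``, ``i8``), of the iCOG velocities
   (``i9``, ``i10``) and of the iCOG fluctuations (``i11``, ``i12``),
   per image axis where applicable.
d. *iCOG movements* — SDs of the iCOG velocities (``i13``) and
   fluctuations (``i14``) per axis, and ``i15``, the area enclosed by the
   outermost circumference (convex hull) of the fluctuation point cloud.

A whole-body movement frequency ``i1_a9`` is kept for the low-movement
exclusion rule: infants with ``i1_a9 <= 5%`` show virtually no
discernible movement and are discarded before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.spatial import ConvexHull, QhullError

from .motion import MotionTimeSeries

__all__ = [
    "SpectralSummary",
    "FEATURE_COLUMNS",
    "IndexParams",
    "spectral_summary",
    "movement_frequency",
    "movement_strength",
    "movement_count",
    "balance_and_symmetry",
    "icog_variability",
    "hull_area",
    "assemble_features",
    "exclusion_rule",
    "active_windows",
    "EXCLUSION_I1_A9_PCT",
]

#: The 26 analysis features, in design-matrix order.
FEATURE_COLUMNS = (
    "i1_a5", "i1_a6", "i2_a5", "i2_a6", "i3_a5", "i3_a6",
    "i4", "i5", "i6",
    "i7_a5", "i7_a6", "i8_a5", "i8_a6",
    "i9x", "i9y", "i10x", "i10y",
    "i11x", "i11y", "i12x", "i12y",
    "i13x", "i13y", "i14x", "i14y",
    "i15",
)

#: Whole-body movement-frequency cut-off (%): at or below it, the infant is
#: treated as showing no discernible movement and discarded.
EXCLUSION_I1_A9_PCT = 5.0


@dataclass(frozen=True)
class IndexParams:
    """Tunable parameters of the index layer.

    active_threshold
        Motion magnitude above which a frame counts as motion-active
        (fraction of region pixels changing; default 1%).
    window_s
        Non-overlapping analysis-window length for movement frequency.
    spectral_window_s
        Segment length of the averaged periodogram (50% overlap, Hann
        taper); its reciprocal is the spectral bin width.
    min_gap_frames
        Bouts separated by fewer inactive frames are merged.
    """

    active_threshold: float = 0.01
    window_s: float = 1.0
    spectral_window_s: float = 10.0
    min_gap_frames: int = 10


@dataclass(frozen=True)
class SpectralSummary:
    """Power-weighted moments of a one-sided power spectrum."""

    central_freq: float
    spectral_sd: float
    total_power: float


def spectral_summary(
    series: np.ndarray,
    fps: float,
    window_s: float = 10.0,
) -> SpectralSummary:
    """Central frequency and spectral SD of a time series.

    The spectrum is an averaged periodogram (Welch: ``window_s``-second
    Hann-tapered segments, 50% overlap) with the zero-frequency bin
    excluded.  ``central_freq`` is the power-weighted mean frequency and
    ``spectral_sd`` the power-weighted SD about it — a small SD means a
    prominent single rhythm, a large SD a lack of rhythmicity.  An
    all-zero (or constant) series has no power: moments come back NaN.
    """
    series = np.asarray(series, dtype=float)
    nperseg = min(len(series), max(8, int(round(window_s * fps))))
    if len(series) < 2 or np.ptp(series) == 0:  # constant: no rhythm at all
        return SpectralSummary(np.nan, np.nan, 0.0)
    freqs, power = signal.welch(
        series, fs=fps, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    freqs, power = freqs[1:], power[1:]  # drop DC
    total = float(power.sum())
    if total <= 0 or not np.isfinite(total):
        return SpectralSummary(np.nan, np.nan, 0.0)
    central = float((freqs * power).sum() / total)
    sd = float(np.sqrt(((freqs - central) ** 2 * power).sum() / total))
    return SpectralSummary(central, sd, total)


def _pool_spectral(summaries: list[SpectralSummary],
                   durations: list[int]) -> tuple[float, float]:
    """Power-mass-weighted pooling of per-run spectral moments.

    Weights are total power x run duration, i.e. each run contributes in
    proportion to its share of the combined spectrum; the pooled SD uses
    the law of total variance so it equals the moment of the combined
    spectrum.
    """
    w = np.array([s.total_power * d for s, d in zip(summaries, durations)])
    c = np.array([s.central_freq for s in summaries])
    v = np.array([s.spectral_sd ** 2 for s in summaries])
    ok = np.isfinite(c) & (w > 0)
    if not ok.any():
        return (np.nan, np.nan)
    w, c, v = w[ok], c[ok], v[ok]
    w = w / w.sum()
    central = float((w * c).sum())
    second = float((w * (v + c ** 2)).sum())
    return central, float(np.sqrt(max(second - central ** 2, 0.0)))


def active_windows(
    motion: np.ndarray,
    fps: float,
    active_threshold: float,
    window_s: float,
) -> np.ndarray:
    """Boolean activity per non-overlapping analysis window.

    A window is active when the maximum motion magnitude inside it
    exceeds ``active_threshold``.  A trailing partial window counts as a
    window.
    """
    n_win = int(np.ceil(len(motion) / (window_s * fps)))
    step = int(round(window_s * fps))
    if n_win == 0:
        return np.zeros(0, dtype=bool)
    return np.array([
        motion[i * step:(i + 1) * step].max() > active_threshold
        for i in range(n_win)
    ])


def movement_frequency(
    motion: np.ndarray,
    fps: float,
    active_threshold: float = 0.01,
    window_s: float = 1.0,
) -> float:
    """Percent of analysis windows containing above-threshold motion."""
    act = active_windows(motion, fps, active_threshold, window_s)
    if len(act) == 0:
        return np.nan
    return 100.0 * act.mean()


def movement_strength(motion: np.ndarray, active_threshold: float = 0.01) -> float:
    """Mean motion magnitude over motion-active frames (NaN if none)."""
    motion = np.asarray(motion, dtype=float)
    active = motion > active_threshold
    if not active.any():
        return np.nan
    return float(motion[active].mean())


def movement_count(
    motion: np.ndarray,
    fps: float,
    active_threshold: float = 0.01,
    min_gap_frames: int = 10,
) -> float:
    """Motion bouts per minute.

    A bout is a maximal run of motion-active frames; bouts separated by
    fewer than ``min_gap_frames`` inactive frames are merged into one.
    """
    motion = np.asarray(motion, dtype=float)
    active = motion > active_threshold
    if not active.any():
        return 0.0
    idx = np.flatnonzero(active)
    # a new bout starts when at least min_gap_frames inactive frames intervene
    starts = idx[np.r_[True, (np.diff(idx) - 1) >= min_gap_frames]]
    n_bouts = len(starts)
    minutes = len(motion) / fps / 60.0
    return n_bouts / minutes


def balance_and_symmetry(
    i1_a5: float, i1_a6: float,
    i2_a5: float, i2_a6: float,
    act_a5: np.ndarray, act_a6: np.ndarray,
) -> tuple[float, float, float]:
    """Upper/lower balance ratios and the symmetry score.

    ``i4`` and ``i5`` are raw upper-to-lower ratios of movement frequency
    and strength (missing when the lower-body denominator is zero or
    missing).  ``i6`` is the Jaccard overlap of the two regions'
    active-window sets: 1 when upper and lower body move in the same
    windows, 0 when their activity is disjoint.  Two entirely inactive
    regions have identical (empty) active sets, so ``i6 = 1``.
    """
    i4 = i1_a5 / i1_a6 if i1_a6 and np.isfinite(i1_a6) and i1_a6 > 0 else np.nan
    i5 = i2_a5 / i2_a6 if i2_a6 and np.isfinite(i2_a6) and i2_a6 > 0 else np.nan
    union = (act_a5 | act_a6).sum()
    inter = (act_a5 & act_a6).sum()
    i6 = 1.0 if union == 0 else inter / union
    return (i4, i5, float(i6))


def icog_variability(ts: MotionTimeSeries) -> tuple[float, float, float, float]:
    """Sample SDs of the iCOG velocities and fluctuations, per axis."""
    return tuple(
        float(np.std(a, ddof=1)) if a is not None and len(a) > 1 else np.nan
        for a in (ts.icog_v_x, ts.icog_v_y, ts.icog_d_x, ts.icog_d_y)
    )


def hull_area(gd_x: np.ndarray, gd_y: np.ndarray) -> float:
    """Area (px²) enclosed by the outermost circumference of the
    fluctuation trajectory — the convex hull of the (G^d_x, G^d_y) cloud.

    Degenerate clouds (fewer than 3 points, or all collinear) enclose no
    area and return 0.
    """
    pts = np.column_stack([gd_x, gd_y])
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D: volume is area
    except QhullError:
        return 0.0


def _per_run_indices(ts: MotionTimeSeries, params: IndexParams) -> dict:
    """All windowed and spectral quantities for a single run."""
    fps = ts.fps
    out: dict = {"n_frames": ts.n_frames}
    acts = {}
    for rid, short in (("A5_upper", "a5"), ("A6_lower", "a6"), ("A9_whole", "a9")):
        m = ts.motion[rid]
        acts[short] = active_windows(m, fps, params.active_threshold, params.window_s)
        out[f"i1_{short}"] = movement_frequency(
            m, fps, params.active_threshold, params.window_s)
        if short != "a9":
            out[f"i2_{short}"] = movement_strength(m, params.active_threshold)
            out[f"i3_{short}"] = movement_count(
                m, fps, params.active_threshold, params.min_gap_frames)
            out[f"spec_m_{short}"] = spectral_summary(
                m, fps, params.spectral_window_s)
    out["act_a5"], out["act_a6"] = acts["a5"], acts["a6"]

    for name, series in (("gv_x", ts.icog_v_x), ("gv_y", ts.icog_v_y),
                         ("gd_x", ts.icog_d_x), ("gd_y", ts.icog_d_y)):
        out[f"spec_{name}"] = spectral_summary(series, fps, params.spectral_window_s)
    out["i13x"], out["i13y"], out["i14x"], out["i14y"] = icog_variability(ts)
    out["gd_x"], out["gd_y"] = ts.icog_d_x, ts.icog_d_y
    return out


def assemble_features(
    runs: list[MotionTimeSeries],
    params: IndexParams = IndexParams(),
    sex: int | None = None,
) -> dict:
    """Pool per-run indices into one feature vector for an infant-state.

    Windowed indices (i1–i3) pool by duration-weighted averaging;
    spectral moments pool by power mass so the result equals the moments
    of the combined spectrum; SDs and the hull are computed on the
    concatenated series.  Ratios and symmetry (i4–i6) are derived from
    the pooled ingredients.  Returns a dict with the 26
    :data:`FEATURE_COLUMNS`, the bookkeeping ``i1_a9``, and ``sex`` when
    given.
    """
    if not runs:
        raise ValueError("no retained runs for this state")
    per_run = [_per_run_indices(ts, params) for ts in runs]
    dur = np.array([r["n_frames"] for r in per_run], dtype=float)
    w = dur / dur.sum()

    def wmean(key):
        vals = np.array([r[key] for r in per_run])
        ok = np.isfinite(vals)
        return float((vals[ok] * w[ok]).sum() / w[ok].sum()) if ok.any() else np.nan

    fv: dict = {}
    for key in ("i1_a5", "i1_a6", "i1_a9", "i2_a5", "i2_a6", "i3_a5", "i3_a6"):
        fv[key] = wmean(key)

    act_a5 = np.concatenate([r["act_a5"] for r in per_run])
    act_a6 = np.concatenate([r["act_a6"] for r in per_run])
    fv["i4"], fv["i5"], fv["i6"] = balance_and_symmetry(
        fv["i1_a5"], fv["i1_a6"], fv["i2_a5"], fv["i2_a6"], act_a5, act_a6)

    spec_map = {
        "spec_m_a5": ("i7_a5", "i8_a5"), "spec_m_a6": ("i7_a6", "i8_a6"),
        "spec_gv_x": ("i9x", "i10x"), "spec_gv_y": ("i9y", "i10y"),
        "spec_gd_x": ("i11x", "i12x"), "spec_gd_y": ("i11y", "i12y"),
    }
    for key, (c_name, s_name) in spec_map.items():
        fv[c_name], fv[s_name] = _pool_spectral(
            [r[key] for r in per_run], [r["n_frames"] for r in per_run])

    for key in ("i13x", "i13y", "i14x", "i14y"):
        fv[key] = wmean(key)
    gd_x = np.concatenate([r["gd_x"] for r in per_run if r["gd_x"] is not None]) \
        if any(r["gd_x"] is not None for r in per_run) else np.array([])
    gd_y = np.concatenate([r["gd_y"] for r in per_run if r["gd_y"] is not None]) \
        if any(r["gd_y"] is not None for r in per_run) else np.array([])
    fv["i15"] = hull_area(gd_x, gd_y)
    if sex is not None:
        fv["sex"] = int(sex)
    return fv


def exclusion_rule(fv: dict) -> bool:
    """Keep/discard decision for the low-movement rule.

    Returns ``True`` (keep) iff the whole-body movement frequency
    ``i1_a9`` exceeds 5% — at or below that, the infant showed
    virtually no discernible movement and reliable feature extraction is
    not possible.  A missing ``i1_a9`` discards.
    """
    v = fv.get("i1_a9", np.nan)
    if not np.isfinite(v):
        return False
    return v > EXCLUSION_I1_A9_PCT
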