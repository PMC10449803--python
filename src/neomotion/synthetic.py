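"""Synthetic study data: silhouette videos, cohorts, annotations.

No recordings of the original cohort are available, so every input the
pipeline consumes can be simulated here with known ground truth:

* **Videos** — a static background with an elliptical infant body laid
  along the image x axis (head at low x), circular limb blobs
  oscillating sinusoidally at region-specific frequencies, an optional
  slow trunk drift that moves everything (the iCOG trend), and additive
  Gaussian pixel noise.  The default geometry mirrors the recording
  setup being emulated: 720x480 at 30 fps.
* **Cohorts** — feature tables drawn from a known logistic risk model.
  Defaults reproduce the study conditions: a 73-infant cohort with
  16/57 high/low prevalence, and state-specific effect patterns — during
  sleep a *positive* coefficient on the upper-body spectral SD
  (``i8_a5``) and a *negative* one on the lower-body central frequency
  (``i7_a6``); during wakefulness positive coefficients on the
  upper/lower movement-frequency ratio (``i4``) and the longitudinal
  iCOG-fluctuation spectral SD (``i12x``).  M-CHAT item responses are
  drawn so that scoring them reproduces the latent label, up to a
  controllable noise rate.
* **Annotation tracks** — alternating awake/sleep intervals with random
  exclusions.

Every generator is a pure function of its seed.  Feature marginals are
Gaussian for tractability; real movement indices are non-negative and
skewed — an accepted divergence, since the risk model standardizes its
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .io import AnnotationTrack, FrameSequence, Interval
from .mchat import DEFAULT_CRITICAL_SET, N_ITEMS

__all__ = [
    "LimbSpec",
    "VideoScenario",
    "CohortScenario",
    "generate_video",
    "generate_cohort",
    "generate_annotations",
    "default_video_scenario",
    "sleep_cohort_scenario",
    "awake_cohort_scenario",
]


@dataclass(frozen=True)
class LimbSpec:
    """One circular limb blob wiggling about its rest position.

    The blob orbits its rest position on a circle of radius
    ``amplitude_px`` with tangential speed ``mean_speed_px_s * (1 +
    depth * sin(2π freq_hz t + phase))``: the *movement intensity* is
    rhythmic at ``freq_hz``, which is what the interframe-difference
    motion magnitude — and hence the motor-alteration rhythm index —
    picks up.  An orbit has no direction reversals, so the visible
    swept area follows the speed rhythm smoothly.  ``amplitude_px = 0``
    or ``mean_speed_px_s = 0`` makes the limb static.
    """

    region: str            # "upper" or "lower"
    center: tuple[float, float]   # rest position (x, y), px
    radius: float = 12.0
    freq_hz: float = 1.0
    amplitude_px: float = 15.0    # orbit radius
    mean_speed_px_s: float = 60.0
    depth: float = 1.0     # modulation depth of the speed rhythm
    phase: float = 0.0
    intensity: float = 200.0

    def offsets(self, n_frames: int, fps: float) -> np.ndarray:
        """Deterministic (dx, dy) orbit offsets for every frame."""
        if self.amplitude_px <= 0 or self.mean_speed_px_s <= 0:
            return np.zeros((n_frames, 2))
        t = np.arange(n_frames) / fps
        omega = self.mean_speed_px_s / self.amplitude_px * (
            1.0 + self.depth * np.sin(2 * np.pi * self.freq_hz * t + self.phase))
        omega = np.maximum(omega, 0.0)
        theta = np.concatenate([[0.0], np.cumsum(omega[:-1]) / fps])
        return self.amplitude_px * np.column_stack(
            [np.cos(theta), np.sin(theta)])


@dataclass
class VideoScenario:
    """Full description of one synthetic recording."""

    duration_s: float = 60.0
    fps: float = 30.0
    width: int = 720
    height: int = 480
    background_intensity: float = 40.0
    body_center: tuple[float, float] = (360.0, 240.0)
    body_semiaxes: tuple[float, float] = (180.0, 70.0)  # (x, y): long axis = x
    body_intensity: float = 150.0
    limbs: list[LimbSpec] = field(default_factory=list)
    drift_amplitude_px: float = 0.0   # slow trunk drift along x (iCOG trend)
    drift_period_s: float = 30.0
    noise_sd: float = 2.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def validate(self) -> None:
        nyquist = self.fps / 2
        for limb in self.limbs:
            if limb.freq_hz >= nyquist:
                raise ValueError(f"limb frequency {limb.freq_hz} Hz >= Nyquist")
            x, y = limb.center
            reach = limb.radius + limb.amplitude_px + self.drift_amplitude_px
            if not (reach <= x <= self.width - reach
                    and reach <= y <= self.height - reach):
                raise ValueError(f"limb at {limb.center} can leave the frame")


def default_video_scenario(
    duration_s: float = 60.0,
    lower_freq_hz: float = 1.2,
    upper_freq_hz: float = 0.6,
    noise_sd: float = 2.0,
    width: int = 720,
    height: int = 480,
    seed: int = 0,
) -> VideoScenario:
    """A supine-infant scene: two arms (upper body), two legs (lower body).

    Geometry scales with the requested frame size so small frames can be
    used for quick runs without changing the motion structure.
    """
    sx, sy = width / 720.0, height / 480.0
    body_center = (360.0 * sx, 240.0 * sy)
    limbs = [
        LimbSpec("upper", (230.0 * sx, 105.0 * sy), radius=22 * sy,
                 freq_hz=upper_freq_hz, amplitude_px=20 * sy,
                 mean_speed_px_s=70 * sy, phase=0.0),
        LimbSpec("upper", (230.0 * sx, 375.0 * sy), radius=22 * sy,
                 freq_hz=upper_freq_hz, amplitude_px=20 * sy,
                 mean_speed_px_s=70 * sy, phase=0.5),
        LimbSpec("lower", (500.0 * sx, 110.0 * sy), radius=30 * sy,
                 freq_hz=lower_freq_hz, amplitude_px=20 * sy,
                 mean_speed_px_s=90 * sy, phase=0.0),
        LimbSpec("lower", (500.0 * sx, 370.0 * sy), radius=30 * sy,
                 freq_hz=lower_freq_hz, amplitude_px=20 * sy,
                 mean_speed_px_s=90 * sy, phase=0.4),
    ]
    return VideoScenario(
        duration_s=duration_s, width=width, height=height,
        body_center=body_center,
        body_semiaxes=(180.0 * sx, 70.0 * sy),
        limbs=limbs, noise_sd=noise_sd, seed=seed,
    )


def _paint_disc(frame: np.ndarray, cx: float, cy: float, r: float,
                intensity: float) -> None:
    """Composite an antialiased disc onto ``frame`` (in place).

    Edge pixels get fractional coverage, so sub-pixel motion produces
    smooth intensity changes rather than whole-pixel flips.
    """
    h, w = frame.shape
    x0, x1 = max(int(cx - r - 2), 0), min(int(cx + r + 3), w)
    y0, y1 = max(int(cy - r - 2), 0), min(int(cy + r + 3), h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
    patch = frame[y0:y1, x0:x1]
    patch[...] = patch * (1.0 - cov) + intensity * cov


def generate_video(scn: VideoScenario) -> tuple[FrameSequence, dict]:
    """Render a scenario into frames plus a ground-truth record.

    The ground truth carries each limb's region, frequency and rest
    position, the per-frame trunk-drift offset, and the body bounding
    box — everything a recovery test needs.
    """
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    n = scn.n_frames
    t = np.arange(n) / scn.fps
    yy, xx = np.mgrid[0:scn.height, 0:scn.width].astype(float)

    drift = scn.drift_amplitude_px * np.sin(
        2 * np.pi * t / scn.drift_period_s) if scn.drift_amplitude_px else np.zeros(n)

    frames = np.empty((n, scn.height, scn.width), dtype=np.uint8)
    bx, by = scn.body_center
    ax, ay = scn.body_semiaxes
    offsets = [limb.offsets(n, scn.fps) for limb in scn.limbs]
    limb_tracks = {i: np.zeros((n, 2)) for i in range(len(scn.limbs))}
    static_body = ((xx - bx) / ax) ** 2 + ((yy - by) / ay) ** 2 <= 1.0
    for k in range(n):
        frame = np.full((scn.height, scn.width), scn.background_intensity)
        if drift[k]:
            body = ((xx - bx - drift[k]) / ax) ** 2 + ((yy - by) / ay) ** 2 <= 1.0
        else:
            body = static_body
        frame[body] = scn.body_intensity
        for i, limb in enumerate(scn.limbs):
            cx = limb.center[0] + drift[k] + offsets[i][k, 0]
            cy = limb.center[1] + offsets[i][k, 1]
            _paint_disc(frame, cx, cy, limb.radius, limb.intensity)
            limb_tracks[i][k] = (cx, cy)
        if scn.noise_sd > 0:
            frame = frame + rng.normal(0.0, scn.noise_sd, frame.shape)
        frames[k] = np.clip(frame, 0, 255).astype(np.uint8)

    truth = {
        "limbs": [
            {"region": l.region, "freq_hz": l.freq_hz,
             "amplitude_px": l.amplitude_px, "center": list(l.center),
             "track": limb_tracks[i]}
            for i, l in enumerate(scn.limbs)
        ],
        "drift_px": drift,
        "body_center": [bx, by],
        "body_semiaxes": [ax, ay],
        "active_regions": sorted({l.region for l in scn.limbs
                                  if l.amplitude_px > 0
                                  and l.mean_speed_px_s > 0}),
    }
    return FrameSequence(frames, fps=scn.fps), truth


@dataclass
class CohortScenario:
    """A cohort drawn from a known logistic risk model.

    ``betas`` maps feature names (from the 26-index vocabulary) to true
    log-odds coefficients on the standardized scale; all other features
    are pure noise.  ``intercept`` sets the baseline prevalence
    (defaults target the study's 16 high / 57 low split).  ``sex_beta``
    is zero by default — sex enters the candidate set but carries no
    signal.  ``mchat_noise`` is the probability that an infant's item
    responses contradict its latent risk label.
    """

    n: int = 73
    betas: dict[str, float] = field(default_factory=dict)
    intercept: float = float(np.log(16 / 57))
    sex_beta: float = 0.0
    male_prob: float = 48 / 75
    feature_corr: float = 0.0      # common pairwise correlation of features
    mchat_noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.betas) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown feature names in betas: {sorted(unknown)}")
        if not -1 / (len(FEATURE_COLUMNS) - 1) < self.feature_corr < 1:
            raise ValueError("feature_corr does not give a valid covariance")


def sleep_cohort_scenario(n: int = 40, seed: int = 0) -> CohortScenario:
    """Sleep-state conditions: n = 40, positive i8_a5 / negative i7_a6 effects."""
    return CohortScenario(
        n=n, seed=seed, intercept=-2.8984,
        betas={"i8_a5": 1.7276, "i7_a6": -2.7631},
    )


def awake_cohort_scenario(n: int = 55, seed: int = 0) -> CohortScenario:
    """Awake-state conditions: n = 55, positive i4 and i12x effects."""
    return CohortScenario(
        n=n, seed=seed, intercept=-1.2496,
        betas={"i4": 1.2332, "i12x": 0.5201},
    )


def _draw_mchat_items(rng: np.random.Generator, high: bool,
                      critical: tuple[int, ...], noncritical: tuple[int, ...],
                      ) -> np.ndarray:
    items = np.zeros(N_ITEMS, dtype=int)
    if high:
        # fail at least one critical item, plus a few others
        items[rng.choice(critical, size=1) - 1] = 1
        extra = rng.binomial(1, 0.15, size=N_ITEMS)
        items |= extra
    else:
        # at most two non-critical failures
        k = rng.integers(0, 3)
        if k:
            idx = rng.choice(noncritical, size=k, replace=False)
            items[idx - 1] = 1
    return items


def generate_cohort(
    scn: CohortScenario,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, pd.DataFrame]:
    """Draw a cohort: features, sex, latent risk labels, M-CHAT responses.

    Features are multivariate normal with unit variances and common
    pairwise correlation ``feature_corr``; the high-risk indicator is
    Bernoulli with log-odds ``intercept + sum(betas * features) +
    sex_beta * sex``.  Item responses are drawn so that the M-CHAT dual
    cut-off reproduces the latent label, except with probability
    ``mchat_noise`` per infant.

    Returns ``(features, sex, labels, mchat)`` with one row per infant.
    """
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    p = len(FEATURE_COLUMNS)
    if scn.feature_corr:
        cov = np.full((p, p), scn.feature_corr)
        np.fill_diagonal(cov, 1.0)
        X = rng.multivariate_normal(np.zeros(p), cov, size=scn.n,
                                    method="cholesky")
    else:
        X = rng.standard_normal((scn.n, p))
    features = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    sex = rng.binomial(1, scn.male_prob, size=scn.n)

    eta = np.full(scn.n, scn.intercept) + scn.sex_beta * sex
    for name, beta in scn.betas.items():
        eta += beta * features[name].to_numpy()
    q = 1.0 / (1.0 + np.exp(-eta))
    labels = rng.binomial(1, q)

    critical = tuple(sorted(DEFAULT_CRITICAL_SET))
    noncritical = tuple(i for i in range(1, N_ITEMS + 1) if i not in critical)
    flip = rng.random(scn.n) < scn.mchat_noise
    rows = []
    for i in range(scn.n):
        high = bool(labels[i]) ^ bool(flip[i])
        items = _draw_mchat_items(rng, high, critical, noncritical)
        rows.append({"infant_id": f"inf{i:03d}",
                     **{f"item_{j + 1}": items[j] for j in range(N_ITEMS)}})
    mchat = pd.DataFrame(rows)
    return features, sex, labels, mchat


def generate_annotations(
    n_frames: int,
    state_pattern: tuple[str, ...] = ("awake", "sleep"),
    interval_frames: int = 600,
    exclusion_rate: float = 0.0,
    seed: int = 0,
) -> AnnotationTrack:
    """Alternating awake/sleep intervals with random exclusions.

    The frame range is tiled with intervals of ``interval_frames``
    cycling through ``state_pattern``; each interval is independently
    marked excluded with probability ``exclusion_rate`` (reason drawn at
    random from the manual-exclusion vocabulary).
    """
    if not 0.0 <= exclusion_rate <= 1.0:
        raise ValueError("exclusion_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reasons = ("cry_fuss", "deep_sleep", "intervention", "noise_onset")
    intervals = []
    start, k = 0, 0
    while start < n_frames:
        end = min(start + interval_frames, n_frames)
        excluded = bool(rng.random() < exclusion_rate)
        intervals.append(Interval(
            start, end, state_pattern[k % len(state_pattern)],
            excluded, rng.choice(reasons) if excluded else "none",
        ))
        start, k = end, k + 1
    return AnnotationTrack(intervals)
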