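"""End-to-end convenience: video + annotations -> per-state feature vectors.

Thin orchestration over the ingestion, motion and index layers; every
step is available individually for finer control.
"""

from __future__ import annotations

import numpy as np

from . import features as feat
from . import motion as mot
from .io import STATES, AnnotationTrack, FrameSequence, screen_segments

__all__ = ["extract_state_features"]


def extract_state_features(
    seq: FrameSequence,
    track: AnnotationTrack,
    min_run: int = 90,
    bin_threshold: float = mot.DEFAULT_BIN_THRESHOLD,
    diff_threshold: float = mot.DEFAULT_DIFF_THRESHOLD,
    split_fraction: float = 0.5,
    params: feat.IndexParams = feat.IndexParams(),
    sex: int | None = None,
) -> dict[str, dict]:
    """Run screening, motion extraction and index pooling for one infant.

    The background and analysis regions are estimated once from all
    retained frames (the camera and bed are fixed within a recording),
    then each retained run yields iCOG and interframe-difference series
    that are pooled per arousal state.

    Returns a mapping ``state -> feature dict`` containing only the
    states with at least one retained run.
    """
    segs = screen_segments(track, min_run=min_run)
    retained = [r for s in STATES for r in segs.runs[s]]
    if not retained:
        return {}

    all_frames = np.concatenate([seq.frames[s:e] for s, e in retained])
    pooled = FrameSequence(all_frames, fps=seq.fps,
                           max_intensity=seq.max_intensity)
    background = mot.estimate_background(pooled)
    ref = mot.reference_silhouette(pooled, background, bin_threshold)
    regions = mot.build_regions(ref, split_fraction=split_fraction)

    out: dict[str, dict] = {}
    for state in STATES:
        runs = []
        for s, e in segs.runs[state]:
            sub = FrameSequence(seq.frames[s:e], fps=seq.fps,
                                max_intensity=seq.max_intensity)
            icog = mot.icog_series(sub, background, bin_threshold)
            motion = mot.motion_series(sub, regions, diff_threshold)
            runs.append(icog.merged_with(motion))
        if runs:
            out[state] = feat.assemble_features(runs, params=params, sex=sex)
    return out
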