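# Methods

## Overview

`neomotion` quantifies the spontaneous movement of a supine newborn
from fixed overhead grayscale video (nominally 30 fps, 720×480),
summarises it as 26 per-infant, per-arousal-state indices, and relates
those indices to a dichotomous ASD-risk label derived from the M-CHAT
screening questionnaire with a stepwise logistic classifier. This note
records the model assumptions, the tunable parameters and their
defaults, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know.

## Ingestion and screening

Recordings arrive as numbered PNG/TIFF directories or multi-page TIFF
stacks; colour input is collapsed with Rec. 601 luma weights. Arousal
state (awake = eyes open) and exclusions (crying/fussing, deep sleep,
nurse intervention, abrupt-onset noise) are *manual* annotations
consumed as half-open, 0-based frame intervals; the package never
infers them from pixels, mirroring the visual-inspection protocol it
models. After removing excluded intervals, contiguous same-state
intervals are merged and runs shorter than `min_run` are dropped.

* `min_run` default **90 frames** (3 s at 30 fps): long enough for the
  windowed indices; runs shorter than the 10 s spectral segment still
  contribute spectra through Welch's automatic segment shortening.
* Unlabeled frames are dropped, not imputed: state is unknown there and
  the indices are state-conditional.

## Motion extraction

* **Background**: per-pixel temporal median over the retained frames of
  a recording. Robust as long as the infant occupies any given pixel
  less than half the time; a mostly static trunk is absorbed into the
  background, which is acceptable because the trunk contributes little
  to interframe change (see Limitations).
* **Silhouette**: `|frame − background| > bin_threshold` (default
  **15** on 0–255) followed by one binary opening with a 3×3 square
  kernel (removes speckle, preserves solid blobs).
* **iCOG**: mean foreground coordinate, image convention (x rightward,
  y downward). Empty-silhouette frames become missing samples; a run
  with > 20% missing is rejected, otherwise gaps are linearly
  interpolated before differencing.
* **Velocities/fluctuations**: `G^v` is the first difference of the
  iCOG; `G^d` is the iCOG minus a centred moving average of
  `detrend_window` = **2 s** — the fast wobble about the slow postural
  drift. The 2 s width passes limb-scale rhythms (≥ ~1 Hz) essentially
  unattenuated while tracking drifts slower than ~0.2 Hz.
* **Regional motion magnitude**: `M^(Ak)(t)` = fraction of region
  pixels with `|frame_t − frame_{t−1}| > diff_threshold` (default
  **10**). Area normalization makes values comparable across regions.
  A centred moving average of **0.2 s** is applied to `M` to suppress
  pixel-quantization flicker of the changed-pixel count; it leaves
  constant series exactly unchanged and attenuates only rhythms above
  ~4 Hz, far beyond the 0.5–2 Hz band of interest.
* **Regions**: the bounding box of the temporal OR of silhouettes is
  split along its long axis at `split_fraction` (default **0.5**) into
  `A5` (head side) and `A6`; `A9` is the whole box. Image x is treated
  as the infant's longitudinal axis and the synthetic renderer enforces
  that orientation.

## The 26 indices

Windowed indices use non-overlapping **1 s** analysis windows and an
activity threshold of **0.01** (1% of region pixels changing);
movement bouts separated by fewer than **10** inactive frames merge.
`I1` is the percentage of active windows, `I2` the mean of `M` over
motion-active frames, `I3` bouts per minute. `I4 = I1(A5)/I1(A6)` and
`I5 = I2(A5)/I2(A6)` are kept on the raw ratio scale; `I6` is the
Jaccard overlap of the upper- and lower-body active-window sets (two
fully inactive regions count as perfectly symmetric). Spectral indices
use Welch periodograms (**10 s** Hann segments, 50% overlap, DC bin
excluded); the central frequency is the power-weighted mean and the
spectral SD the power-weighted spread — a small SD means one prominent
rhythm. `I13`/`I14` are sample SDs of `G^v`/`G^d` per axis and `I15`
the convex-hull area of the fluctuation cloud.

Multiple retained runs pool as follows: windowed indices by
duration-weighted mean; spectral moments by power-mass weights (total
power × duration) with the law of total variance, so the pooled values
equal the moments of the combined spectrum; SDs and the hull use the
concatenated series; ratios and symmetry derive from the pooled
ingredients. Pooling two identical runs reproduces the single-run
vector exactly.

Infants with whole-body movement frequency `I1(A9) ≤ 5.0%` are
discarded before modelling (boundary included), matching the rule that
such infants show virtually no discernible movement.

## Risk grouping

M-CHAT responses are 23 binary failure indicators; high risk means
total ≥ 3 or ≥ 1 failure among the 10 critical items. Item wording is
not encoded — items are anonymous indices and the critical set is
configuration (a fixed default set of 10 indices ships with the
package); only counts matter to the analysis.

## Risk model

Indices are z-scored column-wise (sample SD, n−1); missing cells are
imputed with the column median first, which is neutral after centring;
constant columns are dropped. Sex enters as an unstandardized 0/1
dummy and competes in selection like any other candidate. The logistic
model is fitted by Newton MLE (statsmodels; log-likelihood tolerance
1e-8, ≤ 100 iterations); inference is Wald (SEs from observed
information, two-sided normal p). Selection is *pure forward*
stepwise on AIC: add the single best candidate while AIC decreases,
ties broken toward the earliest column. Quasi-separation (any
standardized |β| > 15, or non-convergence) rejects a candidate at that
step. Whether the original procedure allowed backward removals is
unknown; pure forward is implemented and documented.

A deliberate consequence of AIC-forward selection: with ~25 inert
candidates, the expected number of spurious admissions after the true
terms is ≈ 3–4, because a noise regressor improves AIC with
probability P(χ²₁ > 2) ≈ 0.16. The package's recovery tests therefore
distinguish "planted terms selected first" (≈ 100% at n = 500 under
the default effect pattern) from "selected set exactly equals the
planted set" (rare by construction).

## Evaluation

ROC curves enumerate all distinct score thresholds; AUC is trapezoidal
and equals Mann–Whitney concordance with ties counted ½. The operating
threshold maximizes F = 2·precision·recall/(precision+recall) over
midpoints between consecutive distinct scores, ties resolved toward
the more sensitive (lower) threshold; degenerate precision counts as
F = 0. DeLong's test uses placement-value variances; the sleep/awake
comparison is treated as **unpaired** because the two datasets are
different infant subsets of different sizes. The Brunner–Munzel test
uses midranks, the studentized statistic with Satterthwaite df and a t
reference; fully separated samples leave the statistic undefined and
are flagged. Fisher's exact test is the fixed-margin hypergeometric
two-sided sum of tables no more probable than the observed one.

## Synthetic data

The video generator renders a static background (intensity 40), an
elliptical body (intensity 150) laid along image x, and antialiased
circular limb blobs (intensity 200) that orbit their rest position
with tangential speed `v̄·(1 + depth·sin(2π f t + φ))`, plus optional
slow trunk drift and Gaussian pixel noise (SD 2). The rhythm lives in
the movement *intensity*: interframe differencing measures swept area
per frame, so a symmetric positional sinusoid would concentrate its
energy at twice the swing frequency, whereas the speed-modulated orbit
puts the fundamental of `M^(Ak)` at the planted `f` with no
direction-reversal artefacts. Default geometry is 720×480 at 30 fps;
all sizes scale linearly with the requested frame size so quarter- and
half-scale scenes preserve the motion structure (tests use 240×160 and
360×240; the 60 s half-scale scene keeps the recovered spectral SD
comfortably inside two 0.1 Hz bins).

The cohort generator draws the 26 indices from a multivariate normal
(unit variances, optional common correlation) and the high-risk label
from a logistic model. Defaults reproduce the study conditions: a
73-infant cohort targeting a 16/57 high/low split, and state factories
carrying the published coefficient patterns (sleep: intercept −2.8984,
+1.7276 on `i8_a5`, −2.7631 on `i7_a6`, n = 40; awake: intercept
−1.2496, +1.2332 on `i4`, +0.5201 on `i12x`, n = 55). M-CHAT items are
drawn so the dual cut-off reproduces the latent label, with a
configurable contradiction rate (default 0). Every generator is a pure
function of its seed.

What the generators do *not* emulate: real indices are non-negative
and right-skewed rather than Gaussian (harmless to the classifier,
which standardizes its inputs, but the marginals are not realistic);
the rendered scene has rigid blobs rather than articulated limbs, no
occlusion, no lighting change, and its arousal "states" are arbitrary
labels rather than physiologically distinct movement regimes. Passing
tests therefore demonstrate correctness of the measurement and
inference machinery, not clinical validity on real recordings.

## Numerical choices and degenerate inputs

* Spectral moments of a constant (or empty-power) series are missing,
  with total power 0.
* Ratios with a zero or missing denominator are missing; missing
  features are median-imputed only at modelling time.
* Hull area of < 3 points or a collinear cloud is 0.
* A zero margin makes Fisher's p exactly 1.
* AIC ties in selection break toward the lowest column index, making
  the procedure deterministic and column-order invariant except at
  exact ties.
* Problem sizes used by the recovery checks: CI coverage at n = 2000
  over 100 replicates; stepwise behaviour at n = 500 over 25
  replicates; rhythm recovery on a 60 s half-scale (360×240) scene.

## Limitations

* The silhouette of a motionless trunk merges into the median
  background, so the iCOG is driven by the moving parts; iCOG-derived
  indices are correspondingly limb-weighted. Adding trunk drift to a
  scenario restores a trackable whole-body silhouette edge.
* The `I6` symmetry index and the exact `I4`/`I5` definitions are
  under-documented in the source material; the active-window Jaccard
  overlap and raw ratios implemented here are declared substitutes.
* Exact silhouette/differencing thresholds and the upper/lower body
  boundary of the original system are unpublished; the defaults above
  are this package's own, stated once and used everywhere.
* The published cohort results (specific AICs, coefficient values,
  AUCs) depend on unavailable recordings and are not reproduction
  targets; the package reproduces the *arithmetic* of the published
  tables and the *behaviour* of the methods under known ground truth.
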