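# Methods

## Mapping model

A fixation event carries a start time, a duration, an end time and one
representative gaze coordinate in scene-camera pixels (origin top-left,
x rightward, y downward). Frame `k` of a video at `fps` frames/s covers
the half-open interval `[k/fps, (k+1)/fps)` in milliseconds; a fixation's
frame span is

    first = floor(start · fps / 1000)
    last  = floor((end − ε) · fps / 1000),   ε = 0.1 ms

End times are exclusive: a fixation ending exactly on a frame boundary
does not claim the next frame. The guard ε is 0.1 ms rather than
infinitesimal because fixation exports commonly print timestamps to
0.1 ms, so a seven-frame fixation at 24 fps (exactly 291.66̄ ms) arrives
as 291.7 ms — just past the boundary. The 0.1 ms guard absorbs that
rounding; the cost is that a fixation genuinely overhanging a boundary
by under 0.1 ms (2.4 thousandths of a frame) loses that frame, which is
far below timestamp resolution. A fixation shorter than one frame spans
the frame containing its start.

The mapped frame is the middle one, `first + floor((n−1)/2)` for an
n-frame span: the 4th of 7. For even spans the convention is the earlier
central frame (the 3rd of 6); the choice is arbitrary but fixed, and at
24 fps the two candidates are 42 ms apart, within which scene change is
negligible for handheld-object tasks. Using one frame per fixation, not
all frames, mirrors the manual fixation-by-fixation procedure being
replaced, which keeps accuracy comparisons between the two like-for-like.

Assignment tests the gaze pixel `(floor x, floor y)` against every
instance mask on the middle frame (half-open pixel grid `[0,W)×[0,H)`).
All instances of one class form one AOI. When masks overlap, the hit is
resolved by descending confidence, then ascending pixel area, then
lexicographic label — preferring the more certain, more specific object
and making the mapping fully deterministic. A miss maps to the
background label `"BG"`. Off-frame gaze maps to background and is
flagged `in_bounds = False`; under the `exclude` policy such fixations
are additionally dropped from accuracy comparisons.

Tunable parameters (``MappingConfig``):

| parameter | default | meaning |
|---|---|---|
| `tolerance_px` | 0 px | Chebyshev radius around the gaze pixel also tested; 0 is the strict point-in-mask rule. Mobile trackers are accurate to ~0.5° of visual angle (~11 px on a 1280-px, 60°-FOV scene camera), so small positive values are defensible; raising the tolerance can only move fixations from background to an AOI, never the reverse. |
| `confidence_threshold` | 0.5 | minimum detection confidence, applied in the segmenter adapter; real detection backends rarely document a canonical value, and 0.5 is the conventional operating point. |
| `out_of_bounds_policy` | `background` | off-frame gaze → background; `exclude` drops it from metrics. |

## Segmentation

Masks are binary pixel grids at frame resolution. Ground-truth polygons
rasterize by the pixel-center rule: a pixel belongs to the mask iff its
center `(j+0.5, i+0.5)` lies inside the polygon — unambiguous and
checkable against brute-force point-in-polygon. The oracle segmenter
replays rasterized ground-truth annotations with confidence 1.0 and
stands in for a perfectly trained network; real backends (e.g. a
Mask R-CNN served by the user) enter through an adapter that applies the
confidence threshold. Training, augmentation and weights are explicitly
out of scope.

Mask imperfection is simulated in two directions observed in practice:
under-filled contours (morphological erosion with a `(2r+1)²` square
element) and missed detections (independent annotation dropout). Erosion
can only shrink masks, so for a fixed recording it can only convert
true positives into misses and false alarms into correct rejections:
TPR is non-increasing and TNR non-decreasing in the radius. This
monotone trade-off is asserted as an acceptance property.

## Evaluation metrics

Accuracy is scored per AOI, one-vs-rest, over fixations aligned on id:
TP (both mappings say the AOI), FN (only the ground truth does), FP
(only the prediction does), TN (neither). `TPR = TP/(TP+FN)`,
`TNR = TN/(TN+FP)`; the background is not scored as an AOI of its own.
AOI statistics report fixation count, mean and SD of duration, and total
dwell time; the SD is the sample SD (n−1) by default (`ddof`
configurable) and is reported as absent, not zero, when undefined.
Transition matrices count consecutive label pairs including
self-transitions, so entries sum to N−1.

## Efficiency model

Each evaluation procedure is a line `T(s) = F + r·s` in minutes of work
for `s` minutes of recording. The shipped defaults are the measured mean
sub-times of the study this package operationalizes: manual mapping
128.5 min per 52-min sample (preparation 1.5, mapping 126, export 1 —
folded into a single rate of 2.47 min/min, matching the single-ratio
presentation of the source; the printed 2.48 can be passed as an
override), and the computational procedure with fixed stages of
collecting training images (15 min, operator), labelling (113 min,
operator), network training (67 min, computational), data export (1 min,
operator), plus mapping at 40/52 ≈ 0.77 min/min (computational). The
break-even `s* = (F_c − F_m)/(r_m − r_c)` is computed in closed form and
cross-checked in tests against a 1-minute brute-force scan; reporting
rounds break-even points to whole hours and extrapolations to half
hours. With the defaults: total procedure ≈115 min (2 h), operator time
only ≈52 min (1 h), and a 4-hour sample costs ≈9.9 h manual vs ≈6.3 h
computational (reported 10 h vs 6.5 h). Linearity assumes the analyst
takes sufficient breaks; fatigue and nonlinearity are deliberately not
modelled, nor is the between-analyst spread beyond what custom cost
tables express.

## Synthetic recordings

The generator renders scenes of simple geometric objects whose outlines
drive both the rendered pixels and the label dataset, so ground-truth
masks are pixel-exact by construction. The default scene is a miniature
of the instrument-handling setup the method targets: 320×240 px at
24 fps with five elongated "syringe" rectangles and one round "bottle",
reproducing the strong class imbalance of such training sets (hundreds
of syringe representations against a few dozen bottles). The study's
native resolution (1280×960) is scaled down 4× purely for speed; all
geometry is resolution-independent.

Simulated fixations tile the recording back to back. Durations are
Gaussian with mean 445 ms and SD 300 ms, truncated below at 50 ms —
mean matching observed handling-task fixations, SD tightened so that
truncation does not distort the mean (observed SDs are of the same
order as the mean, which a truncated Gaussian cannot represent
faithfully). Each fixation draws a target class (default mix ≈46%
syringe, 2% bottle, 52% background, the observed fixation shares), then
a uniform pixel of that class's mask — or of the background region — on
the fixation's *middle* frame, plus isotropic Gaussian gaze noise whose
default equals the tracker accuracy of 0.5° converted at 60° horizontal
FOV over the frame width (≈2.7 px on the default scene). The recorded
ground truth is the intended target: what an annotator watching the full
fixation would report.

What the generator does not emulate: photorealistic appearance and
segmentation failures driven by texture or lighting, camera egomotion
and motion blur, saccades and smooth pursuit, blinks, and correlated
(non-isotropic) tracker error. Passing tests therefore demonstrate that
the mapping, metrics and efficiency machinery are correct and that
accuracy responds to mask quality in the expected direction — not that
any particular TPR/TNR level would be reached on real video with a real
network, which depends on the trained segmenter and the recordings. The
study-scale accuracies (TPR ≈80%, TNR ≈85–98%) are consequently not
reproduction targets here; the pipeline's correctness anchor is the
oracle identity (perfect masks + noise-free gaze ⇒ TPR = TNR = 1
exactly).

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); no global state is touched, and identical
seeds reproduce frames, fixation tables and metrics bit-for-bit.

## Numerical and design choices

- Timestamps are real-valued milliseconds internally; input unit (ms/s)
  and column names are dialect configuration, since exports vary.
- End/duration disagreement beyond 1 ms is an error; within 1 ms the
  stated start+duration wins. Adjacent fixations sharing a boundary are
  not flagged as overlapping (1 µs slack).
- Pixel containment and rasterization use the same half-open,
  floor-based grid, so a gaze point sampled inside a mask pixel always
  tests positive at zero noise.
- Degraded datasets apply dropout eagerly (seeded, per annotation) but
  erode lazily per queried frame, keeping memory flat on long scenes.
- The break-even solver returns an explicit "no break-even" value when
  the computational line never drops below the manual one, rather than
  raising.
- Problem sizes in the test suite and acceptance script (hundreds of
  fixations, a few thousand 320×240 frames, erosion radii 0–5) were
  chosen as the smallest scales at which every asserted property is
  non-trivially exercised — class imbalance present, every AOI visited,
  erosion visibly biting.

## Known limitations

- Only the middle frame is consulted; fixations straddling occlusion or
  object exit at mid-fixation inherit that single frame's scene state.
- One gaze coordinate per fixation: within-fixation drift is not used.
- The frame-source abstraction ships with directory-of-PNG and
  in-memory implementations; decoding video containers requires an
  imageio plugin with a suitable codec at run time.
- Cost models are means; no uncertainty propagation from the analyst
  spread is offered beyond supplying custom cost tables.
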