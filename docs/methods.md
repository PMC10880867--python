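# Methods

## Angle definition and invariance

Each of the four key sites is the included angle at a vertex joint between
the two adjacent body-segment vectors, computed by the cosine rule and
expressed in degrees on [0, 180]. The dot-product argument is clipped to
[−1, 1] before `arccos`, so numerically collinear limbs are safe; a
zero-length limb vector is a hard error rather than a silent NaN. The bare
included angle cannot distinguish flexion direction, so hyperextension
clamps at 180° — no signed convention is attempted. Because the included
angle is invariant under rotation, translation, and uniform scaling of the
keypoints, it is the one quantity that survives unconstrained home
recording geometry; this invariance is verified to 1e-9° under random rigid
transforms.

The knee angle is hip–knee–ankle. The hip angle is trunk–hip–knee, where
the trunk reference is the thorax joint if the scheme has one, else the
spine, else the ipsilateral shoulder. Trunk–thigh is the standard
extension–flexion convention for the hip, but the exact trunk anchor is a
genuine design freedom; it is therefore configurable per site via the
site-mapping override, and the default is documented rather than presumed
universal.

## Keypoint ingestion and gap policy

The AlphaPose-dialect reader accepts both per-image and per-detection
record lists, grouping by image id and keeping the highest-scoring
detection — the recordings are single-subject by protocol. Frames are
ordered by the numeric part of the image id; the reader never drops or
reorders content beyond that.

Pose estimators flicker. Runs of at most `max_gap` (default 5) consecutive
missing or low-confidence (< 0.3) frames per joint are filled by linear
interpolation between the flanking valid frames; filled samples are marked
fully confident so the operation is idempotent. Longer runs, or runs
touching either end of the recording, are unrecoverable: they mean the
subject left the frame, and the error names the joint and frame range
rather than inventing data.

## Length normalization

Series longer than the 400-sample target keep indices
`i_k = ⌊k·n/400⌋`. This deletes the `n − 400` surplus at maximally even
spacing, is deterministic, always keeps the first sample, and ends at
`⌊399·n/400⌋` (the final few source samples past that index are part of the
removed surplus). The horizontal axis stays a sample index: curves are
averaged as recorded, with no time-warping, cycle-phase alignment, or
smoothing. Series *shorter* than the target raise an error by default —
silent upsampling must never leak into a group mean — with linear
interpolation available behind an explicit policy flag.

## Severity classification and pooling

WOMAC stiffness ≥ 4 and physical-function ≥ 35 are severe; positive scores
below the cut-offs are mild. A score of exactly 0 lies outside both
intervals (the intended cohort has no asymptomatic subjects) and is
rejected unless `zero_as_mild=True`. Subscale maxima are not validated,
only non-negativity, since scoring variants differ. Pools respect the
affected side: a subject's left-side hip and knee curves are used only if
the left knee is osteoarthritic, and bilateral subjects contribute both
sides — which is why side counts may sum to more than the cohort size.

## Wavelet comparison

Group mean curves are decomposed once (single level) with `pywt.dwt`. The
default family is Haar: for even-length input it is boundary-free, each
coefficient array has exactly half the input length, and the closed form
`cA_k = (x_{2k}+x_{2k+1})/√2`, `cD_k = (x_{2k}−x_{2k+1})/√2` makes every
downstream number auditable; energy conservation and perfect reconstruction
are tested at 1e-9. Any PyWavelets discrete family may be configured
(longer-support families use symmetric extension), and the family used is
recorded on every result.

Dissimilarity per site is the elementwise |Δ| of the two groups' cA and cD
arrays, reduced by summation by default (mean and max are selectable). Sums
of absolute differences over ~200 coefficients of degree-scaled curves land
in the hundreds-to-thousands range, which keeps the two bands directly
comparable as effect sizes. No significance test is attached to the
statistic: the package reports effect sizes, and any inferential layer
(e.g. subject-label permutation) would be an extension, not part of the
core method.

## The simulator

`simulate_sts_recording` builds hip and knee angle trajectories as
raised-cosine ramps between seated (knee 90°, hip 95°) and standing
(knee 175°, hip 175°) postures: per cycle one rise (1 s nominal), a standing
hold (0.5 s), one descent, and a seated hold, times five cycles at 30
frames/s — about 460 frames at defaults, always more than the 400-sample
target. Per-cycle multiplicative jitter (5% sd, clipped to ±30%) perturbs
durations and amplitude. Severity enters through one number,
`stiffness_factor ∈ [0, 1]`:

* range of motion × (1 − 0.5·stiffness_factor) — a maximally stiff subject
  opens the joints half as far;
* transition time × (1 + stiffness_factor) — and rises twice as slowly.

Both effects are *slow-band* by construction, which isolates the cA-vs-cD
contrast the analysis is meant to detect; an optional small high-frequency
tremor term (off by default) is the only mechanism that would move the
detail band.

The skeleton is posed by planar forward kinematics: shank held vertical (as
it nearly is in a sit-to-stand), thigh placed to realize the commanded knee
angle, trunk to realize the commanded hip angle, trunk chain (pelvis,
spine, thorax, neck, head) along the trunk direction, arms folded rigidly
across the chest per the test protocol. All angle-bearing joints lie in one
sagittal plane, so the commanded angles are exactly recoverable from the
noiseless keypoints — the closed loop that validates generator and
extractor against each other to 1e-6°. The deliberate price is that left
and right sides coincide in the noiseless limit and the pelvis has no
lateral width: with laterally offset hips, a shared thorax reference leaves
each hip's sagittal plane and the closed loop acquires a systematic
geometric offset. Isotropic Gaussian keypoint noise (sd 0.005 units against
segment lengths of ~0.45, i.e. roughly 0.5–1° of angle jitter) then
decorrelates the sides the way estimator jitter does.

What the simulator does **not** model — and what passing tests therefore do
not show about real data: frontal/transverse-plane motion, compensatory
strategies (trunk lean asymmetry, arm push-off), camera projection error
beyond isotropic noise, lifting-network bias, within-subject fatigue trends
beyond cycle jitter, and any correlation structure between WOMAC subscales
beyond the shared latent severity.

`simulate_cohort` draws, per subject: a latent severity in the exact
requested proportions; integer WOMAC scores inside the defining intervals
(mild stiffness 1–3 / function 1–34; severe 4–8 / 35–68, the 0–8 and 0–68
Likert ranges); `stiffness_factor` uniform on [0.05, 0.25] (mild) or
[0.55, 0.85] (severe) — monotone in severity with a ≥ 0.3 gap; affected
side(s) with bilateral probability 0.5 (clinically, advanced bilateral
disease is common, and side counts then exceed the cohort size as observed
in practice); and one recording whose noisy keypoints are pushed through
the same extraction-plus-normalization path real data takes. All
randomness flows through one seeded `numpy` generator per call; sub-seeds
stay below 2³¹.

## Problem sizes and numerical choices

The end-to-end group-contrast analyses run on 20 subjects per severity
group (40 recordings, ~450–650 frames each), which gives pool sizes of
~15 curves per site and a cA:cD between-group ratio stably above 20 — an
order of magnitude of headroom over the 5× assertion — while the whole
suite stays desk-scale. Cycle segmentation smooths with a 9-sample centered
moving average and requires 20° of peak prominence on the hip angle (hip
excursions are the most pronounced during an STS); both parameters scale
with resampling and are configurable. Tolerances: 1e-9° for angle-formula
and rigid-motion checks, 1e-6° for the simulator closed loop (trigonometric
round-trip through forward kinematics), 1e-9 relative for DWT energy and
reconstruction, 1e-12 for pure-arithmetic oracles.

## Known limitations

* The even-removal rule is one deterministic operationalization of
  "evenly removing" surplus samples; other schemes (e.g. keeping the final
  sample) differ in at most the placement of single-sample deletions.
* Aggregate cA/cD values depend jointly on wavelet family and aggregation
  choice; only *trends and ratios* across sites and bands are meaningful,
  not absolute magnitudes.
* Segmentation assumes a quasi-periodic seated→stand→seated signal; highly
  irregular executions (aborted rises) count only excursions that clear the
  prominence threshold.
* `zero_as_mild` changes the mild/severe partition for asymptomatic
  subjects and must be set consistently across a study.
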