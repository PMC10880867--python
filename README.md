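# sitstand

Kinematic analysis of the five-times sit-to-stand (STS) test for
knee-osteoarthritis (KOA) severity groups, from pose-estimator keypoints to a
wavelet-based group-dissimilarity statistic.

## The problem

Advanced KOA patients struggle to self-assess their physical condition at
home. A smartphone video of the five-times STS test — five consecutive rises
from a chair, arms crossed, as fast as possible — combined with 2-D pose
estimation (AlphaPose-style 17-keypoint output) and 2-D→3-D lifting yields
3-D joint positions whose *absolute* coordinates are meaningless across
unconstrained recordings, but whose *joint angles* are invariant to camera
pose and scale. This package implements the downstream analysis:

1. **Angle extraction.** For the four key sites (left/right hip, left/right
   knee) the extension–flexion angle at vertex joint *v* between neighbouring
   joints *a*, *b* is the cosine-rule included angle
   `θ = arccos((a−v)·(b−v) / (|a−v||b−v|))` in degrees (180° = fully
   extended). Knees use hip–knee–ankle; hips use trunk–hip–knee with the
   thorax (or spine / ipsilateral shoulder) as trunk reference.
2. **Length normalization.** Every angle series longer than 400 samples is
   reduced to exactly 400 by *even removal*: keep indices
   `i_k = ⌊k·n/400⌋, k = 0…399`.
3. **Severity grouping.** Subjects are classified by WOMAC subscale
   cut-offs — stiffness: mild `0 < s < 4`, severe `s ≥ 4`; physical
   function: mild `0 < s < 35`, severe `s ≥ 35` — and only curves from the
   osteoarthritis-affected side(s) enter the per-site pools.
4. **Wavelet comparison.** Each group's pointwise mean curve is decomposed
   with a single-level discrete wavelet transform (Haar by default) into
   approximation coefficients cA (slow trend) and detail coefficients cD
   (rapid fluctuation); between-group dissimilarity per site is
   `Σ|cA₁−cA₂|` and `Σ|cD₁−cD₂|`.

A forward-kinematics STS simulator (`sitstand.simulate`) generates
ground-truth recordings and cohorts so that every stage is testable without
patient data.

## Worked example

```python
import sitstand as ss

# Simulated cohort: 20 mild + 20 severe subjects, one 5-repetition STS
# recording each, with severity-dependent range of motion and pace.
subjects, recordings = ss.simulate_cohort(40, severity_mix=(0.5, 0.5), seed=11)

rec = recordings[0]
angles = ss.extract_angle_series(rec.keypoints)     # 4 sites × n frames
print(ss.segment_cycles(angles).n_cycles)           # -> 5

pools = ss.build_pools(subjects, "stiffness")       # affected-side pools
means = ss.group_mean_curves(pools)                 # 400-sample mean curves
comps = ss.compare_groups(means)                    # Haar DWT + |Δ| sums
print(ss.comparison_table({"stiffness": comps}).round(1))
```

Output:

```
           stiffness
                  cA     cD
site
left_hip      3024.7  118.5
left_knee     3208.3  120.3
right_hip     3010.9  127.8
right_knee    3197.3  131.0
```

Reading: the mild and severe stiffness groups differ strongly in the
low-frequency band (cA sums in the thousands — the groups rise to different
joint extents at different paces) while the high-frequency band (cD) carries
roughly 25× less between-group difference, consistent with severity acting
on the slow components of the movement rather than on rapid detail.
`ss.plot_report(pools, means, comps, "figs/")` writes per-group curve plots
and per-site coefficient plots.

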