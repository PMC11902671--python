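# Methods

`segmetry` estimates the volume and mass of the 17 body segments of a supine
subject from a single overhead RGB-D view.  This note documents the model,
the numerical choices, and what the synthetic phantoms do and do not show.

## Measurement model

The subject lies on a bed under a downward-looking depth camera.  The camera
frame has X/Y in the image plane and Z increasing away from the camera, so
the bed plane sits at the *largest* Z of the cropped scene and the body
rises toward smaller Z.  The chain is:

1. **Skeleton.** A 2D pose estimator supplies 13 landmarks (nose; left/right
   shoulder, elbow, wrist, hip, knee, ankle).  The neck KP2 and mid-hip KP15
   are their midpoints, and three vertebral keypoints are constructed from
   anthropometric proportions along the trunk axis midBody = KP2 − KP15:

   - C7:      KP19 = KP2 + unit(KP1 − KP2) · |midBody| · 17 %
   - mid-ASI: KP17 = KP15 + unit(midBody) · W_hip · 47 %
   - T12:     KP18 = KP17 + midBody · 36 %

   Midpoints and the three constructions are applied *after* metric
   conversion: a pixel-space midpoint would be unprojected at the mid-body
   surface depth and perspective-shift the neck/mid-hip laterally by
   centimetres, and the W_hip term (metres) is only dimensionally meaningful
   in a metric frame.  Each keypoint's depth is the median of the valid
   depths in a 5×5 pixel window; a single-pixel read would be at the mercy
   of dropout and noise, and a centimetre of depth error moves every cut
   line derived from that joint.

2. **Registration.** Generic pinhole model with Brown–Conrady (rational)
   distortion; undistortion is a fixed-point iteration (tolerance 1e-6 px,
   ≤ 20 iterations).  Depth frames are 16-bit PNGs in millimetres
   (`depth_scale` = 0.001 m/unit by default).

3. **Filtering.** (i) Coarse crop to an area of interest centred on the
   cloud's XY median, half-extent 1.21 m per axis by default — the bed's
   half-diagonal plus margin, so an in-plane-rotated bed survives whole —
   then removal of everything deeper than mean(Z) + 0.40 m (floor).  The
   median-centred crop is idempotent, unlike a min/max-with-padding crop
   (also available) which shrinks on every application.
   (ii) Seeded RANSAC plane fit (3-point hypotheses, total-least-squares
   refinement); T1 is the minimal rotation bringing the bed normal onto the
   Z axis.  (iii) The bed inliers' 2D footprint (convex hull) is filled with
   1e6 uniform Monte Carlo points and T2 rotates the fill's principal axes
   onto X/Y.  The fill regularises the perspective-induced density gradient;
   filling an axis-aligned min/max rectangle instead would make the PCA
   blind to in-plane rotation, so the footprint hull is used.
   (iv) Depth denoising (per-point median Z over k nearest neighbours,
   k = 9 by default), a flatness-aware flying-pixel trim (points standing
   more than max(2 mm, 2·IQR) above their neighbourhood median Z are
   dropped; the IQR term protects silhouette walls), removal of everything
   at or beyond the bed plane, statistical outlier removal (k = 20,
   z-score 6 — the sparsely sampled grazing-incidence silhouette is real
   signal at 2–3 σ, isolated returns sit far beyond 6 σ), and radius
   denoising (2 cm, ≥ 5 neighbours).

4. **Segment separation.** In the bed-aligned XY projection each segment is
   captured by an enclosing polygon: quadrilaterals for the limbs (cut lines
   through the joint keypoints, lateral lines at O/(2π) half-widths padded
   by 15 %), bands between the vertebral cut lines for thorax/abdomen/
   pelvis (half-widths from the measured trunk widths, padded 5 %), an
   eight-line chamfered band for the shoulders, and offset-closed polygons
   for head/hands/feet (offset = the measured segment length).  Every cut
   line is inset 4 mm toward the segment interior: a depth pixel straddling
   a joint is resolved to one side at the sensor's lateral resolution
   (~3.7 mm at 1.5 m), and without the inset a few pixels of a taller
   neighbouring segment bleed across the cut and prop up the segment's
   alpha shape.  Residual bleed is caught by a per-segment spike trim (same
   flatness-aware rule as above, within the segment's own points).
   Overlaps resolve axial-first (head, shoulders, thorax, abdomen, pelvis,
   then limbs proximal-to-distal, left before right).  The published
   polygon routine was never printed; this construction is a faithful
   reconstruction, not a copy.

5. **Filling and volumetry.** Bottom filling copies every segment point to
   the bed plane Z; gap filling (shoulders and trunk segments by default)
   drapes the 2D alpha-boundary of the top surface down to the bed in 5
   evenly spaced levels.  The filled cloud is meshed as a 3D alpha complex
   (Delaunay tetrahedra with circumradius ≤ probe radius; boundary faces
   oriented outward).  The per-segment alpha parameters are 0.08 for head,
   shoulders, pelvis, arms, shanks and feet; 0.05 for forearms and hands;
   0.15 for the trunk; 0.2 for the abdomen; 0.22 for the thighs ("legs").
   Their units are not stated in the source material; the default
   convention treats them as *a* with probe radius 1/a on metre-scaled
   clouds (calibrated once on the phantoms — for these values the complex
   is hull-like, which suits the convex-by-construction filled segments),
   and a "radius" convention is exposed for probe radii given directly.
   The volume is cuboid Monte Carlo: N = 1e6 seeded uniform points in the
   cloud's tight bounding box, V = (N_BS/N)·V_cuboid, with the binomial
   standard error reported.  Containment is evaluated exactly on the alpha
   complex itself (a point is inside iff its Delaunay simplex was kept) —
   faster and more robust than ray casting; plain meshes fall back to a
   convex Delaunay path or vectorized ray-crossing parity with an epsilon
   re-test of edge-grazing rays.  Mass is volume × the reference density
   (1000 kg/m³ when the table has no entry).

6. **Comparison layer.** Reference volume V_ref = (mass fraction × body
   mass)/density — the source formula prints a product, which is
   dimensionally wrong for a volume, so the quotient is used.  Truncated
   cone V_cone = L·π·(r_d² + r_p² + r_p·r_d)/3 with r = O/(2π).  Equivalent
   diameter D = sqrt(4V/(πL)) (the printed form lacks the radical; the
   cylinder definition forces it).  D̂ normalises both diameters by the
   manually measured length (a config switch uses the scanner length for
   the scanner diameter instead), and ΔD = (D̂_scan − D̂_ref)/H exactly as
   printed, although the result then carries 1/m units.  Length deltas are
   height-normalised; masses body-weight-normalised in %.  Bland–Altman
   summaries (mean difference, ±1.96 SD limits) support cohort agreement
   plots.

## Tunable parameters

| parameter | default | unit | why |
|---|---|---|---|
| `z_padding` | 0.40 | m | floor sits ~0.45 m beyond the bed plane |
| `ransac_distance` | 0.01 (`low_noise`: 0.002) | m | plane inlier threshold ≈ a few × depth noise |
| `smooth_k` | 9 (`noisy`: 15) | – | median window; noise σ/√k vs curvature flattening |
| `outlier_std_ratio` | 6.0 | σ | keep sparse silhouette, reject isolated returns |
| `cut_inset` | 0.004 | m | > half a pixel footprint + keypoint jitter |
| `segment_trim_tol` | 0.002 | m | spike height over flat neighbourhoods |
| `width_margin` | 1.15 | – | circumference-derived half-widths underestimate flat sections |
| `pca_fill_n` | 1e6 | – | bed-footprint fill for the axis PCA |
| `n_points` | 1e6 | – | Monte Carlo sample; SE ∝ 1/√N |

All thresholds are config-exposed (`PipelineConfig`, YAML-loadable, unknown
keys rejected).  `FilterParams.low_noise()` / `.noisy()` bundle the two
sensor regimes used in the validation.

## The phantom generator

Phantoms are supine "subjects" assembled from analytic solids — truncated
cones (limbs), elliptic cylinders (trunk, hands, feet), an ellipsoid head —
on a 1.06 × 2.06 m bed ~1.55 m under a 640×576 px depth camera, rendered by
z-buffering densely sampled surfaces at the sensor resolution.  A mixed
boundary pixel is resolved to the closest object and its depth is the mean
over that object's in-pixel samples, which mimics how a ToF pixel
integrates over its footprint and avoids a skirt of floating points at
silhouettes.  Gaussian depth noise and uniform dropout are optional;
everything is seeded and bitwise reproducible.

Default body solids are cut by a horizontal plane 25 % of the section
height *below* their axis (`sink = 0.25`): tissue bulges past the mattress
contact, so the widest visible silhouette rides above the bed.  The
analytic truth is the volume above that cut (closed forms for cylinder and
ellipsoid, validated quadrature for the cones), which is also — up to a
0.25 % sliver under the overhang — exactly what a top surface closed by
bottom filling can recover.  Joint landmarks are placed a few millimetres
inside one smooth surface (e.g. over the deltoid/thigh mass) so the depth
median under a landmark is single-surface, as it is for real joints;
segment interfaces coincide with the cut lines the vertebral construction
produces, so per-pixel truth labels are directly comparable with the
polygon assignment.

What the phantoms deliberately do not model: pose-estimator landmark error
(landmarks are projected ground truth; the robustness of the pose model is
its own literature), soft-tissue deformation, clothing, multi-path/flying
ToF artifacts beyond Gaussian noise + dropout, limb poses other than
straight supine, and the perspective-dependent lateral error of a real
registered RGB-D pair.  Passing phantom tests therefore validates the
*geometry processing* — alignment, separation, closure, integration — not
the pose model or sensor physics.

## Verified behaviour (recomputed by `scripts/acceptance.py` and the test suite)

On the default phantom: noise-free limb volumes within 5 % of analytic
truth and equivalent diameters within 3 %; with 3 mm depth noise and 10 %
dropout, limb volumes within 10 %; bed tilt up to 5° and in-plane rotation
up to 30° recovered to better than 0.5° (typically ≪ 0.1°), with ≥ 99 % of
generator-labelled body points retained and ≥ 99 % of bed points removed;
≥ 95 % label agreement more than 1 cm from any cut line; Monte Carlo
volumes of closed-form solids within 3 binomial standard errors at N = 1e6;
and bitwise-identical results on re-runs with the same config and seed.

## Known limitations

- The single view cannot see the subject's back: trunk segments inherit the
  flat-back assumption of the bottom fill, so thorax/abdomen volumes are
  closure-dependent in a way limb volumes are not.
- Hands and feet are closed by a fixed offset from the wrist/ankle; their
  recovered volumes are systematically a few percent low on the phantoms.
- Convex-hull-like alpha shapes ride positive depth-noise extremes; the
  median smoothing keeps this within ~8 % at 3 mm noise for the thinnest
  segments, but heavier noise needs stronger smoothing (and costs crest
  flattening on thin limbs).
- The anthropometric table shipped with the package is a synthetic
  stand-in; population-appropriate values should replace it for real
  studies.
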