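# Methods

This note documents the measurement model, the defaults that matter, what
the synthetic validation does and does not show, and the design choices
made where the design was genuinely open.

## Camera model and units

A pinhole model with square pixels, zero skew and no lens distortion:
`x = f·X/Z` in pixel units, principal point at the image centre, image
origin at the upper-left corner with x rightward and y downward. Modern
smartphone main cameras justify all three simplifications; radial and
tangential distortion of such cameras is small enough to ignore at the
millimetre scales involved. All world lengths are metres internally;
machine-geometry files may be given in centimetres (`units: cm`) and are
converted at parse time. Pixel centres sit at integer coordinates.

At typical capture settings — portrait 1080×1920 covering ≈3 m vertically
from 2.2 m — the spatial resolution is ≈1.6–2.1 mm per pixel and the
temporal resolution 4.2 ms at 240 fps, which bounds everything downstream:
single-frame quantization is the dominant error source of the instrument.

## Two-plane calibration

**Quad embedding.** The four reference corners are reconstructed from six
tape-measured distances by the law of cosines: P1 at the origin, P2 along
+Y (down the left pillar), P3 and P4 triangulated from two distances each
with the X > 0 branch chosen. Five distances determine the embedding; the
sixth (D34) is redundant and is checked against the embedding with a 5 mm
tolerance — roughly the repeatability of a hand-held tape measure. A
violation raises an error naming the offending distance rather than
silently absorbing a mis-measurement.

**Homography estimation** uses the DLT on Hartley-normalized coordinates
(centroid at the origin, RMS radius √2), which keeps the design matrix
well-conditioned at pixel scales of 10³.

**Focal self-calibration.** With K = diag(f, f, 1) (plus principal point)
and H ∝ K[r1 r2 t], orthonormality of r1 and r2 yields two linear
constraints on 1/f², combined by least squares. A fronto-parallel view
makes both constraints vanish — f is then unobservable and the code raises
a degenerate-view error instead of returning an arbitrary value; the
caller supplies the focal length from camera metadata in that case
(`PipelineConfig.intrinsics`). The synthetic validation sweep uses the
metadata path throughout because its tilt range includes 0°.

**Pose and plane transfer.** Columns of K⁻¹H are rescaled so
mean(|r1|, |r2|) = 1, the sign is fixed so the plane sits in front of the
camera, r3 = r1 × r2, and the rotation is projected to the nearest
orthogonal matrix via SVD. Guide points share the structural points'
in-plane coordinates at Z = +Dg (Z points away from the camera; a
`guide_sign` flag flips the offset for mirrored installations). The guide
homography Hg is fitted to the four projected correspondences and reused
for every frame of the session — the camera is on a tripod, so nothing
moves.

## Detection defaults

| parameter | default | rationale |
|---|---|---|
| tape hue target | 0.0 (red); 1/6 for black–yellow tape | the two commercial warning-tape palettes |
| mark hue target | 1/6 (yellow) | distinct from both tape palettes' surroundings |
| saturation gate | 0.50 | achromatic pixels carry no usable hue; value is heuristic and uncritical |
| binarization half-range | half the circular hue distance from the target to the nearest *other* primary/secondary hue (1/12 for red) | widest band that cannot bleed into a neighbouring color family |
| expected polygon size | image_height/40 px | tape stripes ≈10 cm seen from ≈2 m |
| expected mark size | image_height/60 px | a ≈4 cm tape piece at the same distance |
| RANSAC | threshold 3 px, 200 iterations, seeded | generous against corner jitter; seeded for reproducibility |

Structuring-element lengths for the top-hat band-pass (2× and 0.5× the
expected size) are rounded to the nearest odd integer so that erosion and
dilation share a symmetric centred origin; the band-pass then provably
equals the brute-force shift-based erosion/dilation composition (tested
pixel-exactly). The vertical and inclined (diagonal) band-pass outputs are
intersected to seed the reconstruction — the combination rule is not
forced by the method description, and intersection is the conservative
choice (a polygon must be size-bounded along *both* orientations).
Diagonal openings are computed by shearing rows so the line becomes
vertical, keeping the cost independent of element length.

A polygon's "upper-left corner" is the leftmost pixel of its topmost row
(and "bottom-right" the rightmost pixel of the bottommost row). For a
camera that is tilted but not rolled, the top edge of a projected
rectangle is exactly horizontal, so this pixel is the true corner
projection to within rasterization (≤1 px).

## Tracking and pairing

Search strips are built once from the tape inliers: a RANSAC line through
the bottom-right corners of the left tape polygons, shifted right by half
the polygon width (L2); the search region runs from L2 to the line halfway
between L2 and the image's vertical bisector, mirrored on the right. Pair
selection minimizes the absolute *height* (row) difference of the
left/right upper-left corners: the rigid bar holds both marks at equal
height, whereas column proximity would be meaningless for marks ~1.5 m
apart. Ties break toward the largest combined area. Gaps are filled by
linear interpolation (held at the nearest detection at the ends); gaps
longer than 5 frames are flagged low-confidence in the output. Only the
two mark corners per frame are mapped through Hg (asserted), and the bar
height is −mean(Y_g) of the two sides, which cancels small bar tilt and
halves quantization noise.

## Kinematics

Velocity and acceleration use central differences (one-sided at the ends)
with an optional centred moving average (`smooth_window`, default off;
5 samples at 240 fps is a good choice when peak velocity matters, since
central differences amplify the ±1 px quantization into ~0.2 m/s spikes).

Concentric-phase boundaries are found on *interval* (forward-difference)
velocities: the sample at which the upward interval velocity first exceeds
`v_start` (default 0.05 m/s) sustained for 3 samples still holds the
pre-ascent position and is the segment start; the ascent ends at the first
sample opening a 3-sample run of non-positive or sub-`v_stop`
(default 0.02 m/s) intervals. The sustain requirement on the stop
condition makes the boundary robust to single-frame quantization dropouts
(at 0.4 m/s and 240 fps the bar moves almost exactly one pixel per frame,
so isolated zero-steps are routine). Interval velocities were chosen over
central differences for segmentation because central differences smear the
rest/motion boundary by one sample at each end, inflating the concentric
duration by ~2 frames — a ~3% mean-velocity bias for fast lifts at
240 fps.

Per repetition: range = h(end) − h(start); mean velocity = range/duration
(the standard VBT definition, and exactly consistent with the
fundamental-theorem invariant); peak velocity and its latency from the
instantaneous series; mean force and power averaged point-wise with
F = (m_a + m_l)(a_b + g), g = 9.81 m/s². Bar displacement stands in for
centre-of-mass displacement, the usual simplification for guided squats;
no trunk-model correction is applied.

## Agreement statistics

ICC(2,1) (two-way random, absolute agreement, single measures) from the
ANOVA mean squares with the F-based confidence interval (Satterthwaite
df); Cronbach's α with the two instruments as items; Bland–Altman bias ±
1.96·SD of the differences with an OLS regression of difference on mean
(proportional bias flagged at r² > 0.1); SWC = 0.2 × between-subject SD of
pooled subject means; SEM by the difference-score convention
SD(a−b)/√2 — the ANOVA route (√MS_error) is available via
`sem_method="anova"`; for two raters the two coincide. Pearson r gets a
Fisher-z interval; SEE is the residual SD of regressing the practical
instrument on the criterion, standardized by SD(practical) and labelled on
the halved modified-Cohen scale. Paired comparisons use two-sided 95%
intervals.

## Synthetic validation: what it shows and what it does not

The renderer draws axis-aligned tape stripes (Z = 0) and bar marks
(Z = Dg) through the exact pinhole projection with pixel-centre
rasterization and no anti-aliasing; ground-truth mark pixels are exact
projections, so the full pipeline can be checked against closed-form
truth. The default virtual machine is 1.5 m wide with a 1.45 × 1.0 m
reference quad, Dg = 0.15 m, filmed portrait 1080×1920 from 2.2 m at
240 fps — the capture conditions of a realistic tripod setup.

The end-to-end validation sweep renders 20 constant-velocity lifts of
0.35 m spanning mean velocities 0.4–1.2 m/s and camera tilts 0–20° and
requires mean-velocity recovery within 3% and range recovery within 2 mm
on every sequence (measured: ≤1.1% and ≤1.3 mm). Constant-velocity
profiles are used because their prescribed mean velocity is exactly the
quantity the threshold segmentation measures; for smooth profiles the
detected concentric phase legitimately excludes the near-zero-velocity
tails, so "recovery error" would conflate instrument error with
definition mismatch. Smooth-profile recovery (range, peak velocity) is
exercised separately in the unit tests.

What the passing sweep does **not** show: robustness to motion blur,
specular highlights, cluttered backgrounds with tape-like colors, rolling
shutter, camera roll/yaw, lens distortion, or human occlusion of the
marks. The renderer's colors are exactly saturated and its background
achromatic; real gyms are harsher. Occlusion handling is exercised only
via explicit mark blanking, and illumination robustness only via global
brightness scaling (which the hue/saturation representation removes by
construction). Agreement statistics are validated on a generative model
(subject means ~ Normal, additive instrument bias and noise) whose truth
is known; real instrument-comparison data need not follow it.

## Numerical choices and degenerate inputs

- Homographies are normalized to H[2,2] = 1 (unit Frobenius norm if that
  entry vanishes); singular matrices are rejected at construction.
- Points with depth ≤ 1e-9 m raise behind-camera errors; homogeneous
  w ≈ 0 raises a plane-at-infinity error on inverse mapping.
- The redundant-distance check tolerates 5 mm; triangle-inequality
  violations are geometry errors, not warnings.
- Empty candidate lists are valid per-frame results (handled by
  interpolation); a side with *no* detections in a whole sequence is a
  tracking error.
- Zero total variance makes ICC/α undefined and raises, rather than
  returning NaN.
- All randomness (RANSAC, renderer noise, paired-data generator) flows
  from explicit seeds; identical seeds give byte-identical outputs.

## Known limitations

- Single camera, planar motion only: out-of-plane bar paths (free-weight
  lifts) violate the guide-plane assumption by construction.
- Corner localization is integer-pixel; sub-pixel refinement would cut
  the dominant quantization error but is not implemented.
- The camera must not move during a session; there is no drift detection
  or recalibration.
- Video-container input depends on the imageio backend available;
  directories of numbered PNG frames are the fully supported path.
- Frame rate is taken from configuration, not container metadata, which
  is often wrong in high-speed modes; a mismatch corrupts all velocities
  by the same factor.
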