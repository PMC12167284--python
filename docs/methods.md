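# Methods

## Geometry and conventions

All metric quantities are millimetres; image quantities are pixels, 0-based,
x right / y down, origin at the centre of the top-left pixel. Camera poses
map the world frame `W` to the camera frame `C` (the COLMAP convention);
quaternions are stored (w, x, y, z). The camera model is pinhole without
distortion — undistortion is assumed upstream, because marker-grade
registration is meaningless through an uncorrected lens. Frames are labelled
strings (`S` scan, `W` world, `B` robot base, `EE` end-effector, `C` camera)
and every transform composition checks that labels chain; this catches the
most common integration bug in pose plumbing at the cost of a few
comparisons.

A sphere (centre c, radius r) is the quadric
`Q = [[I, -c], [-c^T, c^T c - r^2]]`; its dual has the rank-one structure
`Q* ∝ c̃ c̃^T − r² diag(1,1,1,0)`. The silhouette conic follows from
`E^{-1} ∝ P Q^{-1} P^T`. Because `P = K[R|t]` gives `B B^T = K K^T` exactly
for `B = KR`, a Sherman–Morrison step reduces the projection to

    E ∝ K^{-T} ( c_cam c_cam^T − (‖c_cam‖² − r²) I ) K^{-1},

with `c_cam` the sphere centre in the camera frame. This form is used
everywhere (projection, residuals, Jacobians): the naive route inverts a
dual conic whose rank-one part dominates by ~‖c_cam‖²/r² (a factor 10^4–10^5
at our working geometry) and loses five to six significant digits; the
reduced form is exact to machine precision. Conics are scale-equivalence
classes; we fix unit Frobenius norm with non-negative trace of the 2×2
block, so ellipse interiors evaluate negative and residual magnitudes are
comparable across markers and images.

The same structure inverts cleanly: pulled back to normalised camera
coordinates the conic is `∝ c c^T − (‖c‖²−r²) I`, whose distinct eigenvalue
and eigenvector recover the camera-frame centre direction exactly and the
distance as `d = r √(1 + 1/ρ)` from the eigenvalue ratio ρ. This closed-form
"centre from conic" drives the SfM scale pre-estimate (below).

## Marker localisation in the scan

Marker radii are known by construction (3D-printed spheres, 30 mm diameter
default), so only centres are estimated. From a user-provided approximate
centre the fit alternates (i) selecting mesh vertices whose spherical
residual `|‖v−c‖−r|` lies within a band (default 1.5 mm = 10% of the 15 mm
radius — wide enough for scan noise, narrow enough to exclude the mounting
stalk), (ii) one pass of 3·MAD trimming against fringe vertices at the
sphere-mount junction, and (iii) a step-halving damped Gauss–Newton update
of the centre. Only vertices are used, never face interiors. Convergence:
centre step < 1e-6 mm, at most 100 iterations; fewer than 10 in-band
vertices raises an error. The per-iteration RMS is non-increasing by
construction for a fixed support set; support re-selection can raise it by
≪ the noise level (measured ≤ 1.1e-4 mm at σ = 0.05 mm), which the tests
allow for. The sphere-distance residual (rather than point-to-point ICP) is
used because it is the quantity the markers are built to realise.

With hemisphere-only coverage (a handheld scanner sees one side), 2000
vertices at σ = 0.05 mm localise the centre to ~0.006 mm (95th percentile) —
the fixed radius is what rescues the ill-conditioned depth direction.

## Ellipse detection

Pipeline: min-max intensity normalisation → Otsu threshold (or fixed) →
connected components → marching-squares sub-pixel boundary at the threshold
level → direct least-squares conic fit constrained to ellipses
(Halir–Flusser partitioning of the Fitzgibbon method, on centred/scaled
coordinates) → gates. Gates: semi-minor axis ≥ 10 px (noise specks),
semi-major ≤ a quarter of the image diagonal (scene-scale blobs), RMS
foot-point distance of boundary points to the fitted ellipse ≤ 0.5 px —
the last rejects merged or occluded blobs, which is the safe failure mode
(a missing observation is harmless, a corrupted one is not). Intensity
normalisation plus Otsu makes detection invariant to affine intensity
changes. Each detection stores both the raw sub-pixel edge points and
parametric samples of the fitted conic; the refinement consumes the edge
points by default (they carry independent noise per point), with the fitted
samples as the fallback. On rendered test images the fitted centres land
within 0.05 px and axes within 0.6% of the analytic silhouettes.

## Registration

**Initialisation.** In one image with all markers visible, every 4-subset of
detected ellipse centres is paired with every ordered assignment of 4 of the
M sphere centres; each hypothesis is solved with minimal P3P (Grunert's
quartic, assembled by exact polynomial arithmetic and solved via batched
companion-matrix eigenvalues; the 4th pair disambiguates the up-to-4 roots)
and scored by how many remaining markers project within a gate (25 px at a
9504 px reference width, scaled with image width) of some detected centre.
Subsets are visited in detection-support order with an early exit when a
hypothesis explains all M markers; ties break by summed gated distance, then
assignment order, making the search deterministic. Ellipse centres are
biased estimators of projected sphere centres (perspective offset, well
under the gate at our geometry); the bias is tolerated here and eliminated
in the refinement, which never uses centres.

**SfM scale.** PnP distances are meaningless when camera poses carry an
unknown global scale. The conic-implied camera-frame centres (computed with
the nominal radius) are the true centres divided by the unknown scale s, so
the world point implied by image i's detection centroid is `μ_i(s) = s u_i +
v_i` with `v_i` the camera centre — and all images must agree on it.
Minimising the spread of `μ_i(s)` is a scalar linear least-squares problem
with a closed form, needs no correspondences, and is exact on clean data.
Similarity mode estimates s this way, scales the marker set, and proceeds
with the ordinary PnP init; rigid mode retries through the same path if
plain PnP fails or if cross-image matching collapses (a wrong-scale PnP
solution can be image-consistent in the init view alone — the single-view
similarity ambiguity).

**Matching.** Given the initial transform, each detection is assigned to the
marker whose projected centre is nearest within the gate; conflicts keep the
nearer detection and are logged; unmatched detections are dropped. Missing
(image, marker) pairs are simply absent from the sparse sum.

**Refinement.** Levenberg–Marquardt on the stacked bilinear residuals
`x̃^T Ê x̃`, over 6 parameters (local axis-angle increment right-composed
onto the rotation, translation) or 7 (plus log-scale). The scale acts on the
scan-to-world map (`c_W = s R c_S + t`, radii `s·r`), which is algebraically
equivalent to scaling the SfM poses but keeps them fixed. Jacobians are
analytic (verified against central differences to 1e-6 relative); damping is
multiplicative with step acceptance only on cost decrease, so the final cost
never exceeds the initial. Convergence: relative cost drop < 1e-10 or step
norm < 1e-12, at most 200 iterations. On noise-free scenes the optimiser
reaches cost ~1e-28 and recovers the truth to ~1e-8 rad / 1e-13 mm from the
PnP init; with scale it recovers s to ~1e-15 relative.

## Evaluation metrics

* **Radial error** (mm): back-project an outline pixel of a *control* marker
  (held out of the registration) to a ray; report |d(ray, centre) − r| —
  the tangency deficit. A secant ray counts its overshoot, not the zero
  distance to the surface as a set; that choice keeps the metric sensitive
  on both sides of tangency. Means are reported per point, per marker and
  per image (the aggregations differ when coverage is uneven; all three are
  exposed).
* **Reprojection error** (px): symmetric mean geometric distance between the
  projected and the detected ellipse — points sampled on each, orthogonal
  foot-point distance to the other (robust bisection on the ellipse's radial
  Lagrange parameter; exact for circles and on-axis points), averaged both
  ways. Geometric, not algebraic, because pixels are the reported unit.
* **Chamfer distance** (mm): area-uniform surface samples (default 1e5),
  exact point-to-triangle distances (barycentric clamping; KD-tree on
  triangle centroids prunes candidates, k = 32 — exact whenever triangles
  are small against feature spacing, which scanner meshes satisfy), mean
  over both directions. The same seed drives both directions, making the
  metric exactly symmetric. Mean/median/RMS and one-sided variants are
  exposed since conventions differ between papers. Note the metric is
  between *polyhedral* surfaces: two concentric icospheres of radii 15 and
  16 mm score 1.0 mm only up to the facet sag (~2e-3 mm at subdivision 5).

## Synthetic scenes

The generator emulates the physical acquisition this package targets:
M = 10 markers (30 mm diameter) on a jittered ring (or board) of ~150 mm
extent around an ellipsoidal specimen blob; N = 16 cameras on two arcs on
opposite sides of the scene (as a camera on a robot repositioned across a
table), ~1 m away; full-frame intrinsics 9504×6336 px with f = 7000 px so a
marker spans ≈ 200 px (a `desk` preset at 1920×1080 keeps image tests
fast); exact silhouette conics and L = 20 outline points per ellipse, with
optional isotropic Gaussian pixel noise; a triangulated scan mesh of all
spheres plus the blob with optional vertex noise and hemisphere-only
coverage; three control markers near the scene centre. The layout jitter is
not cosmetic: a perfectly regular ring has a rotational correspondence
ambiguity that would defeat any exhaustive matcher. One integer seed drives
everything; equal seeds give byte-identical scenes.

What the generator does **not** emulate: correlated detection errors
(specularities, partial occlusions, blur), lens distortion residuals,
non-Gaussian scanner artefacts, and deformation of the scene between scan
and imaging. Passing tests therefore demonstrate correctness and noise
propagation of the estimator, not end-to-end accuracy on real acquisitions;
the renderer-plus-detector tests close part of that gap by exercising the
image path on anti-aliased renders.

Problem sizes in the tests and the acceptance script (100 closure scenes, 20
scale trials, 20 noise repetitions per level, 1e4 oracle directions, 2e4
Chamfer samples) were chosen to keep Monte-Carlo fluctuation well inside the
asserted bounds at interactive runtimes.

## Known limitations

* The detector assumes uniformly bright (or dark) markers; no colour model.
* The exhaustive correspondence search is O(C(n,4)·P(M,4)); fine for M ≈ 10,
  not meant for hundreds of markers.
* Radius is never estimated; a misprinted marker radius biases the scale
  channel in similarity mode.
* COLMAP binary models are not parsed (text models only).
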