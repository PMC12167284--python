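# spherereg

Sphere-fiducial registration of surface scans to calibrated camera images,
for building submillimeter-accurate 3D ground truth in surgical and
laboratory scenes.

## The problem

To benchmark optical 3D reconstruction or feature matching you need a set of
posed images and a reference surface mesh of the scene **expressed in the same
coordinate frame**. The mesh comes from an optical scanner (or CT) in its own
scan-local frame `S`; the images carry camera poses in a world frame `W`
(from structure-from-motion, or a robot arm's forward kinematics plus a
hand-eye transform). `spherereg` recovers the missing link — the rigid (or
similarity) transform `T_S^W` — from spherical fiducial markers of known
radius placed around the specimen: spheres are easy to localise precisely in
a mesh, and they project to ellipses whose exact shape pins down the pose.

## The model

A sphere with centre **c** and radius *r* is the quadric
`Q = [[I, -c], [-c^T, c^T c - r^2]]`. Under a pinhole camera with projection
matrix `P = K [R | t]` its silhouette is the conic `E` with
`E^{-1} ∝ P Q^{-1} P^T`; every image point **x** on the silhouette satisfies
the bilinear identity `x^T E x = 0`. Registration minimises this identity's
violation over all N images, M markers and L sampled outline points:

    T_S^W  =  argmin  Σ_i Σ_j Σ_l  ‖ x_ijl^T E_ij(T) x_ijl ‖²

solved with Levenberg–Marquardt from a Perspective-n-Point initial estimate
obtained by exhaustive correspondence search over ellipse/sphere centres.
Conics are normalised (unit Frobenius norm, positive-trace 2×2 block) so the
algebraic cost is well-posed. When camera poses come from SfM, a global scale
is estimated jointly; the scale is observable because the marker radius is
known. Internally the conic is evaluated in the numerically stable form
`E ∝ K^{-T} (c_cam c_cam^T − (‖c_cam‖² − r²) I) K^{-1}`, which avoids
inverting the ill-conditioned dual conic.

Accuracy is reported with the metrics standard for this task: **radial
error** (deviation from tangency, in mm, of rays back-projected from outline
points of held-out control markers), **reprojection error** (symmetric mean
geometric distance in px between projected and detected ellipses), and
**Chamfer distance** between meshes.

## Worked example

`examples/03_register_scene.py` builds a synthetic scene (10 markers of
30 mm diameter, 16 views at ~1 m, f = 7000 px, 0.5 px outline noise) and runs
the full pipeline:

```
converged             : True (3 LM iterations)
final cost            : 3.704e-08  (initial 1.854e-07)
rotation error        : 5.26e-05 rad
translation error     : 4.73e-03 mm
mean radial error     : 0.0032 mm over 960 control outline points
```

The radial error is measured on **control markers** excluded from the fit:
each outline pixel back-projects to a ray, and the error is |distance from
the ray to the sphere centre − radius|, i.e. how far the ray misses grazing
the sphere. The other examples cover sphere→ellipse projection, marker
localisation in a noisy scan, SfM scale recovery, ellipse detection on
rendered images, and Chamfer mesh comparison; each prints the numbers it
computes and what they mean.

A thin CLI mirrors the pipeline stages:

```bash
spherereg simulate --out fx --preset desk --seed 5     # synthetic fixture
spherereg fit-markers --mesh fx/scene_mesh.ply --inits fx/marker_inits.txt \
    --radius 15 --out markers.txt
spherereg register --fixture fx --out reg              # -> transform + report
spherereg chamfer a.ply b.ply
```

## Scope

The package consumes camera poses (COLMAP text models or robot pose tables +
hand-eye transform); it does not run SfM, calibrate the hand-eye transform,
or segment CT data. Images are assumed undistorted; the camera model is
pinhole. Meshes are metric (millimetres); SfM worlds may be on any scale —
use `mode="similarity"`.
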