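"""Localise spherical fiducials in a (simulated) optical scan mesh.

The scan sees only the upper hemisphere of each marker and carries
scanner-level vertex noise (sigma = 0.05 mm); the fixed-radius fit still
recovers the centres to a few microns.
"""

import numpy as np

from spherereg import SceneConfig, generate_scene, localize_markers

scene = generate_scene(
    SceneConfig(seed=7, mesh_noise_mm=0.05, mesh_coverage="hemisphere")
)
rng = np.random.default_rng(0)
true_centers = np.array([m.center for m in scene.markers])
inits = true_centers + rng.uniform(-2, 2, true_centers.shape)  # "manual" clicks

results = localize_markers(scene.mesh, radius=15.0, init_centers=inits)
print("marker  centre error (mm)  rms residual (mm)  support vertices")
for k, (res, c) in enumerate(zip(results, true_centers)):
    err = np.linalg.norm(res.marker.center - c)
    print(f"  m{k}     {err:10.5f}       {res.rms_residual_mm:10.5f}       "
          f"{res.n_support_vertices}")
print("Centre errors are ~sigma/sqrt(n): far below the 0.05 mm vertex noise, "
      "because thousands of scan vertices constrain each known-radius sphere.")
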