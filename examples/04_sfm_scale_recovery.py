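"""Similarity-mode registration: camera poses on an arbitrary SfM scale.

Structure-from-motion poses are defined only up to a global scale. The
silhouette of a known-radius sphere fixes the metric, so the registration
jointly estimates the scale. The scale is pre-estimated (correspondence-free)
from the conic sizes and then refined with the pose.
"""

from spherereg import SceneConfig, generate_scene, register_scene
from spherereg.register import estimate_scale_from_conics

TRUE_SCALE = 1.5
scene = generate_scene(SceneConfig(seed=3, true_scale=TRUE_SCALE))
dets = scene.detections(noisy=False)

s0 = estimate_scale_from_conics(dets, scene.cameras, radius=15.0)
result, diag = register_scene(scene.markers, dets, scene.cameras, mode="similarity")

print(f"true scale            : {TRUE_SCALE}")
print(f"conic-size pre-estimate: {s0:.9f}")
print(f"jointly refined scale  : {result.scale:.9f}")
print(f"relative error         : {abs(result.scale - TRUE_SCALE) / TRUE_SCALE:.2e}")
print("The pre-estimate alone is already exact on clean data; under real "
      "detection noise the joint refinement over all images sharpens it.")
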