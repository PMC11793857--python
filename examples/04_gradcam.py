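"""3D GradCAM on a glenohumeral crop.

Computes the class activation map of the osteophyte-size head for one
class: gradients of the class score with respect to the 64 bottleneck
feature maps are spatially averaged into per-map weights, the weighted sum
is ReLU-rectified and upsampled onto the crop.  The localization score
reports how much of the top-decile activation mass falls inside the
humerus region.
"""

import numpy as np

from xcelunet.gradcam import compute_gradcam, localization_score, overlay
from xcelunet.network import NetworkConfig, build_model
from xcelunet.preprocessing import extract_gh_crop, hu_normalize
from xcelunet.synthetic import PhantomParams, generate_phantom

ph = generate_phantom(PhantomParams(grid_shape=(48, 48, 48),
                                    head_radius_mm=10.0,
                                    osteophyte_height_mm=8.0,
                                    osteophyte_count=2, seed=4))
vol = hu_normalize(ph.ct)
crop = extract_gh_crop(vol, ph.labels, crop_edge=32, truth=ph.truth)

model = build_model(NetworkConfig(seed=0))  # untrained weights: maps are
# structured but not clinically meaningful until after stage-2 training
act = compute_gradcam(model, crop, class_set="OS", class_index=2)
print(f"bottleneck map {act.raw.shape} averaged over Z={act.z} positions; "
      f"heatmap upsampled to {act.heatmap.shape}")
print(f"map is non-negative by construction: min = {act.heatmap.min():.4f}")

half = 16
lo = [c - half for c in crop.center_voxel]
region = np.zeros_like(crop.data, dtype=bool)
sl = tuple(slice(max(0, -l), None) for l in lo)
src = ph.labels.data[tuple(slice(max(0, l), l + 32) for l in lo)] == 1
region[:src.shape[0], :src.shape[1], :src.shape[2]] = src
score = localization_score(act, region)
print(f"fraction of top-decile activation inside the humerus: "
      f"{score.fraction:.2f}")

montage = overlay(act, crop)
print(f"overlay montage (axial|coronal|sagittal mid-slices): "
      f"shape {montage.shape}, values in [{montage.min():.2f}, "
      f"{montage.max():.2f}]")
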