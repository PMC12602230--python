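"""Extract the full default radiomic feature vector from one lesion.

The default configuration produces exactly 1,834 features per region:
14 shape descriptors plus 91 intensity/texture features (18 first-order,
22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) on each of 20 image types
(original, 8 wavelet sub-bands, 6 LoG scales, square, square-root,
logarithm, exponential, gradient).  Fusing three habitat subregions gives
3 x 1,834 = 5,502 columns.
"""

import habitatbm as hb
from habitatbm.features import FeatureConfig, extract_region_features, fuse_habitat_features

p = hb.generate_cohort(hb.CohortConfig(n_patients=2, seed=5))[0]
vol, mask = hb.resample_isotropic(p.volume, p.mask)

vec = extract_region_features(vol, mask, FeatureConfig())
n_shape = sum(1 for k in vec if k.startswith("shape__"))
n_first = sum(1 for k in vec if "__firstorder__" in k)
print(f"features extracted: {len(vec)} "
      f"({n_shape} shape, {n_first} first-order, {len(vec) - n_shape - n_first} texture)")

for name in ("shape__Sphericity", "shape__MeshVolume",
             "original__firstorder__Mean", "original__firstorder__Entropy",
             "original__glcm__JointEntropy", "original__glszm__ZoneEntropy"):
    print(f"  {name} = {vec[name]:.4f}")
# Sphericity near 1 means a compact, round lesion; the entropies summarize
# gray-level disorder in the discretized region.

fused, missing = fuse_habitat_features({1: vec, 2: vec, 3: vec}, k=3)
print(f"habitat early fusion: {len(fused)} columns (missing habitats: {missing})")
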