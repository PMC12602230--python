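import numpy as np
import pytest

import habitatbm as hb


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-patient default-condition cohort (small lesions for speed)."""
    cfg = hb.CohortConfig(n_patients=8, lesion_diameter_mm=(10, 18), seed=7)
    return cfg, hb.generate_cohort(cfg)


@pytest.fixture(scope="session")
def resampled_patient(small_cohort):
    """First patient of the small cohort on the 1 mm grid, with features."""
    _, pats = small_cohort
    p = pats[0]
    vol, mask = hb.resample_isotropic(p.volume, p.mask)
    fmap = hb.local_features(vol, mask)
    return p, vol, mask, fmap


def make_sphere(radius_mm: float, spacing=(1.0, 1.0, 1.0), margin: int = 4) -> hb.LabelMask:
    sp = np.asarray(spacing)
    half = np.ceil(radius_mm / sp).astype(int) + margin
    shape = 2 * half + 1
    grids = np.meshgrid(*[(np.arange(n) - n // 2) * s for n, s in zip(shape, sp)], indexing="ij")
    m = (sum(g**2 for g in grids) <= radius_mm**2).astype(np.int32)
    return hb.LabelMask(m, tuple(spacing))


@pytest.fixture(scope="session")
def sphere_mask_5mm():
    return make_sphere(5.0)
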