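import numpy as np
import pandas as pd
import pytest

from limbicvbm import BrainMask, CohortStack, RegionSpec, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def small_regions():
    """Planted spheres scaled to a 16^3 grid."""
    return [
        RegionSpec("amygdala_R", (11, 8, 5), 2.0, "atrophy"),
        RegionSpec("amygdala_R_seed", (11, 8, 5), 2.0, "seed"),
        RegionSpec("hippocampus_R", (8, 11, 11), 2.0, "age_slope"),
        RegionSpec("thalamus", (5, 5, 11), 2.0, "covariance_network"),
    ]


def small_config(**over):
    """Desk-scale synthetic config on a 16^3 grid."""
    defaults = dict(shape=(16, 16, 16), n_control=10, n_pd=12,
                    regions=small_regions(), seed=7)
    defaults.update(over)
    return SyntheticConfig(**defaults)


def make_stack(values, shape=None, mask=None, groups=None, ages=None,
               voxel_mm=2.0):
    """CohortStack straight from a (subjects x voxels) array."""
    values = np.asarray(values, dtype=float)
    n, v = values.shape
    if mask is None:
        if shape is None:
            shape = (v, 1, 1)
        m = np.zeros(shape, dtype=bool)
        m.ravel()[:v] = True
        mask = BrainMask(m, np.diag([voxel_mm] * 3 + [1.0]))
    if groups is None:
        groups = ["control"] * (n // 2) + ["pd"] * (n - n // 2)
    subjects = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "group": groups,
        "age": ages if ages is not None else np.linspace(50, 70, n),
        "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
    })
    return CohortStack(values, mask, np.argwhere(mask.data), subjects)
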