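import numpy as np
import pytest

from neuroattn.io import Cohort, GrayMatterVolume, SubjectRecord
from neuroattn.simulate import (
    SimulationSpec,
    make_toy_parcellation,
    planted_effects,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_parcellation():
    """12-region parcellation on a 16^3 grid."""
    return make_toy_parcellation((16, 16, 16), 12, seed=0)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_parcellation):
    """Small two-group cohort with one strongly planted region."""
    spec = SimulationSpec(grid_shape=(16, 16, 16), n_regions=12,
                          effect_size=planted_effects(12, {5: 2.0}),
                          n_per_group={"NC": 20, "AD": 20},
                          severity_slope_mmse=5.0, noise_sd=0.05, seed=7)
    return simulate_cohort(spec, tiny_parcellation)


def make_cohort_from_arrays(values_list, diagnoses, **extra):
    """Hand-build a cohort from raw 3D arrays (one per subject)."""
    records, volumes = [], {}
    for i, (vals, dx) in enumerate(zip(values_list, diagnoses)):
        sid = f"s{i:03d}"
        fields = {k: (v[i] if isinstance(v, (list, np.ndarray)) else v)
                  for k, v in extra.items()}
        records.append(SubjectRecord(id=sid, diagnosis=dx, **fields))
        volumes[sid] = GrayMatterVolume(values=np.asarray(vals, dtype=float))
    return Cohort(records, volumes)
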