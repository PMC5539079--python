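import numpy as np
import pytest

import endowm as e


@pytest.fixture(scope="session")
def mixture_phantom():
    """Mid-size phantom with a 10% secondary component (no lesions)."""
    spec = e.PhantomSpec(secondary_weight=0.1, seed=42)
    return e.generate_phantom(spec)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Phantom with two planted hyperintense lesions at ~6 sigma."""
    lesions = (
        e.LesionSpec((24, 28, 36), 5.0, 160.0, 8.0),
        e.LesionSpec((40, 40, 36), 4.0, 160.0, 8.0),
    )
    spec = e.PhantomSpec(secondary_weight=0.0, lesions=lesions, seed=7)
    return e.generate_phantom(spec)


@pytest.fixture(scope="session")
def cohort36():
    return e.generate_cohort(e.CohortSpec(n=36, seed=11))


def seg_dataset(n_subjects=20, n_voxels=60, effect_voxels=0, effect_beta=0.0, seed=0):
    data = e.generate_fa_dataset(
        e.FaDatasetSpec(
            n_subjects=n_subjects, n_voxels=n_voxels,
            effect_voxels=effect_voxels, effect_beta=effect_beta, seed=seed,
        )
    )
    return data, e.SkeletonDataset.from_fa_dataset(data)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
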