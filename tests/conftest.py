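import numpy as np
import pytest

from radpcr.imaging_io import LesionMask, VolumeImage
from radpcr.patch_sampling import SamplingPlan, SubjectImaging, build_cohort_patches
from radpcr.synthetic_data import SyntheticCohortConfig, generate_cohort_arrays


def small_cohort_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Reduced-scale cohort for module tests: tiny volumes, 17x17 patches."""
    defaults = dict(
        n_carriers=4,
        n_controls=5,
        volume_shape=(8, 64, 64),
        boundary_margin_voxels=9,
        semi_axes_mm=(5.0, 8.0),
        bilateral_second_volume=False,
        rng_seed=seed,
    )
    defaults.update(overrides)
    return SyntheticCohortConfig(**defaults)


def cohort_subjects(cfg: SyntheticCohortConfig) -> tuple[list[SubjectImaging], list]:
    pairs = generate_cohort_arrays(cfg)
    subjects = [SubjectImaging(s.subject_id, s.label, imgs) for s, imgs in pairs]
    records = [s.record | {"subject_id": s.subject_id} for s, _ in pairs]
    return subjects, records


@pytest.fixture(scope="session")
def small_cohort():
    """(subjects, records, patches) at reduced scale, shared across tests."""
    cfg = small_cohort_config(seed=11)
    subjects, records = cohort_subjects(cfg)
    plan = SamplingPlan(n_per_image=30, patch_size=17, rng_seed=5)
    patches = build_cohort_patches(subjects, plan)
    return subjects, records, patches


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def box_volume():
    """Deterministic ramp volume with a central box lesion mask."""
    shape = (4, 40, 40)
    vox = np.arange(np.prod(shape), dtype=np.float64).reshape(shape)
    vol = VolumeImage(vox, spacing=(3.7, 0.75, 0.75))
    mask_arr = np.zeros(shape, dtype=np.uint8)
    mask_arr[1:3, 15:25, 15:25] = 1
    return vol, LesionMask(mask_arr, spacing=(3.7, 0.75, 0.75))
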