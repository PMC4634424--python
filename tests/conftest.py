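import numpy as np
import pytest

from somtraj.pipeline import build_library, record_features, train_posture_map
from somtraj.som import TrainingSchedule
from somtraj.synthetic_motion import builtin_exercises, generate_dataset, neutral_pose
from somtraj.features import SkeletonFrame


@pytest.fixture(scope="session")
def specs():
    return builtin_exercises()


@pytest.fixture(scope="session")
def cohort(specs):
    """Reduced synthetic cohort shared by the slower integration tests."""
    return generate_dataset(specs, n_subjects=4, reps=3, seed=7)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    return record_features(cohort)


@pytest.fixture(scope="session")
def trained_pmap(cohort, cohort_features):
    return train_posture_map(
        cohort,
        10,
        10,
        TrainingSchedule(seed=7),
        max_train_frames=3000,
        feature_arrays=cohort_features,
    )


@pytest.fixture(scope="session")
def trained_library(trained_pmap, cohort, cohort_features):
    return build_library(
        trained_pmap, cohort, instances_per_label=5, feature_arrays=cohort_features
    )


def random_frame(rng: np.random.Generator, jitter: float = 0.05) -> SkeletonFrame:
    """A valid random skeleton frame: jittered standing pose."""
    arr = neutral_pose() + rng.normal(0.0, jitter, (20, 3))
    return SkeletonFrame.from_array(arr)
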