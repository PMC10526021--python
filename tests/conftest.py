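import numpy as np
import pytest

from selffi.manifest import ImageRecord, read_manifest
from selffi.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Ten synthetic patients (40 images) rendered once per session."""
    out = tmp_path_factory.mktemp("cohort10")
    config = SyntheticConfig(n_patients=10, seed=11)
    manifest, truths = generate_dataset(config, out)
    return {"config": config, "manifest": manifest, "truths": truths, "dir": out}


@pytest.fixture(scope="session")
def labeled_cohort(tmp_path_factory):
    """A cohort with prevalent disease signal, for fine-tuning tests."""
    out = tmp_path_factory.mktemp("cohort_labeled")
    config = SyntheticConfig(
        n_patients=16, seed=5, lesion_contrast=1.0,
        disease_prevalence=(0.5, 0.35, 0.3, 0.3, 0.25, 0.2),
    )
    manifest, truths = generate_dataset(config, out)
    return {"config": config, "manifest": manifest, "truths": truths, "dir": out}


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return read_manifest(small_cohort["manifest"])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_record(image_id="i1", patient_id="p1", eye_side="left", modality="UFI",
                path="img.png", labels=None):
    return ImageRecord(image_id=image_id, patient_id=patient_id,
                       eye_side=eye_side, modality=modality, path=path,
                       labels=labels)
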