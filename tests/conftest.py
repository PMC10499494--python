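import numpy as np
import pytest

from ecglvh import (CANONICAL_LEADS, BeatMorphology, CohortSpec, ECGRecord,
                    generate_cohort, generate_record)


@pytest.fixture(scope="session")
def clean_record():
    """Default-morphology 12-lead record, 60 bpm, 10 s, 500 Hz, mild noise."""
    record, truth = generate_record(seed=11, record_id="clean")
    return record, truth


@pytest.fixture(scope="session")
def noisefree_record():
    """Noise- and wander-free record: measured amplitudes should match truth."""
    morph = BeatMorphology.default(noise_sd_mv=0.0, baseline_wander_amp_mv=0.0)
    record, truth = generate_record(morph, seed=5, record_id="noisefree")
    return record, truth


@pytest.fixture(scope="session")
def default_cohort_200():
    """The 200-subject default cohort used for detector performance checks."""
    return generate_cohort(CohortSpec(n_subjects=200, seed=42))


@pytest.fixture()
def flat_record():
    return ECGRecord("flat", 500.0, list(CANONICAL_LEADS), np.zeros((12, 5000)))
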