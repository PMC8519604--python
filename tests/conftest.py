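import numpy as np
import pytest

import eegmsda as m


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects, 40 segments per class — fast full-pipeline fixture."""
    spec = m.CohortSpec(n_subjects=4, segments_per_class=40, seed=7)
    subjects, meta = m.simulate_cohort(spec)
    return spec, subjects, meta


@pytest.fixture(scope="session")
def tiny_cohort_features(tiny_cohort):
    spec, subjects, _ = tiny_cohort
    return [
        m.extract_features(
            {0: s["awake"], 1: s["fatigue"]}, subject_id=s["subject_id"]
        )
        for s in subjects
    ]


@pytest.fixture(scope="session")
def blob_setup():
    """5 shifted labeled blob domains + 1 unlabeled target, moderate shift."""
    spec = m.BlobSpec(
        n_domains=4, n_classes=2, n_per_class=40, dim=5,
        class_separation=3.0, domain_shift_scale=0.8, seed=11,
    )
    domains, target_labels = m.make_blob_domains(spec)
    return spec, domains, target_labels
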