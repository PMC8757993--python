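import numpy as np
import pytest

from comddm import StudyDesign, TaskConfig, generate_dataset
from comddm.stats import apply_exclusions, attach_evidence_predictors


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def study_dataset():
    """Synthetic study at the default (coupled) preset: 4 participants x 4
    sessions x 1050 trials, i.e. ~4000 retained trials per participant."""
    design = StudyDesign(
        n_participants=4,
        sessions_per_participant=4,
        trials_per_session=1050,
        seed=20260929,
    )
    return generate_dataset(design)


@pytest.fixture(scope="session")
def study_retained(study_dataset, config):
    """Retained trials of the study dataset with evidence predictors."""
    retained, report = apply_exclusions(study_dataset.trials)
    residuals = study_dataset.residuals[retained.index.to_numpy()]
    retained = retained.reset_index(drop=True)
    retained = attach_evidence_predictors(retained, residuals, config)
    return retained, residuals, report
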