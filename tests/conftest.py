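import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from sijbme import evaluate as ev
from sijbme import phantom, pipeline
from sijbme.model import ClassifierConfig
from sijbme.preprocess import NoiseParams

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_params() -> phantom.PhantomParams:
    return phantom.PhantomParams()


@pytest.fixture(scope="session")
def small_cohort(phantom_params):
    """2 positive + 2 negative subjects, fixed seed."""
    exams, manifest = phantom.generate_cohort(2, 2, phantom_params, seed=42)
    return exams, manifest


@dataclasses.dataclass
class TrainedExperiment:
    exams: list
    dataset: pipeline.PatchDataset
    outcomes: list  # one FoldOutcome per repeat


@pytest.fixture(scope="session")
def trained_experiment() -> TrainedExperiment:
    """A 20-subject high-contrast phantom cohort with two trained repeats.

    This is the expensive shared fixture: it runs the full pipeline (noise,
    ROI patches, focal-loss training, median filtering, subject diagnosis)
    on an easily separable cohort so downstream tests can probe recovered
    accuracy, median-filter behaviour and Grad-CAM localization.
    """
    params = phantom.PhantomParams(lesion_contrast=0.8)
    exams, _ = phantom.generate_cohort(14, 6, params, seed=0)
    noise = NoiseParams(gaussian_variance=0.005, poisson_rule="disabled", seed=7)
    dataset = pipeline.build_patch_dataset(
        exams, noise=noise, target_size=(64, 64), with_masks=True
    )
    ids = np.array(sorted(dataset.subject_truth))
    labels = np.array([dataset.subject_truth[s] for s in ids])
    folds = ev.make_folds(ids, labels, n_repeats=2, seed=0)
    outcomes = []
    for k, fold in enumerate(folds):
        cfg = ClassifierConfig(backbone="tiny", input_size=(64, 64), epochs=30, seed=k)
        outcomes.append(pipeline.evaluate_fold(dataset, fold, cfg))
    return TrainedExperiment(exams=exams, dataset=dataset, outcomes=outcomes)
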