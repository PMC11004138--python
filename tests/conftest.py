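import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from milts.mil import Bag, TeacherStudentMIL
from milts.pipeline import RunConfig, run_experiment
from milts.synthetic import SyntheticSpec, generate_cohort, cohort_tiles


def make_bags(cohort, slide_ids=None, tissue_only=True):
    """Bags (tiles + planted labels) for the given slides of a cohort."""
    ids = slide_ids or [s.slide_id for s in cohort.slides]
    return [Bag(sid, cohort_tiles(cohort, sid, tissue_only=tissue_only),
                cohort.truths[sid].label) for sid in ids]


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 patients, 1024 px slides (16 tiles each): fast shared test data."""
    return generate_cohort(SyntheticSpec(n_patients=8, image_size=1024, seed=11))


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort):
    """A briefly trained teacher-student model on the tiny cohort."""
    bags = make_bags(tiny_cohort)
    model = TeacherStudentMIL(epochs=4, batch_size=32, seed=5)
    model.fit(bags)
    return model


def benchmark_config(seed: int = 7) -> RunConfig:
    """The desk-scale synthetic benchmark: 60 slides, witness rates 0.2-0.5,
    small encoder (d=32), 10 epochs, batch 64."""
    return RunConfig(seed=seed, n_patients=60, slides_per_patient=1,
                     image_size=1536, witness_rate_lo=0.2, witness_rate_hi=0.5,
                     epochs=10, batch_size=64, labeled_proportion=0.35,
                     aggregation="attention_mlp", mlp_epochs=300,
                     bootstrap_resamples=1000)


@pytest.fixture(scope="session")
def benchmark_run():
    """Full pipeline on the synthetic benchmark (shared across tests)."""
    return run_experiment(benchmark_config())
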