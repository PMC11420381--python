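"""Shared fixtures: seeded synthetic cohorts prepared for modelling."""

import warnings

import pytest
from hypothesis import HealthCheck, settings

from ttcjoint import cohort, lmm, pk, pipeline

settings.register_profile(
    "deterministic", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_cohort(seed: int, truth: cohort.SyntheticTruth | None = None,
                n_patients: int = 100):
    """Generate a cohort and return (records, survival, truth) ready to fit."""
    cfg = cohort.CohortConfig(n_patients=n_patients)
    truth = truth if truth is not None else cohort.SyntheticTruth()
    long_df, surv_df, truth = cohort.generate_cohort(cfg, truth, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, rec = pipeline.prepare_records(
            long_df, pk.SigmoidParams(), pk.PkConstants(), cfg.dose_levels_mg)
    return rec, surv_df, truth


@pytest.fixture(scope="session")
def default_cohort():
    """One 100-patient cohort at the default generating parameters."""
    return make_cohort(seed=42)


@pytest.fixture(scope="session")
def raw_cohort():
    """Raw (untransformed) tables from the same generator."""
    cfg = cohort.CohortConfig()
    return cohort.generate_cohort(cfg, cohort.SyntheticTruth(), 42)
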