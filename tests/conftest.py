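"""Shared fixtures.

All fixtures are generated programmatically; the expensive ones
(multi-subject cohorts) are session-scoped and reuse one synthesis per
run. The 100-subject Monte-Carlo cohort uses 20-s videos — the
generator's per-second structure (ramp, chunked attention, artifacts) is
duration-invariant, so sign/fraction checks carry over at a fraction of
the cost.
"""

import numpy as np
import pytest

from thetamod.pipeline import RunConfig, cohort_tables
from thetamod.synth import (
    GroundTruth,
    SynthParams,
    build_montage,
    synth_cohort,
    synth_subject,
)


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams()


@pytest.fixture(scope="session")
def montage32():
    return build_montage(32)


@pytest.fixture(scope="session")
def clean_truth() -> GroundTruth:
    return GroundTruth(
        subject_id="S001",
        theta_growth={"social": 0.3, "nonsocial": 0.2},
        repetition_effect={"social": 1.15, "nonsocial": 1.1},
        cognitive_scores={"nonverbal_t_12m": 55.0, "verbal_t_12m": 50.0},
    )


@pytest.fixture(scope="session")
def clean_subject(default_params, clean_truth):
    """One artifact-free, fully attended subject at default amplitudes."""
    params = SynthParams(artifact_rate=0.0, attention_fraction=1.0)
    return synth_subject(params, clean_truth, seed=7)


@pytest.fixture(scope="session")
def mc_cohort100():
    """100 subjects with 20-s videos for Monte-Carlo sign/fraction checks.

    Streams subjects through the pipeline (recordings are released as
    processed). Returns (phenotypes, truths, features, power, qc).
    """
    from thetamod.synth import cohort_plan, iter_cohort

    params = SynthParams(video_duration=20.0, condition_gain=1.5)
    truths, pheno, _ = cohort_plan(params, 100, seed=2024)
    cfg = RunConfig(synth=params)
    feats, power, qc = cohort_tables(
        iter_cohort(params, 100, seed=2024), build_montage(32), cfg
    )
    return pheno, truths, feats, power, qc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
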