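from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

from txconsensus import ConsensusParams, generate_assemblies, generate_truth, run_consensus

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

STUDY_SEED = 0
STUDY_LABELS = ("CLC", "IDBA_tran", "Trinity")


@pytest.fixture(scope="session")
def study_fixture():
    """K=50 planted genes under the default study conditions, run once
    through the full pipeline."""
    from txconsensus.synthetic import default_study_plans

    truth, manifest = generate_truth(n_genes=50, seed=STUDY_SEED)
    assemblies = generate_assemblies(
        truth, manifest, default_study_plans(STUDY_LABELS), seed=STUDY_SEED
    )
    result = run_consensus(assemblies, ConsensusParams())
    return truth, manifest, assemblies, result


@pytest.fixture()
def rng():
    return random.Random(1234)
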