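import pytest
from hypothesis import settings

from ienet import constants as C
from ienet import synthetic_data as syn

settings.register_profile("stable", derandomize=True, database=None, deadline=None)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def default_truth():
    return syn.default_truth()


@pytest.fixture(scope="session")
def reporter_truth(default_truth):
    return default_truth[0]


@pytest.fixture(scope="session")
def decomposition_truth(default_truth):
    return default_truth[2]


@pytest.fixture(scope="session")
def noiseless_reporter_truth(reporter_truth):
    return syn.ReporterTruth(
        dict(reporter_truth.basal_promoter_effects),
        dict(reporter_truth.interaction_effects),
        set_replicate_sd=0.0,
        residual_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_decomposition_truth(decomposition_truth):
    return syn.DecompositionTruth(
        {t: dict(v) for t, v in decomposition_truth.coefficients.items()},
        replicate_sd=0.0,
        residual_sd=0.0,
    )


@pytest.fixture(scope="session")
def null_reporter_truth(reporter_truth):
    """All true promoter:driver interactions zero, default noise."""
    return syn.ReporterTruth(
        dict(reporter_truth.basal_promoter_effects), {}
    )
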