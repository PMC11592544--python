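import pytest

from osascreen import TANClassifier, encode_cohort, generate_cohort
from osascreen.simulate import reference_tan_model


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded synthetic cohort at the reference size (n=216)."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def fitted_model(default_cohort):
    """TAN fitted on a seeded synthetic cohort (AHI >= 5 outcome)."""
    X = encode_cohort(default_cohort)
    y = [r.ahi_events_per_hour >= 5 for r in default_cohort]
    return TANClassifier(alpha=1.0).fit(X, y)


@pytest.fixture(scope="session")
def ref_model():
    """The hand-specified ground-truth TAN used for recovery studies."""
    return reference_tan_model()
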