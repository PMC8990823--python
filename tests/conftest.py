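import pytest

from faersvig.synthetic import ScenarioConfig, generate


@pytest.fixture(scope="session")
def small_quarter():
    """A compact synthetic quarter with all messiness switched on."""
    cfg = ScenarioConfig(
        n_exposed=150,
        n_control=350,
        true_or=3.0,
        baseline_event_prob=0.10,
        dup_version_prob=0.2,
        exact_dup_prob=0.05,
        partial_date_prob=0.3,
        preexisting_event_prob=0.03,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def clean_quarter():
    """No duplicates, no partial dates, no pre-existing events: the
    pipeline should recover the planted table exactly."""
    cfg = ScenarioConfig(
        n_exposed=100,
        n_control=300,
        true_or=2.5,
        baseline_event_prob=0.08,
        dup_version_prob=0.0,
        exact_dup_prob=0.0,
        partial_date_prob=0.0,
        preexisting_event_prob=0.0,
        seed=7,
    )
    return generate(cfg)
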