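import pytest

from fibrostage.cohort_sim import nash_preset, sample_cohort


@pytest.fixture(scope="session")
def nash_cohort():
    """A 140-record biopsy-labelled NASH-like cohort (stage counts 38/23/79)."""
    return sample_cohort(nash_preset(), seed=20240917)
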