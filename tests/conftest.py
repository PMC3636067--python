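import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_series(times, scores, pid="P1", labels=None):
    from pdfluct import SymptomSeries

    return SymptomSeries(
        patient_id=pid, times=np.asarray(times, float),
        scores=np.asarray(scores), labels=labels,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient simulated cohort with ground truth (session-cached)."""
    from pdfluct import CohortSimSpec, simulate_cohort

    return simulate_cohort(CohortSimSpec(n_patients=12, seed=42))
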