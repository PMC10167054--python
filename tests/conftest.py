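import numpy as np
import pytest

from corticoflow.pipeline import analyze_cohort
from corticoflow.protocol import ProtocolSpec, Timeline, build_timeline
from corticoflow.synthetic import Cohort

#: seed of the default synthetic study cohort
COHORT_SEED = 7


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_protocol() -> ProtocolSpec:
    """Reduced session (1-min relaxation, 2 cycles) for fast unit tests."""
    return ProtocolSpec(relaxation_s=60.0, repetitions=2)


@pytest.fixture
def task_only_timeline() -> Timeline:
    """A single 6-s task block, for segment-level EMG tests."""
    return Timeline.from_records([{"label": "task", "start_s": 0.0, "end_s": 6.0}])


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort: 21 subjects, 4 conditions."""
    return Cohort(n_subjects=21, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_cohort_result(default_cohort):
    """Full pipeline output on the default cohort (shared; expensive)."""
    return analyze_cohort(default_cohort)
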