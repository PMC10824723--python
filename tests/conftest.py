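import numpy as np
import pytest
from hypothesis import settings

from ppspace import ExperimentDesign, TrialRecord

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def design_exp1():
    return ExperimentDesign.exp1()


@pytest.fixture
def design_exp2():
    return ExperimentDesign.exp2()


def make_trial(
    pid="P01",
    condition="baseline",
    trial_type="test",
    launcher="center",
    distance=1.25,
    rt=0.28,
    status="valid",
    experiment="exp1",
):
    return TrialRecord(
        participant_id=pid,
        experiment=experiment,
        condition=condition,
        trial_type=trial_type,
        launcher=launcher,
        distance_m=distance,
        rt_s=rt,
        response_status=status,
    )


def trials_from_means(means_by_distance, pid="P01", condition="baseline", n_per=1):
    """One participant's central test trials whose per-distance means are the
    given mapping (each distance gets n_per identical RTs)."""
    trials = []
    for d, rt in means_by_distance.items():
        for _ in range(n_per):
            trials.append(make_trial(pid=pid, condition=condition, distance=d, rt=rt))
    return trials


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
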