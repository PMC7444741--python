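import numpy as np
import pytest

from pfcsim import (
    EngineSettings,
    TrialCondition,
    build_task_model,
    run_trial,
)


@pytest.fixture(scope="session")
def task_model():
    return build_task_model()


@pytest.fixture(scope="session")
def settings():
    return EngineSettings()


@pytest.fixture(scope="session")
def intact_trial(task_model, settings):
    """One intact traced trial: attend-vision rule, blue target."""
    return run_trial(
        task_model,
        settings,
        TrialCondition(rule=0, target=0),
        np.random.default_rng(1),
        record_trace=True,
    )


@pytest.fixture(scope="session")
def intact_trial_audition(task_model, settings):
    """One intact traced trial under the attend-audition rule."""
    return run_trial(
        task_model,
        settings,
        TrialCondition(rule=1, target=1),
        np.random.default_rng(2),
        record_trace=True,
    )
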