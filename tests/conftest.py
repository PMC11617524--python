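import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gazeassist as ga
from gazeassist import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def skeleton():
    return sd.SkeletonModel()


@pytest.fixture
def short_script():
    """One stand/sit cycle, scripted indices at the expert means."""
    return sd.MotionScript(
        peak_flexion_deg=41.0, com_velocity_ms=0.436, com_bos_m=-0.023,
        n_cycles=1,
    )


@pytest.fixture
def clean_trial(short_script, skeleton):
    """A noise-free single-cycle trial with a trivial gaze stream."""
    markers = sd.generate_motion(short_script, skeleton)
    grf = sd.generate_grf(short_script)
    static = sd.generate_static(skeleton)
    n_gaze = int(round(short_script.duration_s * 50)) + 1
    gaze = ga.GazeStream(
        np.arange(n_gaze) * 20.0, np.zeros((n_gaze, 2)),
        np.ones(n_gaze, dtype=bool),
    )
    meta = {
        "n_cycles": short_script.n_cycles,
        "support_window_s": list(short_script.support_window),
        "hand_release_s": short_script.support_window[1],
        "group": "expert", "participant_id": "E01", "trial_id": "E01T1",
    }
    return ga.TrialDataset(markers, grf, gaze, static, meta)


@pytest.fixture
def standing_markers(skeleton):
    """A short static standing capture (all markers visible)."""
    return sd.generate_static(skeleton, duration_s=0.2)
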