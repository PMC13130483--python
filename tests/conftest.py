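import numpy as np
import pytest

from eden_gaze.io import GazeTrial, normalize_coordinates
from eden_gaze.synthetic import SynthConfig, simulate_trials


def make_trial(
    x,
    y,
    valid=None,
    rate_hz=50.0,
    participant_id="P000",
    stimulus_id="S00",
    normalized=False,
):
    """Build a GazeTrial from coordinate lists on a regular time grid."""
    x = np.asarray(x, float)
    if valid is None:
        valid = ~np.isnan(x)
    return GazeTrial(
        participant_id=participant_id,
        stimulus_id=stimulus_id,
        t_ms=np.arange(len(x)) * (1000.0 / rate_hz),
        x_px=x,
        y_px=np.asarray(y, float),
        valid=np.asarray(valid, bool),
        sampling_rate_hz=rate_hz,
        normalized=normalized,
    )


@pytest.fixture(scope="session")
def small_cohorts():
    """Small two-cohort simulation shared across tests (4+4 x 2 stimuli)."""
    cfg = SynthConfig(n_participants_per_cohort=4, n_stimuli=2, k_true=4, seed=11)
    trials, gt = simulate_trials(cfg)
    return cfg, trials, gt


@pytest.fixture(scope="session")
def small_cohorts_normalized(small_cohorts):
    cfg, trials, gt = small_cohorts
    norm = [normalize_coordinates(t, cfg.stim_width_px, cfg.stim_height_px)
            for t in trials]
    return cfg, norm, gt
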