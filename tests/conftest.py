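import numpy as np
import pytest

from alphalight.containers import EpochSet
from alphalight.synth import GeneratorParams, ScheduleConfig


@pytest.fixture
def quiet_params():
    """Generator with every noise source and effect switched off."""
    return GeneratorParams(
        light_gain_right=(1.0, 1.0, 1.0),
        light_gain_left=(1.0, 1.0, 1.0),
        desync_depth=0.0,
        tot_alpha_slope=0.0,
        alpha_trial_sigma=0.0,
        alpha_shared_sigma=0.0,
        alpha_subject_sd=0.0,
        alpha_hemisphere_sd=0.0,
        hemifield_offset_ms=0.0,
        light_left_rt_effect_ms=(0.0, 0.0, 0.0),
        alpha_rt_slope_ms=(0.0, 0.0, 0.0),
        tot_rt_interaction_ms=0.0,
        subject_intercept_sd_ms=0.0,
        subject_hemifield_sd_ms=0.0,
        subject_alpha_slope_sd_ms=0.0,
        resid_sd_ms=0.0,
        miss_rate=0.0,
        artifact_rate=0.0,
        noise_sd_uv=0.0,
    )


@pytest.fixture
def small_schedule():
    return ScheduleConfig(n_blocks=1)


def make_epochs(voltages, fs=500.0, t_start_ms=-700.0, labels=None):
    voltages = np.asarray(voltages, dtype=np.float32)
    if labels is None:
        labels = [f"Ch{i}" for i in range(voltages.shape[1])]
    return EpochSet(voltages=voltages, fs=fs, t_start_ms=t_start_ms,
                    channel_labels=labels)


@pytest.fixture
def epoch_factory():
    return make_epochs
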