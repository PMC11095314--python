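import numpy as np
import pytest

import phyloemg as pe


@pytest.fixture(scope="session")
def snr5_recording():
    """One-channel recording with nine 300 ms bursts at SNR 5 (gain/background)."""
    strides = pe.gen_stride_events(9, stance_s=0.5, swing_s=0.2, seed=0, start_s=0.5)
    sched = pe.stride_burst_schedule(
        "PEC_sim_ch1", strides, onset_in_stance=0.0, offset_in_stance=0.6,
        gain=25.0, background_rms=5.0,
    )
    duration = float(strides.touchdowns[-1] + 0.5)
    rec, truth = pe.gen_emg_recording(sched, fs=5000.0, duration=duration, seed=1)
    return rec, truth, strides


@pytest.fixture(scope="session")
def snr5_processed(snr5_recording):
    rec, truth, strides = snr5_recording
    processed = pe.process_emg(rec, pe.RunConfig(seed=1))
    return processed["PEC_sim_ch1"], truth, strides


@pytest.fixture()
def square_envelope():
    """Noise-free square envelope: 1 s baseline 0.1, 1 s plateau 1.0, 1 s baseline."""
    fs = 500.0
    env = np.full(1500, 0.1)
    env[500:1000] = 1.0
    return env, fs
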