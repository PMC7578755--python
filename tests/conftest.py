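import numpy as np
import pytest

from gesturelat.io import AccelRecording, BimanualSession, TaskWindow
from gesturelat.preprocess import EpochSeries, FilteredSignal


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_recording(
    samples,
    fs=50.0,
    t0=0.0,
    participant_id="p01",
    arm_side="right",
    arm_role="intact",
):
    return AccelRecording(
        participant_id=participant_id,
        arm_side=arm_side,
        arm_role=arm_role,
        fs=fs,
        t0=t0,
        samples=np.asarray(samples, dtype=float),
    )


def constant_recording(duration_s, fs=50.0, vec=(0.0, 0.0, 1.0), **kw):
    n = int(round(duration_s * fs))
    return make_recording(np.tile(vec, (n, 1)), fs=fs, **kw)


def make_session(rec_a, rec_b, windows=None):
    return BimanualSession(
        participant_id=rec_a.participant_id,
        recording_a=rec_a,
        recording_b=rec_b,
        windows=windows or [TaskWindow("task", 0.0, min(rec_a.duration_s, rec_b.duration_s))],
    )


def make_epochs(mag1, mag2, threshold=0.01, epoch_len=1.0):
    mag1 = np.asarray(mag1, dtype=float)
    mag2 = np.asarray(mag2, dtype=float)
    return EpochSeries(
        participant_id="p01",
        epoch_len_s=epoch_len,
        activity_threshold_g=threshold,
        arm1_role="intact",
        arm2_role="prosthesis",
        t_start_s=np.arange(len(mag1), dtype=float) * epoch_len,
        mag_arm1=mag1,
        mag_arm2=mag2,
        active_arm1=mag1 >= threshold,
        active_arm2=mag2 >= threshold,
    )


def make_signal(mag, fs=50.0, t0=0.0, arm_role="intact"):
    return FilteredSignal(
        participant_id="p01", arm_role=arm_role, fs=fs, t0=t0,
        mag=np.asarray(mag, dtype=float),
    )
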