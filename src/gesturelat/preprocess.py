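"""Gravity removal, movement magnitude, and per-second epoching.

The movement-intensity signal is the Euclidean norm of the gravity-removed
tri-axial acceleration. Gravity is removed either by a zero-phase Butterworth
high-pass per axis (default, order 4, 0.25 Hz cutoff — standard practice for
wrist-worn accelerometry of voluntary movement) or by subtracting 1 g from the
raw vector magnitude. Magnitudes are then averaged within consecutive
half-open epochs (default 1 s, matching the second-by-second laterality
analysis downstream); an arm is "active" in an epoch when its mean magnitude
reaches the activity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .io import AccelRecording, BimanualSession, RecordingError

DEFAULT_CUTOFF_HZ = 0.25
DEFAULT_EPOCH_LEN_S = 1.0
DEFAULT_ACTIVITY_THRESHOLD_G = 0.01


@dataclass
class FilteredSignal:
    """Gravity-removed movement magnitude for one arm.

    ``mag`` holds per-sample magnitudes in g at the recording's timebase.
    """

    participant_id: str
    arm_role: str
    fs: float
    t0: float
    mag: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.mag)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class EpochSeries:
    """Time-aligned per-epoch movement magnitudes for both arms.

    Arm 1 is the preferred arm (intact / dominant), arm 2 the nonpreferred arm
    (prosthesis / nondominant); the laterality sign convention downstream
    depends on this ordering.
    """

    participant_id: str
    epoch_len_s: float
    activity_threshold_g: float
    arm1_role: str
    arm2_role: str
    t_start_s: np.ndarray
    mag_arm1: np.ndarray
    mag_arm2: np.ndarray
    active_arm1: np.ndarray
    active_arm2: np.ndarray

    def __post_init__(self) -> None:
        self.t_start_s = np.asarray(self.t_start_s, dtype=float)
        self.mag_arm1 = np.asarray(self.mag_arm1, dtype=float)
        self.mag_arm2 = np.asarray(self.mag_arm2, dtype=float)
        self.active_arm1 = np.asarray(self.active_arm1, dtype=bool)
        self.active_arm2 = np.asarray(self.active_arm2, dtype=bool)
        n = len(self.t_start_s)
        for arr in (self.mag_arm1, self.mag_arm2, self.active_arm1, self.active_arm2):
            if len(arr) != n:
                raise ValueError("all per-epoch arrays must share one timebase")
        if (self.mag_arm1 < 0).any() or (self.mag_arm2 < 0).any():
            raise ValueError("epoch magnitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.t_start_s)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpochSeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.epoch_len_s == other.epoch_len_s
            and self.activity_threshold_g == other.activity_threshold_g
            and self.arm1_role == other.arm1_role
            and self.arm2_role == other.arm2_role
            and np.array_equal(self.t_start_s, other.t_start_s)
            and np.array_equal(self.mag_arm1, other.mag_arm1)
            and np.array_equal(self.mag_arm2, other.mag_arm2)
            and np.array_equal(self.active_arm1, other.active_arm1)
            and np.array_equal(self.active_arm2, other.active_arm2)
        )

    def swapped(self) -> "EpochSeries":
        """The same series with the two arms' roles exchanged."""
        return EpochSeries(
            participant_id=self.participant_id,
            epoch_len_s=self.epoch_len_s,
            activity_threshold_g=self.activity_threshold_g,
            arm1_role=self.arm2_role,
            arm2_role=self.arm1_role,
            t_start_s=self.t_start_s,
            mag_arm1=self.mag_arm2,
            mag_arm2=self.mag_arm1,
            active_arm1=self.active_arm2,
            active_arm2=self.active_arm1,
        )


def sample_magnitude(ax, ay, az):
    """Euclidean norm sqrt(ax^2 + ay^2 + az^2) of a tri-axial sample, in g."""
    return np.sqrt(np.square(ax) + np.square(ay) + np.square(az))


def remove_gravity(
    rec: AccelRecording,
    method: str = "highpass",
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = 4,
) -> FilteredSignal:
    """Remove the gravity component and return per-sample movement magnitude.

    ``highpass`` applies a zero-phase (forward-backward) Butterworth high-pass
    of the given order per axis and takes the vector magnitude; static posture
    maps to ~0 while dynamic content above the cutoff passes essentially
    unattenuated. ``magnitude_minus_1g`` takes |norm(a) - 1 g|, a cruder
    filter-free alternative.
    """
    if method == "highpass":
        nyq = rec.fs / 2.0
        if cutoff_hz >= nyq:
            raise RecordingError(
                f"high-pass cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)"
            )
        sos = _signal.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
        filtered = _signal.sosfiltfilt(sos, rec.samples, axis=0)
        mag = np.linalg.norm(filtered, axis=1)
    elif method == "magnitude_minus_1g":
        mag = np.abs(np.linalg.norm(rec.samples, axis=1) - 1.0)
    else:
        raise ValueError(f"unknown gravity-removal method {method!r}")
    return FilteredSignal(
        participant_id=rec.participant_id,
        arm_role=rec.arm_role,
        fs=rec.fs,
        t0=rec.t0,
        mag=mag,
    )


def _epoch_means(sig: FilteredSignal, start_s: float, end_s: float, epoch_len_s: float):
    """Mean magnitude per half-open epoch [start + k*L, start + (k+1)*L)."""
    n_epochs = int(np.floor((end_s - start_s) / epoch_len_s + 1e-9))
    starts = start_s + epoch_len_s * np.arange(n_epochs)
    means = np.empty(n_epochs)
    for k in range(n_epochs):
        lo = starts[k]
        hi = lo + epoch_len_s
        i0 = int(np.ceil((lo - sig.t0) * sig.fs - 1e-9))
        i1 = int(np.ceil((hi - sig.t0) * sig.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, sig.n_samples)
        if i1 <= i0:
            raise RecordingError(
                f"epoch [{lo:.3f}, {hi:.3f}) contains no samples of the "
                f"{sig.arm_role} recording"
            )
        means[k] = sig.mag[i0:i1].mean()
    return starts, means


def epoch_magnitudes(
    session: BimanualSession,
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
    activity_threshold_g: float = DEFAULT_ACTIVITY_THRESHOLD_G,
    method: str = "highpass",
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
) -> EpochSeries:
    """Aggregate both arms to aligned per-epoch mean magnitudes over all windows.

    Each task window is cut into consecutive epochs of ``epoch_len_s``; the
    trailing partial epoch is dropped. A window shorter than one epoch raises.
    """
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    for w in session.windows:
        if w.duration_s < epoch_len_s:
            raise RecordingError(
                f"window {w.label!r} ({w.duration_s:.3f}s) is shorter than one "
                f"epoch ({epoch_len_s}s)"
            )
    sig1 = remove_gravity(session.preferred, method=method, cutoff_hz=cutoff_hz)
    sig2 = remove_gravity(session.nonpreferred, method=method, cutoff_hz=cutoff_hz)
    t_all, m1_all, m2_all = [], [], []
    for w in sorted(session.windows, key=lambda w: w.start_s):
        t, m1 = _epoch_means(sig1, w.start_s, w.end_s, epoch_len_s)
        _, m2 = _epoch_means(sig2, w.start_s, w.end_s, epoch_len_s)
        t_all.append(t)
        m1_all.append(m1)
        m2_all.append(m2)
    t = np.concatenate(t_all)
    m1 = np.concatenate(m1_all)
    m2 = np.concatenate(m2_all)
    return EpochSeries(
        participant_id=session.participant_id,
        epoch_len_s=epoch_len_s,
        activity_threshold_g=activity_threshold_g,
        arm1_role=session.preferred.arm_role,
        arm2_role=session.nonpreferred.arm_role,
        t_start_s=t,
        mag_arm1=m1,
        mag_arm2=m2,
        active_arm1=m1 >= activity_threshold_g,
        active_arm2=m2 >= activity_threshold_g,
    )
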