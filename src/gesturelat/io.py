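"""Reading, validating, aligning and writing bilateral accelerometry recordings.

The canonical raw dialect is a headered CSV with columns
``time_s, ax_g, ay_g, az_g``. The sampling rate is taken from the dialect if
declared, otherwise inferred from the median time step; relative timing jitter
beyond 1% is rejected as an inconsistent sampling rate. Acceleration declared
in m/s^2 is converted to g on read (division by standard gravity, 9.80665).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.80665  # m/s^2 per g

#: arm roles whose owner is expected to favour that arm
PREFERRED_ROLES = frozenset({"intact", "dominant"})
#: arm roles of the prosthesis / nondominant arm (the "nonpreferred" arm)
NONPREFERRED_ROLES = frozenset({"prosthesis", "nondominant"})
VALID_ROLES = PREFERRED_ROLES | NONPREFERRED_ROLES
VALID_SIDES = frozenset({"left", "right"})


class RecordingError(ValueError):
    """Raised when a recording or session violates its contract."""


@dataclass(frozen=True)
class CsvDialect:
    """Describes how a raw tri-axial CSV is laid out.

    Parameters
    ----------
    time_col, x_col, y_col, z_col
        Column names. ``time_col=None`` means the file has no time column and
        ``fs`` must be declared.
    units
        ``"g"`` or ``"m/s2"``; m/s^2 values are divided by 9.80665 on read.
    fs
        Sampling rate in Hz. ``None`` derives it from the time column.
    float_digits
        Significant digits used when writing; the read/write roundtrip is exact
        to this precision.
    """

    time_col: str | None = "time_s"
    x_col: str = "ax_g"
    y_col: str = "ay_g"
    z_col: str = "az_g"
    units: str = "g"
    fs: float | None = None
    float_digits: int = 6

    def __post_init__(self) -> None:
        if self.units not in ("g", "m/s2"):
            raise ValueError(f"unknown units {self.units!r}; expected 'g' or 'm/s2'")
        if self.time_col is None and self.fs is None:
            raise ValueError("dialect must declare fs when there is no time column")


@dataclass
class AccelRecording:
    """One wrist's tri-axial acceleration time series.

    ``samples`` is an (n, 3) float array in units of g; sample k occurs at
    ``t0 + k / fs`` seconds.
    """

    participant_id: str
    arm_side: str
    arm_role: str
    fs: float
    t0: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise RecordingError("samples must be an (n, 3) array")
        if self.samples.shape[0] < 1:
            raise RecordingError("recording must contain at least one sample")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise RecordingError(f"sampling rate must be positive, got {self.fs}")
        if self.arm_side not in VALID_SIDES:
            raise RecordingError(f"arm_side must be left/right, got {self.arm_side!r}")
        if self.arm_role not in VALID_ROLES:
            raise RecordingError(
                f"arm_role must be one of {sorted(VALID_ROLES)}, got {self.arm_role!r}"
            )
        if np.isnan(self.samples).any():
            bad = int(np.argwhere(np.isnan(self.samples).any(axis=1))[0, 0])
            raise RecordingError(
                f"NaN sample at row {bad}; reject or gap-fill before constructing"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class TaskWindow:
    """A labelled task interval, seconds relative to session start, half-open."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise RecordingError(
                f"window {self.label!r}: end ({self.end_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BimanualSession:
    """Two time-aligned wrist recordings plus the task windows analysed.

    ``role_map`` maps arm side to role, e.g. ``{"left": "prosthesis",
    "right": "intact"}``; it must agree with the recordings' own roles.
    """

    participant_id: str
    recording_a: AccelRecording
    recording_b: AccelRecording
    windows: list[TaskWindow]
    role_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a, b = self.recording_a, self.recording_b
        if a.participant_id != b.participant_id:
            raise RecordingError("recordings belong to different participants")
        if a.arm_side == b.arm_side:
            raise RecordingError(f"both recordings are {a.arm_side} side")
        if not self.role_map:
            self.role_map = {a.arm_side: a.arm_role, b.arm_side: b.arm_role}
        for rec in (a, b):
            if self.role_map.get(rec.arm_side) != rec.arm_role:
                raise RecordingError(
                    f"role_map says {rec.arm_side}={self.role_map.get(rec.arm_side)!r} "
                    f"but recording declares {rec.arm_role!r}"
                )
        roles = {a.arm_role, b.arm_role}
        if not (len(roles & PREFERRED_ROLES) == 1 and len(roles & NONPREFERRED_ROLES) == 1):
            raise RecordingError(
                f"session needs one preferred (intact/dominant) and one nonpreferred "
                f"(prosthesis/nondominant) arm, got {sorted(roles)}"
            )

    @property
    def preferred(self) -> AccelRecording:
        """The intact (one-handers) or dominant (controls) arm's recording."""
        a = self.recording_a
        return a if a.arm_role in PREFERRED_ROLES else self.recording_b

    @property
    def nonpreferred(self) -> AccelRecording:
        """The prosthesis (one-handers) or nondominant arm's recording."""
        a = self.recording_a
        return a if a.arm_role in NONPREFERRED_ROLES else self.recording_b

    @property
    def total_task_s(self) -> float:
        return sum(w.duration_s for w in self.windows)


def read_recording(
    path,
    dialect: CsvDialect = CsvDialect(),
    *,
    participant_id: str = "unknown",
    arm_side: str = "left",
    arm_role: str = "intact",
    max_rel_jitter: float = 0.01,
) -> AccelRecording:
    """Read one wrist's CSV and return a validated :class:`AccelRecording`.

    Raises :class:`RecordingError` for missing columns, non-monotone time,
    sampling jitter above ``max_rel_jitter`` relative to the median step,
    an all-NaN axis, or any NaN sample (the default NaN policy is reject;
    interpolate short gaps beforehand with :func:`fill_gaps` if desired).
    """
    df = pd.read_csv(path)
    needed = [c for c in (dialect.time_col, dialect.x_col, dialect.y_col, dialect.z_col) if c]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise RecordingError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    xyz = df[[dialect.x_col, dialect.y_col, dialect.z_col]].to_numpy(dtype=float)
    for ax_i, name in enumerate((dialect.x_col, dialect.y_col, dialect.z_col)):
        if np.isnan(xyz[:, ax_i]).all():
            raise RecordingError(f"{path}: axis column {name!r} is entirely NaN")
    if dialect.units == "m/s2":
        xyz = xyz / STANDARD_GRAVITY

    t0 = 0.0
    fs = dialect.fs
    if dialect.time_col is not None:
        t = df[dialect.time_col].to_numpy(dtype=float)
        t0 = float(t[0])
        if len(t) > 1:
            dt = np.diff(t)
            bad = np.argwhere(dt <= 0)
            if bad.size:
                raise RecordingError(
                    f"{path}: non-monotone time at row {int(bad[0, 0]) + 1}"
                )
            med = float(np.median(dt))
            jitter = np.abs(dt - med) / med
            bad = np.argwhere(jitter > max_rel_jitter)
            if bad.size:
                row = int(bad[0, 0]) + 1
                raise RecordingError(
                    f"{path}: inconsistent sampling at row {row} "
                    f"(step {dt[row - 1]:.6g}s vs median {med:.6g}s)"
                )
            if fs is None:
                fs = 1.0 / med
        elif fs is None:
            raise RecordingError(f"{path}: cannot derive fs from a single sample")
    return AccelRecording(
        participant_id=participant_id,
        arm_side=arm_side,
        arm_role=arm_role,
        fs=float(fs),
        t0=t0,
        samples=xyz,
    )


def write_recording(rec: AccelRecording, path, dialect: CsvDialect = CsvDialect()) -> None:
    """Write a recording in the canonical CSV dialect (always in g)."""
    fmt = f"%.{dialect.float_digits}g"
    df = pd.DataFrame(
        {
            dialect.time_col or "time_s": rec.times(),
            dialect.x_col: rec.samples[:, 0],
            dialect.y_col: rec.samples[:, 1],
            dialect.z_col: rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=fmt)


def fill_gaps(rec: AccelRecording, max_gap_s: float = 0.2) -> AccelRecording:
    """Linearly interpolate NaN runs no longer than ``max_gap_s``.

    Longer runs raise :class:`RecordingError`. Operates on an (n, 3) array that
    may contain NaNs, so it must be applied to raw arrays *before*
    :class:`AccelRecording` construction; provided for device dropouts.
    """
    xyz = np.array(rec.samples, dtype=float, copy=True)
    max_run = int(round(max_gap_s * rec.fs))
    for ax in range(3):
        col = xyz[:, ax]
        isnan = np.isnan(col)
        if not isnan.any():
            continue
        idx = np.flatnonzero(isnan)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if len(run) > max_run or run[0] == 0 or run[-1] == len(col) - 1:
                raise RecordingError(
                    f"NaN gap of {len(run)} samples at row {run[0]} exceeds "
                    f"max_gap_s={max_gap_s} or touches the recording edge"
                )
        good = ~isnan
        col[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(good), col[good])
    return replace(rec, samples=xyz)


def build_session(
    rec_a: AccelRecording,
    rec_b: AccelRecording,
    windows: list[TaskWindow],
    role_map: dict[str, str] | None = None,
) -> BimanualSession:
    """Assemble a bimanual session, clipping windows to the recordings' overlap.

    Windows are clipped (with a log message) to the temporal intersection of
    the two recordings; windows wholly outside it raise.
    """
    lo = max(rec_a.t0, rec_b.t0)
    hi = min(rec_a.t_end, rec_b.t_end)
    if hi <= lo:
        raise RecordingError(
            f"recordings do not overlap in time ([{rec_a.t0}, {rec_a.t_end}) vs "
            f"[{rec_b.t0}, {rec_b.t_end}))"
        )
    _check_no_overlap(windows)
    clipped: list[TaskWindow] = []
    for w in windows:
        s, e = max(w.start_s, lo), min(w.end_s, hi)
        if e <= s:
            raise RecordingError(
                f"window {w.label!r} [{w.start_s}, {w.end_s}) lies outside the "
                f"recordings' common span [{lo:.3f}, {hi:.3f})"
            )
        if (s, e) != (w.start_s, w.end_s):
            log.info(
                "window %r clipped from [%.3f, %.3f) to [%.3f, %.3f)",
                w.label, w.start_s, w.end_s, s, e,
            )
        clipped.append(TaskWindow(w.label, s, e))
    return BimanualSession(
        participant_id=rec_a.participant_id,
        recording_a=rec_a,
        recording_b=rec_b,
        windows=clipped,
        role_map=role_map or {},
    )


def _check_no_overlap(windows: list[TaskWindow]) -> None:
    ordered = sorted(windows, key=lambda w: w.start_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_s < prev.end_s:
            raise RecordingError(f"windows {prev.label!r} and {nxt.label!r} overlap")


# -- epoch table I/O ---------------------------------------------------------

EPOCH_COLUMNS = [
    "epoch_index", "t_start_s", "mag_arm1_g", "mag_arm2_g", "active_arm1", "active_arm2",
]


def write_epochs(epochs, path) -> None:
    """Write an :class:`~gesturelat.preprocess.EpochSeries` to CSV.

    Metadata (participant, epoch length, roles, threshold) goes into ``#``
    comment lines so ``read_epochs(write_epochs(x)) == x``.
    """
    buf = _io.StringIO()
    buf.write(f"# participant_id={epochs.participant_id}\n")
    buf.write(f"# epoch_len_s={epochs.epoch_len_s!r}\n")
    buf.write(f"# activity_threshold_g={epochs.activity_threshold_g!r}\n")
    buf.write(f"# arm1_role={epochs.arm1_role}\n")
    buf.write(f"# arm2_role={epochs.arm2_role}\n")
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(len(epochs.t_start_s), dtype=int),
            "t_start_s": epochs.t_start_s,
            "mag_arm1_g": epochs.mag_arm1,
            "mag_arm2_g": epochs.mag_arm2,
            "active_arm1": epochs.active_arm1.astype(int),
            "active_arm2": epochs.active_arm2.astype(int),
        }
    )
    df.to_csv(buf, index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_epochs(path):
    """Inverse of :func:`write_epochs`."""
    from .preprocess import EpochSeries  # local import to avoid a cycle

    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingError(f"{path}: epoch CSV missing columns {missing}")
    return EpochSeries(
        participant_id=meta.get("participant_id", "unknown"),
        epoch_len_s=float(meta.get("epoch_len_s", 1.0)),
        activity_threshold_g=float(meta.get("activity_threshold_g", 0.01)),
        arm1_role=meta.get("arm1_role", "intact"),
        arm2_role=meta.get("arm2_role", "prosthesis"),
        t_start_s=df["t_start_s"].to_numpy(float),
        mag_arm1=df["mag_arm1_g"].to_numpy(float),
        mag_arm2=df["mag_arm2_g"].to_numpy(float),
        active_arm1=df["active_arm1"].to_numpy(bool),
        active_arm2=df["active_arm2"].to_numpy(bool),
    )
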