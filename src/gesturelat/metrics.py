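"""Per-participant gesture measures: movement rates and magnitude-ratio laterality.

Two families of measures are computed from the epoch-level magnitudes:

* **Movement counts** — maximal suprathreshold runs of the filtered magnitude
  signal, merged across brief dips, expressed per minute of task time. The
  count depends on an explicit detection threshold, so every threshold used is
  recorded in the metric's configuration fingerprint.

* **Median magnitude ratio (MMR)** — for every second in which at least one
  arm is active, the log ratio ln(m_nonpreferred / m_preferred) of the two
  arms' mean movement magnitudes; seconds where only one arm moved receive a
  capped ratio (+cap if only the nonpreferred arm was active, -cap if only the
  preferred arm). The MMR is the median of these per-second ratios: 0 means
  both arms contribute equally, negative values mean the intact/dominant arm
  dominates. Being a ratio of magnitudes it needs no movement-segmentation
  threshold, only the activity threshold that defines an active second.

Two simpler laterality indices are provided as companions: a use ratio
(active-second counts) and a magnitude laterality index in [-1, 1].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import BimanualSession
from .preprocess import (
    DEFAULT_ACTIVITY_THRESHOLD_G,
    DEFAULT_CUTOFF_HZ,
    DEFAULT_EPOCH_LEN_S,
    EpochSeries,
    FilteredSignal,
    epoch_magnitudes,
    remove_gravity,
)

DEFAULT_RATIO_CAP = 7.0  # capped log-ratio for unilateral seconds
DEFAULT_MOVE_THRESHOLD_G = 0.05
DEFAULT_MIN_DUR_S = 0.25
DEFAULT_MERGE_GAP_S = 0.25
DEFAULT_MIN_ACTIVE_EPOCHS = 10


class InsufficientDataError(ValueError):
    """Raised when a metric's minimum-data precondition is not met."""


@dataclass(frozen=True)
class MovementEvent:
    """One detected movement bout of a single arm."""

    arm_role: str
    start_s: float
    end_s: float
    peak_mag_g: float
    mean_mag_g: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class MetricConfig:
    """All thresholds the gesture metrics depend on."""

    epoch_len_s: float = DEFAULT_EPOCH_LEN_S
    activity_threshold_g: float = DEFAULT_ACTIVITY_THRESHOLD_G
    gravity_method: str = "highpass"
    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    move_threshold_g: float = DEFAULT_MOVE_THRESHOLD_G
    min_dur_s: float = DEFAULT_MIN_DUR_S
    merge_gap_s: float = DEFAULT_MERGE_GAP_S
    ratio_cap: float = DEFAULT_RATIO_CAP
    min_active_epochs: int = DEFAULT_MIN_ACTIVE_EPOCHS

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class GestureMetrics:
    """Per-participant gesture measures; NaN fields carry a reason in ``missing``."""

    participant_id: str
    moves_per_min_preferred: float
    moves_per_min_nonpreferred: float
    mmr: float
    n_active_epochs: int
    n_unilateral_epochs: int
    alt_use_ratio: float
    alt_laterality_index: float
    config_fingerprint: str
    missing: dict[str, str] = field(default_factory=dict)


def detect_movements(
    sig: FilteredSignal,
    threshold_g: float = DEFAULT_MOVE_THRESHOLD_G,
    min_dur_s: float = DEFAULT_MIN_DUR_S,
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
    windows=None,
) -> list[MovementEvent]:
    """Segment the magnitude signal into movement bouts.

    A bout is a maximal run of samples with magnitude >= ``threshold_g``,
    after merging subthreshold gaps shorter than ``merge_gap_s``, kept only if
    it lasts at least ``min_dur_s``. If ``windows`` is given, detection runs
    independently inside each task window.
    """
    if threshold_g <= 0:
        raise ValueError("threshold_g must be positive")
    if windows is not None:
        events: list[MovementEvent] = []
        t = sig.times()
        for w in sorted(windows, key=lambda w: w.start_s):
            mask = (t >= w.start_s) & (t < w.end_s)
            if not mask.any():
                continue
            idx = np.flatnonzero(mask)
            sub = FilteredSignal(
                sig.participant_id, sig.arm_role, sig.fs, t[idx[0]], sig.mag[idx]
            )
            events.extend(detect_movements(sub, threshold_g, min_dur_s, merge_gap_s))
        return events

    above = sig.mag >= threshold_g
    if not above.any():
        return []
    runs = _runs(above)
    merged = [runs[0]]
    max_gap = int(np.ceil(merge_gap_s * sig.fs)) - 1  # gaps strictly shorter merge
    for s, e in runs[1:]:
        if s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_len = max(1, int(np.ceil(min_dur_s * sig.fs)))
    events = []
    for s, e in merged:
        if e - s < min_len:
            continue
        seg = sig.mag[s:e]
        events.append(
            MovementEvent(
                arm_role=sig.arm_role,
                start_s=sig.t0 + s / sig.fs,
                end_s=sig.t0 + e / sig.fs,
                peak_mag_g=float(seg.max()),
                mean_mag_g=float(seg.mean()),
            )
        )
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def movements_per_minute(events, total_task_s: float) -> float:
    """Movement rate, 60 x count / total task seconds."""
    if total_task_s <= 0:
        raise ValueError("total_task_s must be positive")
    return 60.0 * len(events) / total_task_s


def magnitude_ratio_series(epochs: EpochSeries, cap: float = DEFAULT_RATIO_CAP) -> np.ndarray:
    """Per-epoch log magnitude ratios ln(m_nonpreferred / m_preferred).

    Epochs where both arms are inactive are excluded. Unilateral epochs get
    +cap (only the nonpreferred arm active) or -cap (only the preferred arm);
    bilateral ratios are clipped to [-cap, +cap].
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    a1, a2 = epochs.active_arm1, epochs.active_arm2
    m1, m2 = epochs.mag_arm1, epochs.mag_arm2
    out = []
    for k in range(len(epochs)):
        if a1[k] and a2[k]:
            # log m2 - log m1 (not log of the quotient) so that swapping the
            # arms negates every ratio exactly in floating point
            out.append(float(np.clip(np.log(m2[k]) - np.log(m1[k]), -cap, cap)))
        elif a2[k]:
            out.append(cap)
        elif a1[k]:
            out.append(-cap)
    return np.asarray(out)


def median_magnitude_ratio(
    ratios, min_count: int = DEFAULT_MIN_ACTIVE_EPOCHS
) -> float:
    """Sample median of the per-epoch log ratios (the MMR).

    Raises :class:`InsufficientDataError` below ``min_count`` ratios, so a
    sparse recording yields a flagged missing metric rather than a silent 0.
    """
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) < min_count:
        raise InsufficientDataError(
            f"only {len(ratios)} active epochs; at least {min_count} required for MMR"
        )
    return float(np.median(ratios))


def alternative_laterality(epochs: EpochSeries, metric: str = "use_ratio") -> float:
    """Companion laterality indices over the same epoch series.

    ``use_ratio``: active nonpreferred seconds / active preferred seconds.
    ``laterality_index``: (M_np - M_p) / (M_np + M_p) over each arm's summed
    active-second magnitudes, in [-1, 1]. Both are simple stand-ins for
    activity-count laterality measures; neither needs a movement threshold.
    """
    n1 = int(epochs.active_arm1.sum())
    n2 = int(epochs.active_arm2.sum())
    if metric == "use_ratio":
        if n1 == 0:
            raise InsufficientDataError("no active preferred-arm epochs: use ratio undefined")
        return n2 / n1
    if metric == "laterality_index":
        m_p = float(epochs.mag_arm1[epochs.active_arm1].sum())
        m_np = float(epochs.mag_arm2[epochs.active_arm2].sum())
        if m_p + m_np == 0:
            raise InsufficientDataError("no active epochs: laterality index undefined")
        return (m_np - m_p) / (m_np + m_p)
    raise ValueError(f"unknown laterality metric {metric!r}")


def compute_gesture_metrics(
    session: BimanualSession, config: MetricConfig = MetricConfig()
) -> GestureMetrics:
    """Run the full per-participant measurement: rates, MMR, companion indices.

    Metrics whose preconditions fail are set to NaN with the reason recorded in
    ``missing`` — a participant is never silently dropped.
    """
    if not session.windows:
        raise ValueError("session has no task windows")
    missing: dict[str, str] = {}
    total_s = session.total_task_s

    sig_p = remove_gravity(session.preferred, config.gravity_method, config.cutoff_hz)
    sig_np = remove_gravity(session.nonpreferred, config.gravity_method, config.cutoff_hz)
    ev_p = detect_movements(
        sig_p, config.move_threshold_g, config.min_dur_s, config.merge_gap_s,
        windows=session.windows,
    )
    ev_np = detect_movements(
        sig_np, config.move_threshold_g, config.min_dur_s, config.merge_gap_s,
        windows=session.windows,
    )
    rate_p = movements_per_minute(ev_p, total_s)
    rate_np = movements_per_minute(ev_np, total_s)

    epochs = epoch_magnitudes(
        session,
        epoch_len_s=config.epoch_len_s,
        activity_threshold_g=config.activity_threshold_g,
        method=config.gravity_method,
        cutoff_hz=config.cutoff_hz,
    )
    ratios = magnitude_ratio_series(epochs, cap=config.ratio_cap)
    n_active = len(ratios)
    n_unilateral = int(np.sum(np.abs(ratios) == config.ratio_cap))
    try:
        mmr = median_magnitude_ratio(ratios, min_count=config.min_active_epochs)
    except InsufficientDataError as err:
        mmr = float("nan")
        missing["mmr"] = str(err)
    try:
        use_ratio = alternative_laterality(epochs, "use_ratio")
    except InsufficientDataError as err:
        use_ratio = float("nan")
        missing["alt_use_ratio"] = str(err)
    try:
        lat_index = alternative_laterality(epochs, "laterality_index")
    except InsufficientDataError as err:
        lat_index = float("nan")
        missing["alt_laterality_index"] = str(err)

    return GestureMetrics(
        participant_id=session.participant_id,
        moves_per_min_preferred=rate_p,
        moves_per_min_nonpreferred=rate_np,
        mmr=mmr,
        n_active_epochs=n_active,
        n_unilateral_epochs=n_unilateral,
        alt_use_ratio=use_ratio,
        alt_laterality_index=lat_index,
        config_fingerprint=config.fingerprint(),
        missing=missing,
    )
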