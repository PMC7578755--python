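"""Scoring of daily prosthesis use and perceived prosthesis embodiment.

Daily prosthesis use has two components: weekly wear time (hours, 0-168) and
a functional-use score from the PAL (Prosthesis Activity/ability) item set,
normalised to [0, 1] (0 = minimum function, 1 = maximum function). Because
hours and a unit-interval score are incommensurate, the composite daily-use
score is the mean of the two components' within-cohort z-scores (a
rank-average composite is available as an alternative; Spearman-based
analyses downstream are invariant to the choice when both components enter
monotonically).

Perceived embodiment is the mean of five agreement ratings, each on a
-3 (strongly disagree) .. +3 (strongly agree) scale with 0 neutral.
Participants are split into a positive group (score > 0) and a
neutral/negative group (score <= 0). A control item ("it seems like I have
three hands") flags possible non-engagement when it is not clearly rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

N_EMBODIMENT_ITEMS = 5
EMBODIMENT_MIN, EMBODIMENT_MAX = -3.0, 3.0
DEFAULT_CONTROL_CUTOFF = -1.0
MAX_PAL_MISSING_FRAC = 0.2


class ScoringError(ValueError):
    """Raised when questionnaire responses violate their contract."""


@dataclass
class QuestionnaireScores:
    participant_id: str
    wear_hours_week: float
    pal_score: float
    daily_use_score: float
    embodiment_score: float
    embodiment_group: str
    control_engaged: bool


def score_pal(pal_items, item_scale_max: float) -> float:
    """Mean PAL item response normalised to [0, 1]; NaN items are excluded.

    More than 20% missing items raises :class:`ScoringError` (flagged missing
    score rather than an optimistic mean).
    """
    items = np.asarray(pal_items, dtype=float)
    if items.size == 0:
        raise ScoringError("PAL item list is empty")
    if item_scale_max <= 0:
        raise ScoringError("item_scale_max must be positive")
    missing = np.isnan(items)
    if missing.mean() > MAX_PAL_MISSING_FRAC:
        raise ScoringError(
            f"{int(missing.sum())}/{items.size} PAL items missing "
            f"(> {MAX_PAL_MISSING_FRAC:.0%}); score flagged missing"
        )
    present = items[~missing]
    if ((present < 0) | (present > item_scale_max)).any():
        raise ScoringError(f"PAL responses must lie in [0, {item_scale_max}]")
    return float(present.mean() / item_scale_max)


def score_embodiment(embodiment_items) -> float:
    """Arithmetic mean of exactly five -3..+3 agreement ratings."""
    items = np.asarray(embodiment_items, dtype=float)
    if items.size != N_EMBODIMENT_ITEMS:
        raise ScoringError(
            f"expected {N_EMBODIMENT_ITEMS} embodiment items, got {items.size}"
        )
    if np.isnan(items).any():
        raise ScoringError("embodiment items contain missing responses")
    if ((items < EMBODIMENT_MIN) | (items > EMBODIMENT_MAX)).any():
        raise ScoringError("embodiment responses must lie in [-3, +3]")
    return float(items.mean())


def embodiment_group(embodiment_score: float) -> str:
    """``positive`` iff score > 0; 0 itself falls in ``neutral_negative``."""
    if not np.isfinite(embodiment_score):
        raise ScoringError("embodiment score must be finite")
    return "positive" if embodiment_score > 0 else "neutral_negative"


def check_control_item(control_item: float, cutoff: float = DEFAULT_CONTROL_CUTOFF) -> bool:
    """True (engaged) when the three-hands control item is rejected (<= cutoff)."""
    if control_item < EMBODIMENT_MIN or control_item > EMBODIMENT_MAX:
        raise ScoringError("control item response must lie in [-3, +3]")
    return control_item <= cutoff


def daily_use_scores(
    wear_hours_week, pal_scores, method: str = "zscore"
) -> np.ndarray:
    """Composite daily-use score for a complete cohort.

    ``zscore`` (default): mean of the two components' within-cohort z-scores
    (sample SD, ddof=1), so the composite has cohort mean 0. ``rank``:
    mean of the two components' mid-ranks, centred. A zero-variance component
    is dropped with a warning rather than producing NaNs.
    """
    import warnings

    wear = np.asarray(wear_hours_week, dtype=float)
    pal = np.asarray(pal_scores, dtype=float)
    if wear.shape != pal.shape:
        raise ScoringError("wear and PAL arrays must align")
    if np.isnan(wear).any() or np.isnan(pal).any():
        raise ScoringError("daily-use composite requires both components for every row")
    if ((wear < 0) | (wear > 168)).any():
        raise ScoringError("weekly wear hours must lie in [0, 168]")
    comps = []
    for name, comp in (("wear_hours_week", wear), ("pal_score", pal)):
        if method == "zscore":
            sd = comp.std(ddof=1) if comp.size > 1 else 0.0
            if sd == 0:
                warnings.warn(f"daily-use component {name!r} has zero variance; dropped")
                continue
            comps.append((comp - comp.mean()) / sd)
        elif method == "rank":
            r = rankdata(comp)
            comps.append(r - r.mean())
        else:
            raise ScoringError(f"unknown composite method {method!r}")
    if not comps:
        raise ScoringError("both daily-use components degenerate; composite undefined")
    return np.mean(comps, axis=0)


def daily_use_score(wear_hours_week: float, pal_score: float, cohort_context) -> float:
    """One participant's composite given the cohort's (wear, pal) distributions.

    ``cohort_context`` is a pair of arrays (cohort wear hours, cohort PAL
    scores) that must include this participant.
    """
    if not (np.isfinite(wear_hours_week) and np.isfinite(pal_score)):
        raise ScoringError("missing component: daily-use composite flagged missing")
    wear_all, pal_all = (np.asarray(v, dtype=float) for v in cohort_context)
    composite = daily_use_scores(wear_all, pal_all)
    match = np.flatnonzero(
        np.isclose(wear_all, wear_hours_week) & np.isclose(pal_all, pal_score)
    )
    if match.size == 0:
        raise ScoringError("participant's components not found in cohort context")
    return float(composite[match[0]])


def score_questionnaire_table(df, item_scale_max: float = 4.0):
    """Score a questionnaire table into a per-participant DataFrame.

    Expects columns ``participant_id``, ``wear_hours_week``, PAL items
    ``pal_*``, embodiment items ``emb_01..emb_05`` and ``control_item``.
    Rows whose PAL score is flagged missing get NaN pal/daily-use scores.
    """
    import pandas as pd

    pal_cols = sorted(c for c in df.columns if c.startswith("pal_"))
    emb_cols = sorted(c for c in df.columns if c.startswith("emb_"))
    if len(emb_cols) != N_EMBODIMENT_ITEMS:
        raise ScoringError(
            f"expected columns emb_01..emb_05, found {emb_cols or 'none'}"
        )
    if not pal_cols:
        raise ScoringError("no pal_* item columns found")
    rows = []
    for _, row in df.iterrows():
        try:
            pal = score_pal(row[pal_cols].to_numpy(float), item_scale_max)
        except ScoringError:
            pal = float("nan")
        emb = score_embodiment(row[emb_cols].to_numpy(float))
        rows.append(
            {
                "participant_id": row["participant_id"],
                "wear_hours_week": float(row["wear_hours_week"]),
                "pal_score": pal,
                "embodiment_score": emb,
                "embodiment_group": embodiment_group(emb),
                "control_engaged": check_control_item(float(row["control_item"])),
            }
        )
    out = pd.DataFrame(rows)
    complete = out["pal_score"].notna() & out["wear_hours_week"].notna()
    out["daily_use_score"] = float("nan")
    if complete.sum() >= 2:
        out.loc[complete, "daily_use_score"] = daily_use_scores(
            out.loc[complete, "wear_hours_week"].to_numpy(),
            out.loc[complete, "pal_score"].to_numpy(),
        )
    return out
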