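"""End-to-end orchestration: sessions -> metrics -> cohort table -> stats report.

A run is driven by one YAML config (unknown keys rejected) naming a session
manifest and a questionnaire CSV. Outputs are a per-participant epoch CSV,
a metrics CSV, the assembled cohort table, a statistics report (text +
machine-readable JSON), and a provenance record (config hash, package
version, per-participant exclusions). Reruns with an identical config are
byte-identical.

``reproduce_osf`` recomputes the battery from a locally downloaded copy of
the original study's public deposit (osf.io/spt2a) and prints the recomputed
statistics next to the study's reported values; it never downloads anything
itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import CsvDialect, TaskWindow, build_session, read_recording, write_epochs
from .metrics import MetricConfig, compute_gesture_metrics
from .preprocess import epoch_magnitudes
from .questionnaires import score_questionnaire_table
from .stats import (
    StatResult,
    ancova,
    benjamini_hochberg,
    mann_whitney_u,
    mixed_anova_2x2,
    one_sample_t,
    outlier_policy,
    paired_t,
    spearman,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending participant."""


@dataclass(frozen=True)
class StatsOptions:
    exact_u: bool | None = None
    bf_r_scale: float = 0.707
    outlier_rule: str = "mad"
    outlier_k: float = 3.0
    named_exclusions: tuple = ()
    bh_column: bool = False


@dataclass(frozen=True)
class RunConfig:
    manifest: str
    questionnaires: str
    out_dir: str
    seed: int = 0
    pal_scale_max: float = 4.0
    metrics: MetricConfig = field(default_factory=MetricConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        for key, typ in (("metrics", MetricConfig), ("stats", StatsOptions)):
            sub = raw.get(key, {})
            if isinstance(sub, dict):
                sub_known = {f.name for f in dataclasses.fields(typ)}
                sub_unknown = set(sub) - sub_known
                if sub_unknown:
                    raise PipelineError(f"unknown {key} config keys: {sorted(sub_unknown)}")
                if key == "stats" and "named_exclusions" in sub:
                    sub["named_exclusions"] = tuple(sub["named_exclusions"])
                raw[key] = typ(**sub)
        return cls(**raw)

    def fingerprint(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def load_manifest(path) -> list[dict]:
    """Read the session manifest (YAML list of participants with files/roles)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sessions = raw.get("sessions") if isinstance(raw, dict) else raw
    if not isinstance(sessions, list) or not sessions:
        raise PipelineError(f"{path}: manifest must contain a non-empty 'sessions' list")
    return sessions


def _session_from_manifest(entry: dict, base_dir: Path):
    recs = []
    for spec in entry["recordings"]:
        p = base_dir / spec["path"]
        if not p.exists():
            raise PipelineError(
                f"stage 'read' failed for participant {entry['participant_id']}: "
                f"missing file {p}"
            )
        dialect = CsvDialect(units=spec.get("units", "g"))
        recs.append(
            read_recording(
                p, dialect,
                participant_id=entry["participant_id"],
                arm_side=spec["side"], arm_role=spec["role"],
            )
        )
    if len(recs) != 2:
        raise PipelineError(
            f"participant {entry['participant_id']}: expected 2 recordings, got {len(recs)}"
        )
    windows = [TaskWindow(w["label"], float(w["start_s"]), float(w["end_s"]))
               for w in entry["windows"]]
    return build_session(recs[0], recs[1], windows)


def assemble_cohort(metrics_df: pd.DataFrame, scores_df: pd.DataFrame,
                    meta_df: pd.DataFrame) -> pd.DataFrame:
    """Join metadata, gesture metrics and questionnaire scores per participant."""
    out = meta_df.merge(metrics_df, on="participant_id", how="left").merge(
        scores_df, on="participant_id", how="left"
    )
    out["excluded"] = False
    out["exclusion_reason"] = ""
    return out


def run_stat_battery(cohort: pd.DataFrame, options: StatsOptions = StatsOptions()):
    """The full cohort-level battery over an assembled cohort table.

    Returns ``(results, exclusions)``: a list of :class:`StatResult` and a
    DataFrame of outlier/named exclusion flags (applied to parametric
    analyses only; rank-based tests keep everyone).
    """
    res: list[StatResult] = []
    oh = cohort[cohort["group"] == "one_hander"]
    th = cohort[cohort["group"] == "two_hander"]

    # outlier flags on the laterality measure, parametric analyses only
    flags = pd.DataFrame({"participant_id": oh["participant_id"].to_numpy()})
    mmr_oh = oh["mmr"].to_numpy(float)
    valid = np.isfinite(mmr_oh)
    mad_flag = np.zeros(len(oh), dtype=bool)
    if valid.sum() >= 5:
        mad_flag[valid] = outlier_policy(mmr_oh[valid], options.outlier_rule, options.outlier_k)
    named = oh["participant_id"].isin(options.named_exclusions).to_numpy()
    flags["mad_outlier"] = mad_flag
    flags["named_exclusion"] = named
    flags["excluded_parametric"] = mad_flag | named
    for _, row in flags[flags["excluded_parametric"]].iterrows():
        why = "named in config" if row["named_exclusion"] else "median/MAD rule"
        log.warning("participant %s excluded from parametric analyses (%s)",
                    row["participant_id"], why)
    keep_param = ~flags["excluded_parametric"].to_numpy()

    def _try(fn, *args, **kw):
        try:
            res.append(fn(*args, **kw))
        except Exception as err:  # degenerate subset: record, keep going
            log.warning("%s skipped: %s", getattr(fn, "__name__", fn), err)

    if len(th) and valid.any():
        r = mann_whitney_u(mmr_oh[valid], th["mmr"].to_numpy(float), options.exact_u)
        r.name = "mmr_group_u"
        res.append(r)

    mp = "moves_per_min_preferred"
    mn = "moves_per_min_nonpreferred"
    if len(th) >= 2 and len(oh) >= 2:
        anova = mixed_anova_2x2(
            np.concatenate([oh[mp], th[mp]]),
            np.concatenate([oh[mn], th[mn]]),
            np.array(["one_hander"] * len(oh) + ["two_hander"] * len(th)),
        )
        for key, r in anova.items():
            r.name = f"moves_anova_{key}"
            res.append(r)
        _try(lambda: _renamed(paired_t(oh[mp], oh[mn]), "moves_paired_t_onehanders"))
        _try(lambda: _renamed(
            paired_t(th[mp], th[mn], bayes=True, r_scale=options.bf_r_scale),
            "moves_paired_t_twohanders",
        ))

    emb = oh["embodiment_score"].to_numpy(float)
    if np.isfinite(emb).sum() >= 2:
        _try(lambda: _renamed(
            one_sample_t(emb[np.isfinite(emb)], 0.0, bayes=True,
                         r_scale=options.bf_r_scale),
            "embodiment_vs_zero_t",
        ))

    use = oh["daily_use_score"].to_numpy(float)
    both = np.isfinite(mmr_oh) & np.isfinite(use)
    if both.sum() >= 4:
        _try(lambda: _renamed(spearman(mmr_oh[both], use[both]), "mmr_daily_use_spearman"))
    both_e = np.isfinite(mmr_oh) & np.isfinite(emb)
    if both_e.sum() >= 4:
        _try(lambda: _renamed(spearman(mmr_oh[both_e], emb[both_e]), "mmr_embodiment_spearman"))
        grp = oh["embodiment_group"].to_numpy()
        pos = both_e & (grp == "positive")
        neg = both_e & (grp == "neutral_negative")
        if pos.any() and neg.any():
            r = mann_whitney_u(mmr_oh[pos], mmr_oh[neg], options.exact_u)
            r.name = "mmr_embodiment_group_u"
            res.append(r)

    # sub-group contrasts (cause of limb loss; passive vs active prosthesis)
    lat_moves = oh[mp].to_numpy(float) - oh[mn].to_numpy(float)
    for col, split, label in (
        ("cause", lambda v: v == "congenital", "cause"),
        ("prosthesis_type", lambda v: v == "cosmetic", "passive_active"),
    ):
        vals = oh[col].to_numpy()
        isstr = np.array([isinstance(v, str) for v in vals])
        a_mask = np.array([isinstance(v, str) and bool(split(v)) for v in vals])
        b_mask = isstr & ~a_mask
        if (a_mask & valid).any() and (b_mask & valid).any():
            r = mann_whitney_u(mmr_oh[a_mask & valid], mmr_oh[b_mask & valid], options.exact_u)
            r.name = f"mmr_{label}_u"
            res.append(r)
            r2 = mann_whitney_u(lat_moves[a_mask], lat_moves[b_mask], options.exact_u)
            r2.name = f"moves_laterality_{label}_u"
            res.append(r2)

    # ANCOVA on the laterality measure, parametric exclusions applied
    sub = oh.loc[keep_param].copy()
    sub["prosthesis_class"] = sub["prosthesis_type"].map(
        lambda v: "passive" if v == "cosmetic" else ("active" if isinstance(v, str) else None)
    )
    sub = sub.dropna(subset=["mmr", "daily_use_score", "cause", "prosthesis_class"])
    if len(sub) >= 8 and sub["cause"].nunique() == 2 and sub["prosthesis_class"].nunique() == 2:
        try:
            for term, r in ancova(
                sub, "mmr", ["cause", "prosthesis_class"], "daily_use_score"
            ).items():
                res.append(r)
        except Exception as err:
            log.warning("ancova skipped: %s", err)

    if options.bh_column:
        adj = benjamini_hochberg([r.p for r in res])
        for r, a in zip(res, adj):
            r.options["p_bh_adjusted"] = float(a)
    return res, flags


def _renamed(r: StatResult, name: str) -> StatResult:
    r.name = name
    return r


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        df1, df2 = (r.df if isinstance(r.df, tuple) else (r.df, None))
        rows.append(
            {
                "name": r.name, "statistic": r.statistic, "symbol": r.stat_symbol,
                "df1": df1, "df2": df2, "p": r.p,
                "bf10": r.bayes_factor_10, "n": str(r.n), "direction": r.direction,
                "options": json.dumps(r.options, default=str),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the output bundle.

    Returns a dict of output paths plus the in-memory cohort table and
    results. Any stage failure raises :class:`PipelineError` naming the stage
    and participant.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "epochs").mkdir(exist_ok=True)
    base = Path(config.manifest).parent

    sessions = load_manifest(config.manifest)
    metric_rows, meta_rows = [], []
    for entry in sessions:
        pid = entry.get("participant_id", "?")
        session = _session_from_manifest(entry, base)
        try:
            epochs = epoch_magnitudes(
                session,
                epoch_len_s=config.metrics.epoch_len_s,
                activity_threshold_g=config.metrics.activity_threshold_g,
                method=config.metrics.gravity_method,
                cutoff_hz=config.metrics.cutoff_hz,
            )
            write_epochs(epochs, out_dir / "epochs" / f"{pid}.csv")
            gm = compute_gesture_metrics(session, config.metrics)
        except Exception as err:
            raise PipelineError(f"stage 'metrics' failed for participant {pid}: {err}") from err
        metric_rows.append(
            {
                "participant_id": pid,
                "moves_per_min_preferred": gm.moves_per_min_preferred,
                "moves_per_min_nonpreferred": gm.moves_per_min_nonpreferred,
                "mmr": gm.mmr,
                "n_active_epochs": gm.n_active_epochs,
                "n_unilateral_epochs": gm.n_unilateral_epochs,
                "alt_use_ratio": gm.alt_use_ratio,
                "alt_laterality_index": gm.alt_laterality_index,
                "config_fingerprint": gm.config_fingerprint,
                "missing": ";".join(f"{k}: {v}" for k, v in gm.missing.items()),
            }
        )
        meta_rows.append(
            {
                "participant_id": pid,
                "group": entry.get("group", "one_hander"),
                "cause": entry.get("cause"),
                "prosthesis_type": entry.get("prosthesis_type"),
            }
        )
    metrics_df = pd.DataFrame(metric_rows)
    meta_df = pd.DataFrame(meta_rows)

    try:
        q_raw = pd.read_csv(config.questionnaires)
        scores_df = score_questionnaire_table(q_raw, config.pal_scale_max)
    except FileNotFoundError as err:
        raise PipelineError(f"stage 'score' failed: {err}") from err

    cohort = assemble_cohort(metrics_df, scores_df, meta_df)
    results, exclusions = run_stat_battery(cohort, config.stats)

    paths = {
        "metrics": out_dir / "metrics.csv",
        "cohort": out_dir / "cohort.csv",
        "stats_json": out_dir / "stats_report.json",
        "stats_txt": out_dir / "stats_report.txt",
        "exclusions": out_dir / "exclusions.csv",
        "provenance": out_dir / "provenance.json",
    }
    metrics_df.to_csv(paths["metrics"], index=False)
    cohort.to_csv(paths["cohort"], index=False)
    results_to_frame(results).to_json(paths["stats_json"], orient="records", indent=2)
    with open(paths["stats_txt"], "w") as fh:
        for r in results:
            fh.write(r.summary() + "\n")
    exclusions.to_csv(paths["exclusions"], index=False)
    with open(paths["provenance"], "w") as fh:
        json.dump(
            {
                "package_version": __version__,
                "config_fingerprint": config.fingerprint(),
                "config": dataclasses.asdict(config),
                "n_sessions": len(sessions),
                "excluded_parametric": flagslist(exclusions),
            },
            fh, indent=2, default=str,
        )
    return {"paths": paths, "cohort": cohort, "results": results, "exclusions": exclusions}


def flagslist(exclusions: pd.DataFrame) -> list[str]:
    return exclusions.loc[exclusions["excluded_parametric"], "participant_id"].tolist()


# -- reproduction from the public deposit ------------------------------------

#: statistics reported by the original study, for the side-by-side printout
REFERENCE_STATISTICS = {
    "mmr_group_u": {"U": 47.0, "p": "< 0.001"},
    "moves_anova_group": {"F": 0.045, "p": 0.83},
    "moves_anova_interaction": {"F": 4.25, "p": 0.046},
    "moves_paired_t_onehanders": {"t": 2.94, "p": 0.007},
    "moves_paired_t_twohanders": {"t": 0.088, "p": 0.93, "BF10": 0.263},
    "embodiment_vs_zero_t": {"t": 2.23, "p": 0.035},
    "mmr_daily_use_spearman": {"rho": 0.55, "p": 0.005},
    "mmr_embodiment_group_u": {"U": 35.0, "p": 0.03},
    "mmr_embodiment_spearman": {"rho": 0.37, "p": 0.07},
    "ancova_daily_use_score": {"F": 13.97, "p": 0.001},
}

REQUIRED_DEPOSIT_COLUMNS = [
    "participant_id", "group", "mmr",
    "moves_per_min_preferred", "moves_per_min_nonpreferred",
    "wear_hours_week", "pal_score", "embodiment_score",
]


def reproduce_osf(data_dir, options: StatsOptions = StatsOptions(named_exclusions=("aa11",))):
    """Recompute the battery from a manually downloaded copy of the deposit.

    ``data_dir`` must already contain a per-participant CSV with the columns
    in :data:`REQUIRED_DEPOSIT_COLUMNS` (map the deposit's own column names
    onto these and save the result as a CSV in ``data_dir``). Nothing is ever
    downloaded. Returns ``(results, report_text)`` where the report places
    each recomputed statistic next to the study's reported value.
    """
    data_dir = Path(data_dir)
    if not data_dir.exists():
        raise FileNotFoundError(
            f"{data_dir} does not exist. Download the deposit (osf.io/spt2a) "
            "manually, export a per-participant CSV with columns "
            f"{REQUIRED_DEPOSIT_COLUMNS}, and pass that directory."
        )
    candidates = sorted(data_dir.glob("*.csv"))
    table = None
    for p in candidates:
        df = pd.read_csv(p)
        if all(c in df.columns for c in REQUIRED_DEPOSIT_COLUMNS):
            table = df
            break
    if table is None:
        raise FileNotFoundError(
            f"no CSV in {data_dir} carries the required columns "
            f"{REQUIRED_DEPOSIT_COLUMNS}; found {[p.name for p in candidates]}. "
            "Map the deposit's per-participant values onto those columns first."
        )
    from .questionnaires import daily_use_scores, embodiment_group

    oh = table["group"] == "one_hander"
    if "daily_use_score" not in table.columns:
        table.loc[oh, "daily_use_score"] = daily_use_scores(
            table.loc[oh, "wear_hours_week"], table.loc[oh, "pal_score"]
        )
    if "embodiment_group" not in table.columns:
        table.loc[oh, "embodiment_group"] = [
            embodiment_group(v) for v in table.loc[oh, "embodiment_score"]
        ]
    if "cause" not in table.columns:
        table["cause"] = pd.NA
    if "prosthesis_type" not in table.columns:
        table["prosthesis_type"] = pd.NA
    results, _ = run_stat_battery(table, options)
    lines = ["recomputed vs reported:"]
    by_name = {r.name: r for r in results}
    for name, ref in REFERENCE_STATISTICS.items():
        reftxt = ", ".join(f"{k} = {v}" for k, v in ref.items())
        if name in by_name:
            lines.append(f"  {by_name[name].summary()}   | reported: {reftxt}")
        else:
            lines.append(f"  {name}: not computable from this table | reported: {reftxt}")
    return results, "\n".join(lines)
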