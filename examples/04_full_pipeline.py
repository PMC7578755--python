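"""End-to-end run: raw signal CSVs -> epochs -> metrics -> cohort -> stats.

Writes a four-participant synthetic dataset (raw recordings, session
manifest, questionnaire items) to a temporary directory, then executes the
whole pipeline from a single config and prints the bundle it produced.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gesturelat import (
    CsvDialect,
    RunConfig,
    SignalSimParams,
    run_pipeline,
    simulate_session,
    write_recording,
)

tmp = Path(tempfile.mkdtemp(prefix="gesturelat_demo_"))
sessions = []
for i, (pid, group, k) in enumerate(
    [("oh01", "one_hander", 0.4), ("oh02", "one_hander", 0.6),
     ("th01", "two_hander", 1.0), ("th02", "two_hander", 1.0)]
):
    session, _ = simulate_session(
        SignalSimParams(seed=60 + i, duration_s=120, participant_id=pid,
                        group=group, laterality_k=k)
    )
    recs = []
    for rec in (session.recording_a, session.recording_b):
        fname = f"{pid}_{rec.arm_role}.csv"
        write_recording(rec, tmp / fname, CsvDialect())
        recs.append({"path": fname, "side": rec.arm_side, "role": rec.arm_role})
    sessions.append(
        {"participant_id": pid, "group": group,
         "cause": "congenital" if pid == "oh01" else ("acquired" if pid == "oh02" else None),
         "prosthesis_type": "myoelectric" if group == "one_hander" else None,
         "recordings": recs,
         "windows": [{"label": "task", "start_s": 0.0, "end_s": 120.0}]}
    )
(tmp / "manifest.yaml").write_text(yaml.safe_dump({"sessions": sessions}))

pd.DataFrame(
    {
        "participant_id": ["oh01", "oh02"],
        "wear_hours_week": [90.0, 30.0],
        "pal_01": [4, 1], "pal_02": [3, 2],
        "emb_01": [2.0, -1.0], "emb_02": [1.0, 0.0], "emb_03": [2.0, -2.0],
        "emb_04": [1.0, 0.0], "emb_05": [2.0, -1.0],
        "control_item": [-3.0, -3.0],
    }
).to_csv(tmp / "questionnaires.csv", index=False)

config = RunConfig.from_dict(
    {"manifest": str(tmp / "manifest.yaml"),
     "questionnaires": str(tmp / "questionnaires.csv"),
     "out_dir": str(tmp / "out"), "seed": 1}
)
bundle = run_pipeline(config)

cohort = bundle["cohort"]
cols = ["participant_id", "group", "mmr", "moves_per_min_preferred",
        "moves_per_min_nonpreferred", "daily_use_score", "embodiment_score"]
print(cohort[cols].to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
print()
for r in bundle["results"]:
    print(r.summary())
print()
print("outputs:", *(f"  {k}: {p}" for k, p in bundle["paths"].items()), sep="\n")
print()
print("One-handers were simulated with amplitude ratios k < 1, so their MMR is")
print("negative (intact arm dominates); the two controls sit near zero. With only")
print("four participants most cohort tests are skipped with a logged reason.")
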