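"""Score prosthesis daily-use and embodiment questionnaires for a tiny cohort.

Each row holds weekly wear hours, functional-use (PAL) items on a 0-4 scale,
five embodiment agreement items on -3..+3, and the three-hands control item.
"""

import pandas as pd

from gesturelat import score_questionnaire_table

responses = pd.DataFrame(
    {
        "participant_id": ["p01", "p02", "p03"],
        "wear_hours_week": [100.0, 40.0, 10.0],
        "pal_01": [4, 2, 1], "pal_02": [3, 2, 0], "pal_03": [4, 1, 1],
        "emb_01": [2, 0, -2], "emb_02": [3, 1, -3], "emb_03": [1, 0, -2],
        "emb_04": [2, -1, -3], "emb_05": [2, 0, -2],
        "control_item": [-3, -3, 2],
    }
)
scores = score_questionnaire_table(responses, item_scale_max=4.0)
print(scores.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
print()
print("pal_score is the mean item response normalised to [0, 1]; the daily-use")
print("score averages within-cohort z-scores of wear time and PAL (cohort mean 0).")
print("embodiment_group is 'positive' only for scores strictly above 0, and a")
print("control response above -1 flags possible non-engagement (p03).")
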