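"""The cognitively weighted dual-task cost and its motivating limit case.

A participant who stops counting keeps their motor output near baseline:
the standard cost DTC = 100*(f_DT - f_ST)/f_ST reads ~0% and misses the
impairment.  Weighting the dual-task feature by the rescaled correct-
response count Zc in [0.01, 1] exposes it: DTC* = 100*(Zc*f_DT - f_ST)/f_ST.
"""

import pandas as pd

from mcdt import weighted_dtc_table, zc_scores

# three participants, identical motor output at baseline and under load
rows = []
for pid in ("engaged", "average", "disengaged"):
    rows.append(dict(participant_id=pid, exercise="FTAP", cl="CL0", feature="tap", value=30.0))
    rows.append(dict(participant_id=pid, exercise="FTAP", cl="CL1", feature="tap", value=30.0))
features = pd.DataFrame(rows)
# ... but very different counting performance
nc = pd.DataFrame(
    dict(participant_id=["engaged", "average", "disengaged"],
         exercise="FTAP", cl="CL1", nc=[12, 6, 0])
)

print("correct answers -> weights:", dict(zip(nc.participant_id, zc_scores(nc.nc.to_numpy()).round(3))))
table = weighted_dtc_table(features, nc)
print(table.to_string(index=False))
# All three have a standard cost of 0% (motor output unchanged).  The
# weighted cost stays 0% for the fully engaged participant, but drops to
# -99% for the one who never counted: the dual task was not actually done.
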