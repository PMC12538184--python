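"""Demographic comparability statistics for a cohort table.

Chi-square for sex and education by group, Kruskal-Wallis for age and
FAB, and the Bonferroni-corrected critical p for the three pairwise
post hoc contrasts.
"""

import json

from mcdt import CohortConfig, describe_cohort, generate_cohort
from mcdt.cohort import participants_frame

cohort = participants_frame(generate_cohort(CohortConfig(seed=1)))
summary = describe_cohort(cohort)
print(json.dumps(summary, indent=2))
# n per group is fixed by design (10/17/17); ages centre near 63/72/73
# with FAB ordered OA > SCI > MCI.  The chi-square and Kruskal-Wallis
# statistics test whether sex/education and age distributions differ
# across the three diagnostic groups.
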