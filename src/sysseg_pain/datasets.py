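"""Reference group-level summary statistics for recomputation examples.

Printed summaries (mean, SD, n per group) of a middle-aged community cohort —
214 pain-free and 133 chronic-pain participants — are enough to recompute the
two-group pooled-variance ANOVA F and the sex chi-square, which is what the
summary-statistic utilities in :mod:`sysseg_pain.stats` exist for. These
numbers are inputs to worked examples, not outputs of this package.
"""

from .stats import GroupSummary

#: Group sizes.
N_NO_PAIN, N_PAIN = 214, 133

#: Per-variable (no_pain, pain) summaries.
GROUP_SUMMARIES = {
    "age": (GroupSummary(52.87, 7.02, N_NO_PAIN), GroupSummary(54.81, 7.04, N_PAIN)),
    "bmi": (GroupSummary(25.36, 3.72, N_NO_PAIN), GroupSummary(26.86, 5.40, N_PAIN)),
    "mental_health": (GroupSummary(1.21, 1.59, N_NO_PAIN), GroupSummary(2.18, 2.02, N_PAIN)),
    "cognitive_complaints": (
        GroupSummary(53.26, 6.54, N_NO_PAIN),
        GroupSummary(48.41, 9.28, N_PAIN),
    ),
}

#: Proportion of women per group (for the 2x2 chi-square contrast).
PROP_WOMEN = {"no_pain": 0.472, "pain": 0.632}

#: Group mean framewise displacement (mm) during the scan.
FD_MEAN_MM = {"no_pain": 0.163, "pain": 0.179}

#: Published two-group statistics recomputable from the summaries above.
PRINTED_F = {"age": 6.271, "bmi": 9.362, "mental_health": 24.772,
             "cognitive_complaints": 31.945}
PRINTED_CHI2_SEX = 8.396
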