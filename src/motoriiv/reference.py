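"""Published cohort summary statistics used as simulation targets and inputs.

These are the printed group-level descriptives from a study of motor
inconsistency in 66 stroke survivors versus 32 healthy older adults
performing 30 rapid goal-directed ankle dorsiflexion contractions toward a
10 N / 180 ms force-time target. They serve two purposes:

* the synthetic cohort generator draws covariates at these group means/SDs,
  so simulated metadata tables have realistic marginals;
* the summary-based test functions in :mod:`motoriiv.stats` can recompute the
  comparison statistics (t, Cohen's d) directly from them, without raw data.

Units: IIV is a T-score SD; episodic memory is words recalled (HVLT);
visuospatial processing is items completed (DSST); processing speed and
executive function are seconds (TMT-A / TMT-B, larger = worse); DRS-2 is an
age/education-adjusted global cognition score; ankle strength is the
paretic/non-paretic (non-dominant/dominant) force ratio; mRS is the 0-5
disability scale (stroke only).
"""

from __future__ import annotations

from .stats import SummaryStats

STROKE_N = 66
HEALTHY_N = 32
N_TRIALS = 30
TARGET_FORCE_N = 10.0
TARGET_TIME_MS = 180.0

#: (stroke, healthy) printed summaries per variable.
GROUP_SUMMARIES: dict[str, tuple[SummaryStats, SummaryStats]] = {
    "iiv": (SummaryStats("stroke", 66, 6.61, 5.39),
            SummaryStats("healthy", 32, 3.74, 1.78)),
    "episodic_memory": (SummaryStats("stroke", 66, 5.67, 1.94),
                        SummaryStats("healthy", 32, 9.59, 1.85)),
    "visuospatial": (SummaryStats("stroke", 66, 47.82, 18.11),
                     SummaryStats("healthy", 32, 61.75, 12.97)),
    "processing_speed": (SummaryStats("stroke", 66, 51.80, 52.24),
                         SummaryStats("healthy", 32, 31.79, 9.87)),
    "executive_function": (SummaryStats("stroke", 66, 118.56, 77.52),
                           SummaryStats("healthy", 32, 79.14, 40.58)),
    "education_years": (SummaryStats("stroke", 66, 15.88, 2.59),
                        SummaryStats("healthy", 32, 16.81, 2.60)),
    "drs2": (SummaryStats("stroke", 66, 8.29, 3.11),
             SummaryStats("healthy", 32, 10.91, 1.69)),
    "strength_ratio": (SummaryStats("stroke", 66, 0.94, 0.22),
                       SummaryStats("healthy", 32, 1.00, 0.16)),
    "age": (SummaryStats("stroke", 66, 67.15, 12.32),
            SummaryStats("healthy", 32, 70.67, 12.67)),
}

#: mRS summary for the stroke group (healthy participants have no mRS).
MRS_STROKE = SummaryStats("stroke", 66, 1.42, 0.93)

#: Women / men counts per group.
SEX_COUNTS: dict[str, dict[str, int]] = {
    "stroke": {"F": 28, "M": 38},
    "healthy": {"F": 20, "M": 12},
}
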