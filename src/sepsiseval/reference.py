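"""Published cohort sizes used for prevalence arithmetic and harmonization targets.

These are the patient-flow counts of the two reference ICU cohorts the evaluation
framework was designed around: a German multi-site ICU cohort ("BerlinICU") and the
public MIMIC-IV training cohort.  They serve two purposes: sanity arithmetic (the
sepsis prevalence implied by the counts) and as default targets for prevalence
harmonization when comparing prevalence-sensitive metrics across strategies.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CohortCounts:
    """Stay-level counts of an ICU cohort after eligibility filtering."""

    name: str
    total_stays: int
    sepsis_stays: int

    @property
    def control_stays(self) -> int:
        return self.total_stays - self.sepsis_stays

    @property
    def prevalence(self) -> float:
        """Sepsis prevalence as a fraction of stays."""
        return self.sepsis_stays / self.total_stays


#: German multi-site adult ICU cohort, 2012-2021, after filtering.
BERLIN_ICU = CohortCounts("BerlinICU", total_stays=40_132, sepsis_stays=4_134)

#: MIMIC-IV v2.0 training cohort.
MIMIC_IV = CohortCounts("MIMIC-IV", total_stays=67_056, sepsis_stays=3_730)


def prevalence_percent(counts: CohortCounts, digits: int = 1) -> float:
    """Cohort sepsis prevalence in percent, rounded to the reporting precision."""
    return round(100.0 * counts.sepsis_stays / counts.total_stays, digits)
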