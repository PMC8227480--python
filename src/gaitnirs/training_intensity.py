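"""Relative training intensity (RTI).

RTI = (mean session speed) / (reference gait speed); for robot-assisted
sessions the ratio is multiplied by the mean load fraction
(1 - body-weight-support fraction), so 50% support halves the value.
Subjects are dichotomized at the within-arm median (ties go high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass
class TrainingLog:
    subject_id: str
    treatment: str                        # "RAGT" | "OW"
    session_speeds: np.ndarray            # m/s, one per session
    bws_fractions: np.ndarray             # body-weight-support fraction in [0,1]
    reference_speed: float                # baseline T25FW speed (or declared max)

    def __post_init__(self) -> None:
        self.session_speeds = np.asarray(self.session_speeds, dtype=float)
        self.bws_fractions = np.asarray(self.bws_fractions, dtype=float)
        if self.session_speeds.size == 0:
            raise InvalidInputError("training log needs at least one session")
        if (self.session_speeds < 0).any():
            raise InvalidInputError("session speeds must be >= 0")
        if ((self.bws_fractions < 0) | (self.bws_fractions > 1)).any():
            raise InvalidInputError("BWS fractions must be in [0, 1]")


@dataclass
class RTIResult:
    subject_id: str
    rti: float
    category: str | None = None           # "high" | "low"
    cohort_median: float | None = None


def compute_rti(log: TrainingLog, bws_correction: str = "load_fraction") -> RTIResult:
    """Speed ratio with body-weight-support correction for RAGT.

    ``bws_correction`` selects the multiplier applied to the ratio:
    "load_fraction" (default) multiplies by mean(1 - BWS); the alternative
    "support_fraction" multiplies by mean(BWS).  At 50% support both give
    x0.50.  Overground walking gets no correction.
    """
    if log.reference_speed <= 0:
        raise InvalidInputError(
            f"subject {log.subject_id}: reference speed must be positive"
        )
    if bws_correction not in ("load_fraction", "support_fraction"):
        raise InvalidInputError(f"unknown bws_correction {bws_correction!r}")
    rti = float(np.mean(log.session_speeds)) / log.reference_speed
    if log.treatment == "RAGT":
        mean_bws = float(np.mean(log.bws_fractions))
        factor = (1.0 - mean_bws) if bws_correction == "load_fraction" else mean_bws
        rti *= factor
    return RTIResult(subject_id=log.subject_id, rti=rti)


def dichotomize_rti(cohort_rtis, subject_rti: float) -> str:
    """"low" below the cohort median, "high" at or above it.

    The median of an even cohort is the midpoint of the two central order
    statistics; ties at the median are classed high.
    """
    cohort = np.asarray(list(cohort_rtis), dtype=float)
    if cohort.size == 0:
        raise InvalidInputError("empty RTI cohort")
    median = float(np.median(cohort))
    return "low" if subject_rti < median else "high"


def categorize_cohort(
    logs: list[TrainingLog], bws_correction: str = "load_fraction"
) -> list[RTIResult]:
    """Compute RTI for every log and dichotomize within each treatment arm."""
    results = [compute_rti(log, bws_correction) for log in logs]
    for arm in {log.treatment for log in logs}:
        arm_rtis = [
            r.rti for r, log in zip(results, logs) if log.treatment == arm
        ]
        median = float(np.median(arm_rtis))
        for r, log in zip(results, logs):
            if log.treatment == arm:
                r.cohort_median = median
                r.category = dichotomize_rti(arm_rtis, r.rti)
    return results
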