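"""In-vivo efficacy metrics for PDX treatment/vehicle cohorts.

Tumor volume is estimated from caliper length and width with the
hemi-ellipsoid formula V = (L x W^2) / 2.  Antitumor efficacy of a
passage is summarized by the relative growth ratio

    T/C (%) = (Tti - Tt0) / (Vci - Vc0) x 100

and tumor growth inhibition

    TGI (%) = [1 - (Tti - Tt0) / (Vci - Vc0)] x 100 = 100 - T/C,

where Tt0/Tti are the treatment-group mean volumes on the first
treatment day and on day i, and Vc0/Vci the vehicle-group means.  A
treated tumor growing faster than vehicle gives a negative TGI, as
observed once resistance emerges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .io import GrowthRecord

__all__ = [
    "TreatmentComparison",
    "EfficacyResult",
    "tumor_volume",
    "efficacy",
    "group_summary",
    "resistance_call",
    "comparison_from_records",
]


@dataclass(frozen=True)
class TreatmentComparison:
    """Group mean volumes (mm^3) at baseline and at the evaluation day."""

    treatment_baseline: float  # Tt0
    treatment_day_i: float  # Tti
    vehicle_baseline: float  # Vc0
    vehicle_day_i: float  # Vci
    day: int = 0

    def __post_init__(self) -> None:
        for v in (
            self.treatment_baseline,
            self.treatment_day_i,
            self.vehicle_baseline,
            self.vehicle_day_i,
        ):
            if v < 0:
                raise ValueError("volumes must be non-negative")
        if self.day < 0:
            raise ValueError("day must be non-negative")


@dataclass(frozen=True)
class EfficacyResult:
    t_over_c_percent: float
    tgi_percent: float


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Hemi-ellipsoid caliper volume (L x W^2) / 2 in mm^3."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("length and width must be non-negative")
    if width_mm > length_mm:
        warnings.warn(
            f"width {width_mm} exceeds length {length_mm}; computing anyway",
            stacklevel=2,
        )
    return length_mm * width_mm**2 / 2.0


def efficacy(c: TreatmentComparison) -> EfficacyResult:
    """T/C and TGI percentages for one treatment/vehicle comparison.

    The two metrics are exact complements: T/C + TGI = 100.
    """
    denom = c.vehicle_day_i - c.vehicle_baseline
    if denom == 0:
        raise ZeroDivisionError(
            "vehicle group did not grow (Vci == Vc0); T/C undefined"
        )
    t_over_c = (c.treatment_day_i - c.treatment_baseline) / denom * 100.0
    return EfficacyResult(t_over_c_percent=t_over_c, tgi_percent=100.0 - t_over_c)


def group_summary(
    records: Sequence[GrowthRecord], group: str, day: int
) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and n of volumes for (group, day).

    With a single animal the SD is reported as 0.0 (n flags the case).
    """
    volumes = [r.volume_mm3 for r in records if r.group == group and r.day == day]
    if not volumes:
        raise LookupError(f"no growth records for group={group!r} day={day}")
    n = len(volumes)
    mean = sum(volumes) / n
    if n == 1:
        return mean, 0.0, 1
    sd = math.sqrt(sum((v - mean) ** 2 for v in volumes) / (n - 1))
    return mean, sd, n


def resistance_call(eff: EfficacyResult, threshold_percent: float = 30.0) -> str:
    """Classify a passage as responsive (TGI >= threshold) or resistant.

    The 30% TGI convention is a configurable default, not a measured
    quantity; the boundary itself counts as responsive.
    """
    return "responsive" if eff.tgi_percent >= threshold_percent else "resistant"


def comparison_from_records(
    records: Sequence[GrowthRecord], baseline_day: int, day: int
) -> TreatmentComparison:
    """Build a :class:`TreatmentComparison` from raw measurements using
    group means on the baseline and evaluation days."""
    t0, _, _ = group_summary(records, "treatment", baseline_day)
    ti, _, _ = group_summary(records, "treatment", day)
    v0, _, _ = group_summary(records, "vehicle", baseline_day)
    vi, _, _ = group_summary(records, "vehicle", day)
    return TreatmentComparison(t0, ti, v0, vi, day=day)
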