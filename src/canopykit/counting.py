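"""Fruit counting with occlusion correction.

Detectors count partly occluded fruit but never the fully hidden ones, so
machine counts systematically undershoot. A correction factor calibrated
against manual counts on a subset of trees scales machine counts up to
whole-tree estimates. The factor is the ratio of totals, sum(manual) /
sum(machine), which tolerates individual zero-count trees and, applied back
to the calibration set, reproduces the manual total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class CountReport:
    raw_count: int
    correction_factor: float
    corrected_count: float
    confidence_threshold: float

    def __post_init__(self):
        if self.raw_count < 0 or self.correction_factor <= 0:
            raise ValueError("raw count must be >= 0 and factor > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def count(detections, class_label: str = "fruit",
          conf_threshold: float = 0.5) -> int:
    """Number of detections of a class with score >= threshold (inclusive)."""
    if not (0.0 <= conf_threshold <= 1.0):
        raise ValueError("confidence threshold must be in [0, 1]")
    return sum(1 for d in detections
               if d.class_label == class_label and d.score >= conf_threshold)


def calibrate_correction(machine_counts, manual_counts) -> float:
    """Occlusion correction factor: sum(manual) / sum(machine) over the
    calibration trees."""
    machine = np.asarray(machine_counts, dtype=float)
    manual = np.asarray(manual_counts, dtype=float)
    if machine.shape != manual.shape or machine.size == 0:
        raise ValueError("count lists must be equal-length and non-empty")
    total = machine.sum()
    if total <= 0:
        raise ValueError("total machine count must be positive")
    return float(manual.sum() / total)


def count_report(detections, class_label: str = "fruit",
                 conf_threshold: float = 0.5,
                 correction_factor: float = 1.0) -> CountReport:
    raw = count(detections, class_label, conf_threshold)
    return CountReport(raw_count=raw, correction_factor=correction_factor,
                       corrected_count=raw * correction_factor,
                       confidence_threshold=conf_threshold)
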