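"""Relative gene expression by the comparative-Ct (2^-ddCt) method.

Used to validate SILAC candidates at the transcript level: expression of a
target gene in a test sample (co-culture) is expressed relative to a
reference gene and a control sample (monoculture),

    dCt_test    = Ct(target, test)    - Ct(reference, test)
    dCt_control = Ct(target, control) - Ct(reference, control)
    fold        = 2 ** -(dCt_test - dCt_control)

The formula assumes perfect (2-fold per cycle) amplification efficiency for
both genes; efficiency-corrected models are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["QpcrMeasurement", "fold_expression"]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Threshold cycles of target and reference gene in test and control."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_control: float
    ct_reference_control: float

    def validate(self) -> None:
        for name in (
            "ct_target_test", "ct_reference_test",
            "ct_target_control", "ct_reference_control",
        ):
            ct = getattr(self, name)
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be a finite positive cycle count, got {ct}")


def fold_expression(measurement: QpcrMeasurement) -> float:
    """2^-ddCt relative expression of the target gene (test vs control)."""
    measurement.validate()
    d_ct_test = measurement.ct_target_test - measurement.ct_reference_test
    d_ct_control = measurement.ct_target_control - measurement.ct_reference_control
    return 2.0 ** -(d_ct_test - d_ct_control)
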