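"""Verification utilities: random draws of valid models and records.

Used by the test suite and the acceptance script to exercise the
closed-form likelihood against the matrix-exponential oracle over a
clinically plausible parameter range.
"""

from __future__ import annotations

import numpy as np

from .likelihood import PatientRecord
from .model import REVISED_ZEROS, DischargeMode, ModelParams, StrokeType


def random_params(rng: np.random.Generator,
                  mask=REVISED_ZEROS) -> ModelParams:
    """A random valid parameter set in a clinically plausible range."""
    draw = lambda lo, hi: float(rng.uniform(lo, hi))
    return ModelParams(
        gamma1=draw(3.0, 8.0), beta1=draw(-0.08, 0.0),
        gamma2=draw(-5.0, 0.0), beta2=draw(0.0, 0.1),
        theta0=draw(-12.0, -6.0), theta1=draw(0.04, 0.12),
        mu1=draw(5.0, 40.0), mu2=draw(0.5, 5.0), mu3=draw(0.5, 3.0),
        nu1=draw(0.0, 2.0), nu2=draw(0.0, 1.0), nu3=draw(0.5, 3.0),
        rho1=draw(0.0, 2.0), rho2=draw(4.0, 20.0), rho3=draw(1.0, 6.0),
        rho4=draw(20.0, 120.0),
        zero_mask=mask,
    )


def random_record(rng: np.random.Generator) -> PatientRecord:
    """A random patient record spanning all types, modes, ages and stays."""
    return PatientRecord(
        stroke_type=rng.choice([t.value for t in StrokeType]),
        age=float(rng.uniform(40.0, 100.0)),
        los_days=float(rng.uniform(0.2, 400.0)),
        mode=rng.choice([m.value for m in DischargeMode]),
    )
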