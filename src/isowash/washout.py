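"""Exponential washout forward model.

Breath δ¹³C relaxes from the fed-state value δ¹³C₀ toward the fasted
asymptote δ¹³C∞ as recently ingested sugar washes out of the oxidized fuel
pool:

    δ¹³C(t) = δ¹³C∞ − (δ¹³C∞ − δ¹³C₀) · e^(−t/τ)

with τ the average retention time in minutes.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ValidationError
from .types import WashoutParams


def predict_d13c(params: WashoutParams, t: float) -> float:
    """Expected breath δ¹³C at time t minutes after the first measurement."""
    if not (t >= 0):
        raise ValidationError(f"time must be >= 0, got {t}")
    return params.d13c_inf - (params.d13c_inf - params.d13c_0) * np.exp(
        -t / params.tau_min
    )


def predict_series(params: WashoutParams, schedule: Sequence[float]) -> np.ndarray:
    """Vectorized predict_d13c over a non-decreasing sampling schedule."""
    t = np.asarray(schedule, dtype=float)
    if t.size == 0:
        return t.copy()
    if np.any(t < 0):
        raise ValidationError("schedule times must be >= 0")
    if np.any(np.diff(t) < 0):
        raise ValidationError("schedule must be non-decreasing")
    return params.d13c_inf - (params.d13c_inf - params.d13c_0) * np.exp(
        -t / params.tau_min
    )
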