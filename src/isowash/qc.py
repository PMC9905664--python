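"""Equilibration QC: segmented regression on CO₂ concentration traces.

Before breath measurements start, the cuvette must have equilibrated with
CO₂-free inflow: the concentration trace should rise and then plateau. A
two-segment continuous piecewise-linear (hinge) model is fit by least
squares, with the breakpoint grid-searched over interior observation times;
equilibration is declared when the post-break slope is negligible relative
to the pre-break slope.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError

_MIN_POINTS = 6
_EDGE_EXCLUDE = 2
_SSE_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class BreakpointFit:
    breakpoint_min: float
    slope_before: float
    slope_after: float
    sse: float
    intercept: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.breakpoint_min, self.slope_before, self.slope_after, self.sse)


def fit_breakpoint(times: Sequence[float], co2: Sequence[float]) -> BreakpointFit:
    """Two-segment continuous least-squares fit of a CO₂ trace.

    The breakpoint is chosen by grid search over interior observation times
    (two points excluded at each end); ties in SSE break toward the earliest
    candidate.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(co2, dtype=float)
    if t.size != y.size:
        raise ValidationError("times and co2 must have equal length")
    if t.size < _MIN_POINTS:
        raise InsufficientDataError(
            f"segmented regression needs >= {_MIN_POINTS} points, got {t.size}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")

    candidates = t[_EDGE_EXCLUDE : t.size - _EDGE_EXCLUDE]
    best: BreakpointFit | None = None
    for c in candidates:
        X = np.column_stack([np.ones_like(t), t, np.maximum(0.0, t - c)])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        fit = BreakpointFit(
            breakpoint_min=float(c),
            slope_before=float(beta[1]),
            slope_after=float(beta[1] + beta[2]),
            sse=sse,
            intercept=float(beta[0]),
        )
        # strict improvement beyond fp noise keeps the earliest tied candidate
        if best is None or sse < best.sse * (1 - _SSE_TIE_RTOL) - 1e-12:
            best = fit
    assert best is not None
    return best


def is_equilibrated(
    fit: BreakpointFit,
    slope_tol: float | None = None,
    rel_tol: float = 0.01,
    abs_floor: float = 0.0,
) -> bool:
    """True when the post-break slope is flat enough.

    Default tolerance is 1% of |slope_before| with an optional absolute
    floor; pass `slope_tol` to override entirely.
    """
    tol = slope_tol if slope_tol is not None else max(rel_tol * abs(fit.slope_before), abs_floor)
    return abs(fit.slope_after) <= tol
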