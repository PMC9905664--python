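"""Posterior summaries: HPD intervals, KDE modes, peaks, and pooling.

The 85% highest posterior density interval (HPDI) is the narrowest
contiguous interval holding 85% of the draws; modes are argmaxes of a
Gaussian kernel density estimate with Silverman's rule-of-thumb bandwidth.
Per-bird posteriors are pooled by concatenation (equal retained draw counts
give each bird equal weight) to describe population-level distributions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyGroupError, InsufficientSamplesError, ValidationError
from .inference import PosteriorSamples, convergence_check

_MIN_DRAWS = 20
_GRID_SIZE = 512
_PEAK_REL_HEIGHT = 0.10


@dataclass(frozen=True)
class HPDInterval:
    """Shortest contiguous interval holding `mass` posterior probability."""

    lower: float
    upper: float
    mass: float
    mode: float

    def __post_init__(self):
        if not (0 < self.mass < 1):
            raise ValidationError("mass must be in (0, 1)")
        if not (self.lower <= self.mode <= self.upper):
            raise ValidationError("mode must lie inside the interval")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class PooledPosterior:
    """Concatenated per-bird draws for one (group, parameter) cell."""

    labels: dict[str, object]
    parameter: str
    draws: np.ndarray
    bird_counts: dict[str, int]

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.size != sum(self.bird_counts.values()):
            raise ValidationError("pooled draw count must equal the sum over birds")


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = float(np.std(x))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * x.size ** (-0.2)


def _kde_grid(x: np.ndarray, bandwidth: float | None = None):
    """Gaussian KDE evaluated on a 512-point grid padded by one bandwidth."""
    bw = _silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    grid = np.linspace(x.min() - bw, x.max() + bw, _GRID_SIZE)
    density = np.zeros(_GRID_SIZE)
    for start in range(0, x.size, 4096):
        block = x[start : start + 4096]
        z = (grid[:, None] - block[None, :]) / bw
        density += np.exp(-0.5 * z * z).sum(axis=1)
    density /= x.size * bw * math.sqrt(2 * math.pi)
    return grid, density


def mode_estimate(draws: Sequence[float], bandwidth: float | None = None) -> float:
    """KDE-based posterior mode; exact common value if variance is zero."""
    x = np.asarray(draws, dtype=float)
    if x.size < _MIN_DRAWS:
        raise InsufficientSamplesError(f"mode needs >= {_MIN_DRAWS} draws, got {x.size}")
    if np.ptp(x) == 0:
        return float(x[0])
    grid, density = _kde_grid(x, bandwidth)
    return float(grid[int(np.argmax(density))])


def kde_peaks(draws: Sequence[float], rel_height: float = _PEAK_REL_HEIGHT) -> list[float]:
    """All local KDE maxima above `rel_height` of the global maximum."""
    x = np.asarray(draws, dtype=float)
    if x.size < _MIN_DRAWS:
        raise InsufficientSamplesError(f"peaks need >= {_MIN_DRAWS} draws")
    if np.ptp(x) == 0:
        return [float(x[0])]
    grid, d = _kde_grid(x)
    interior = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
    keep = interior[d[interior] >= rel_height * d.max()]
    return [float(grid[i]) for i in keep]


def is_multimodal(draws: Sequence[float]) -> bool:
    """True when the KDE shows >= 2 peaks above 10% of the global maximum."""
    return len(kde_peaks(draws)) >= 2


def hpdi(draws: Sequence[float], mass: float = 0.85) -> HPDInterval:
    """Shortest contiguous interval holding ceil(mass·n) sorted draws.

    Ties between equally narrow windows break toward the lowest starting
    index. The attached mode is the KDE mode (restricted to the interval in
    the rare multimodal case where the global KDE mode falls outside it).
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < _MIN_DRAWS:
        raise InsufficientSamplesError(f"hpdi needs >= {_MIN_DRAWS} draws, got {n}")
    if not (0 < mass < 1):
        raise ValidationError("mass must be in (0, 1)")
    m = math.ceil(mass * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lowest index
    lower, upper = float(x[i]), float(x[i + m - 1])

    if np.ptp(x) == 0:
        return HPDInterval(lower=lower, upper=upper, mass=mass, mode=float(x[0]))
    mode = mode_estimate(x)
    if not (lower <= mode <= upper):
        grid, density = _kde_grid(x)
        inside = (grid >= lower) & (grid <= upper)
        mode = float(grid[inside][int(np.argmax(density[inside]))])
    return HPDInterval(lower=lower, upper=upper, mass=mass, mode=mode)


def pool(
    samples: PosteriorSamples,
    parameter: str,
    group_by: Sequence[str] = ("species",),
    expected_groups: Sequence[tuple] | None = None,
) -> dict[tuple, PooledPosterior]:
    """Concatenate per-bird draws of `parameter` within metadata groups.

    `group_by` names metadata columns (species and/or year). If
    `expected_groups` is given, any expected group with no birds raises an
    EmptyGroupError naming its labels.
    """
    if parameter not in ("d13c_0", "d13c_inf"):
        raise ValidationError(f"cannot pool parameter {parameter!r}")
    for col in group_by:
        if col not in ("species", "year"):
            raise ValidationError(f"cannot group by {col!r}")
    arr = getattr(samples, parameter)
    meta = samples.meta.set_index("bird_id")

    groups: dict[tuple, list[str]] = {}
    for bid in samples.bird_ids:
        key = tuple(meta.loc[bid, col] for col in group_by)
        groups.setdefault(key, []).append(bid)

    if expected_groups is not None:
        for key in expected_groups:
            key = tuple(key)
            if key not in groups:
                labels = ", ".join(f"{c}={v}" for c, v in zip(group_by, key))
                raise EmptyGroupError(f"no birds in group ({labels})")

    out: dict[tuple, PooledPosterior] = {}
    for key, bids in groups.items():
        cols = [samples.bird_ids.index(b) for b in bids]
        draws = arr[:, :, cols].reshape(-1)
        out[key] = PooledPosterior(
            labels=dict(zip(group_by, key)),
            parameter=parameter,
            draws=draws,
            bird_counts={b: arr.shape[0] * arr.shape[1] for b in bids},
        )
    return out


def summarize_table1(samples: PosteriorSamples, mass: float = 0.85) -> pd.DataFrame:
    """Per-species report of τ mode + HPDI and pooled endpoint HPDIs.

    One row per (species, years, parameter). τ is shared across birds, so
    its row repeats identically for every species. Species observed in more
    than one year additionally get per-year endpoint rows. A convergence
    flag (R̂ < 1.1 for all parameters) is attached to every row.
    """
    report = convergence_check(samples)
    tau_flat = samples.tau.reshape(-1)
    tau_int = hpdi(tau_flat, mass)
    rows = []

    def add_row(species, years, parameter, interval, n_birds):
        rows.append(
            {
                "species": species,
                "years": years,
                "parameter": parameter,
                "mode": interval.mode,
                "hpdi_lower": interval.lower,
                "hpdi_upper": interval.upper,
                "mass": mass,
                "n_birds": n_birds,
                "converged": report.passed,
            }
        )

    meta = samples.meta
    for species in sorted(meta["species"].unique()):
        n_sp = int((meta["species"] == species).sum())
        add_row(species, "all", "tau_min", tau_int, n_sp)
        for parameter in ("d13c_0", "d13c_inf"):
            pooled = pool(samples, parameter, group_by=("species",))
            add_row(species, "all", parameter, hpdi(pooled[(species,)].draws, mass), n_sp)
        years = sorted(meta.loc[meta["species"] == species, "year"].unique())
        if len(years) > 1:
            for year in years:
                n_year = int(((meta["species"] == species) & (meta["year"] == year)).sum())
                for parameter in ("d13c_0", "d13c_inf"):
                    pooled = pool(samples, parameter, group_by=("species", "year"))
                    add_row(
                        species,
                        str(year),
                        parameter,
                        hpdi(pooled[(species, year)].draws, mass),
                        n_year,
                    )
    return pd.DataFrame(rows)


def peaks_table(samples: PosteriorSamples, round_to: int = 0) -> pd.DataFrame:
    """Pooled-distribution KDE peaks per (species, parameter), rounded to 1‰."""
    rows = []
    for parameter in ("d13c_0", "d13c_inf"):
        pooled = pool(samples, parameter, group_by=("species",))
        for (species,), pp in sorted(pooled.items()):
            for peak in kde_peaks(pp.draws):
                rows.append(
                    {
                        "species": species,
                        "parameter": parameter,
                        "peak": round(peak, round_to),
                    }
                )
    return pd.DataFrame(rows)
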