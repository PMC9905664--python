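"""Domain types for breath-sample time series and washout parameters.

All isotope values are carbon δ¹³C in per mil (‰) relative to VPDB; times
are minutes since the first breath measurement of a bird.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .errors import ValidationError


class Species(str, Enum):
    broad_tailed = "broad_tailed"
    rufous = "rufous"


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


_SPECIES_ALIASES = {
    "broad_tailed": Species.broad_tailed,
    "broad-tailed": Species.broad_tailed,
    "broadtailed": Species.broad_tailed,
    "selasphorus platycercus": Species.broad_tailed,
    "rufous": Species.rufous,
    "selasphorus rufus": Species.rufous,
}

_SEX_ALIASES = {
    "male": Sex.male,
    "m": Sex.male,
    "female": Sex.female,
    "f": Sex.female,
    "unknown": Sex.unknown,
    "u": Sex.unknown,
    "": Sex.unknown,
    "na": Sex.unknown,
}


def parse_species(value: str) -> Species:
    """Normalize a species string; unrecognized taxa are a hard error."""
    key = str(value).strip().lower()
    try:
        return _SPECIES_ALIASES[key]
    except KeyError:
        raise ValidationError(
            f"unknown species {value!r}; expected one of "
            f"{sorted({a.value for a in Species})}"
        ) from None


def parse_sex(value: str) -> Sex:
    """Normalize a sex string; anything unrecognized maps to `unknown`."""
    key = str(value).strip().lower()
    return _SEX_ALIASES.get(key, Sex.unknown)


@dataclass(frozen=True)
class BreathSample:
    """One timed breath measurement: δ¹³C of exhaled CO₂, optional [CO₂]."""

    time_min: float
    d13c: float
    co2_ppm: float | None = None

    def __post_init__(self):
        if not (self.time_min >= 0):
            raise ValidationError(f"time_min must be >= 0, got {self.time_min}")
        if not math.isfinite(self.d13c):
            raise ValidationError(f"d13c must be finite, got {self.d13c}")
        if self.co2_ppm is not None and not (self.co2_ppm > 0):
            raise ValidationError(f"co2_ppm must be > 0, got {self.co2_ppm}")


@dataclass(frozen=True)
class BirdSeries:
    """One bird's breath time series plus metadata.

    Samples must be strictly increasing in time. A series may hold a single
    sample, but fitting requires at least two (enforced at fit time).
    """

    bird_id: str
    species: Species
    sex: Sex
    year: int
    site: str
    samples: tuple[BreathSample, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(self.samples))
        times = [s.time_min for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"bird {self.bird_id!r}: sample times must be strictly increasing"
            )

    @property
    def times(self) -> list[float]:
        return [s.time_min for s in self.samples]

    @property
    def d13c_values(self) -> list[float]:
        return [s.d13c for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class WashoutParams:
    """Parameters of one exponential washout curve.

    d13c_0 is the fed-state breath value at t = 0, d13c_inf the fasted-state
    asymptote, and tau_min the average retention time in minutes (1/τ is the
    instantaneous turnover rate).
    """

    d13c_0: float
    d13c_inf: float
    tau_min: float

    def __post_init__(self):
        if not (self.tau_min > 0):
            raise ValidationError(f"tau_min must be > 0, got {self.tau_min}")
        if not (math.isfinite(self.d13c_0) and math.isfinite(self.d13c_inf)):
            raise ValidationError("d13c_0 and d13c_inf must be finite")


@dataclass(frozen=True)
class RatioPair:
    """A sample ¹³C/¹²C ratio paired with the VPDB standard ratio."""

    r_sample: float
    r_standard: float

    def __post_init__(self):
        if not (self.r_sample > 0 and self.r_standard > 0):
            raise ValidationError("isotope ratios must be positive")


def ratio_to_delta(pair: RatioPair) -> float:
    """Convert a ratio pair to δ-notation: (R_sample/R_standard − 1) × 1000 ‰."""
    return (pair.r_sample / pair.r_standard - 1.0) * 1000.0


def validate_collection(collection: Sequence[BirdSeries]) -> None:
    """Check that bird_ids are unique within a dataset."""
    seen: set[str] = set()
    for series in collection:
        if series.bird_id in seen:
            raise ValidationError(f"duplicate bird_id {series.bird_id!r} in dataset")
        seen.add(series.bird_id)
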