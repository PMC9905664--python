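"""Readers and writers for the breath-sample CSV contract and run configs.

Breath table: CSV with header ``bird_id,species,sex,year,site,time_min,d13c``
plus an optional ``co2_ppm`` column; UTF-8, ``.`` decimal separator, one row
per breath sample. Lines starting with ``#`` are provenance comments and are
ignored on read.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DuplicateSampleError, RowParseError, SchemaError
from .types import BirdSeries, BreathSample, parse_sex, parse_species, validate_collection

REQUIRED_COLUMNS = ["bird_id", "species", "sex", "year", "site", "time_min", "d13c"]
OPTIONAL_COLUMNS = ["co2_ppm"]


def read_breath_table(path: str | Path) -> list[BirdSeries]:
    """Read a breath-sample CSV into BirdSeries grouped by bird_id.

    Rows are grouped by bird and sorted by time; species/sex strings are
    normalized. Errors name the offending column, row, or duplicate.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    has_co2 = "co2_ppm" in df.columns

    numeric_cols = ["time_min", "d13c"] + (["co2_ppm"] if has_co2 else [])
    for col in numeric_cols:
        raw = df[col].str.strip()
        optional = col == "co2_ppm"
        parsed = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = parsed.isna() & (raw != "" if optional else True)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: header line plus 1-based indexing
            raise RowParseError(
                f"unparseable numeric value {raw.iloc[idx]!r} in column {col!r} "
                f"at line {idx + 2}",
                line=idx + 2,
            )
        # re-parse with Python's strtod: exact to the last ulp, unlike the
        # fast path behind to_numeric
        df[col] = [float(v) if v.strip() != "" else np.nan for v in raw]
    try:
        df["year"] = df["year"].str.strip().astype(int)
    except ValueError as exc:
        raise RowParseError(f"unparseable year: {exc}") from exc

    dup = df.duplicated(subset=["bird_id", "time_min"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise DuplicateSampleError(
            f"duplicate sample for bird {row['bird_id']!r} at t={row['time_min']} min"
        )

    collection: list[BirdSeries] = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        grp = grp.sort_values("time_min")
        samples = [
            BreathSample(
                time_min=float(r.time_min),
                d13c=float(r.d13c),
                co2_ppm=(
                    float(r.co2_ppm)
                    if has_co2 and np.isfinite(getattr(r, "co2_ppm", np.nan))
                    else None
                ),
            )
            for r in grp.itertuples()
        ]
        first = grp.iloc[0]
        collection.append(
            BirdSeries(
                bird_id=str(bird_id),
                species=parse_species(first["species"]),
                sex=parse_sex(first["sex"]),
                year=int(first["year"]),
                site=str(first["site"]),
                samples=samples,
            )
        )
    validate_collection(collection)
    return collection


def collection_to_frame(collection: Sequence[BirdSeries]) -> pd.DataFrame:
    rows = []
    any_co2 = any(s.co2_ppm is not None for b in collection for s in b.samples)
    for bird in collection:
        for s in bird.samples:
            row = {
                "bird_id": bird.bird_id,
                "species": bird.species.value,
                "sex": bird.sex.value,
                "year": bird.year,
                "site": bird.site,
                "time_min": s.time_min,
                "d13c": s.d13c,
            }
            if any_co2:
                row["co2_ppm"] = s.co2_ppm if s.co2_ppm is not None else np.nan
            rows.append(row)
    cols = REQUIRED_COLUMNS + (["co2_ppm"] if any_co2 else [])
    return pd.DataFrame(rows, columns=cols)


def write_breath_table(
    collection: Sequence[BirdSeries],
    path: str | Path,
    provenance: str | None = None,
) -> Path:
    """Write BirdSeries to the CSV contract. read∘write is the identity.

    Floats are written with Python's shortest round-trip repr so values are
    reproduced to full stored precision.
    """
    validate_collection(collection)
    df = collection_to_frame(collection)
    path = Path(path)
    buf = _io.StringIO()
    if provenance:
        buf.write(f"# {provenance}\n")
    # shortest round-trip repr keeps read∘write the identity at full precision
    df.to_csv(buf, index=False, float_format=lambda v: repr(float(v)))
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("run configuration must be a YAML mapping")
    return cfg
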