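"""Reading and validating bout logs, body-weight tables, and animal metadata.

The canonical input is a delimited text log with one row per feeding bout
(one uninterrupted feeder visit): animal id, ISO 8601 start timestamp, bout
duration in seconds, and bout mass in grams (mass of food removed during the
visit). This module only parses and validates; interpretation of gaps
between bouts is the segmentation module's job.

Timestamps are timezone-naive local clock times, because the light schedule
is defined on the local clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MealPatternError",
    "SchemaError",
    "ValidationError",
    "AnimalRecord",
    "BoutStream",
    "read_bout_log",
    "read_body_weights",
    "read_metadata",
    "mean_body_weight",
    "write_table",
]

BOUT_COLUMNS = ("animal_id", "timestamp", "bout_duration_s", "bout_mass_g")
BW_COLUMNS = ("animal_id", "timestamp", "bw_g")
META_COLUMNS = ("animal_id", "genotype", "sex", "age_weeks")


class MealPatternError(Exception):
    """Base class for package errors."""


class SchemaError(MealPatternError):
    """Input file is missing required columns."""


class ValidationError(MealPatternError):
    """Input rows violate the data contract; offending rows are listed."""


@dataclass
class AnimalRecord:
    """Per-animal metadata and body-weight series.

    ``body_weight`` is a DataFrame with columns ``timestamp`` (datetime64)
    and ``bw_g`` (grams, strictly positive), sorted by time.
    """

    animal_id: str
    genotype: str = "control"
    sex: str = "male"
    age_weeks: int | None = None
    body_weight: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.body_weight is not None:
            bw = self.body_weight
            if not {"timestamp", "bw_g"}.issubset(bw.columns):
                raise SchemaError("body_weight needs columns timestamp, bw_g")
            if (bw["bw_g"] <= 0).any():
                raise ValidationError(
                    f"animal {self.animal_id}: non-positive body weights"
                )
            self.body_weight = bw.sort_values("timestamp").reset_index(drop=True)


@dataclass
class BoutStream:
    """Time-ordered feeding bouts of one animal within a recording window.

    ``bouts`` has columns ``t_start`` (datetime64), ``duration_s`` and
    ``mass_g`` (floats, non-negative), sorted by ``t_start``.
    """

    animal_id: str
    bouts: pd.DataFrame
    window: tuple[pd.Timestamp, pd.Timestamp]
    animal: AnimalRecord | None = None

    def __post_init__(self) -> None:
        b = self.bouts
        required = {"t_start", "duration_s", "mass_g"}
        if not required.issubset(b.columns):
            raise SchemaError(f"bouts needs columns {sorted(required)}")
        b = b.sort_values("t_start", kind="stable").reset_index(drop=True)
        if (b["mass_g"] < 0).any() or (b["duration_s"] < 0).any():
            raise ValidationError(
                f"animal {self.animal_id}: negative bout mass or duration"
            )
        self.bouts = b
        lo, hi = pd.Timestamp(self.window[0]), pd.Timestamp(self.window[1])
        if len(b):
            t_end = b["t_start"] + pd.to_timedelta(b["duration_s"], unit="s")
            if (b["t_start"] < lo).any() or (t_end > hi).any():
                raise ValidationError(
                    f"animal {self.animal_id}: bouts outside recording window"
                )
        self.window = (lo, hi)

    @property
    def t_end(self) -> pd.Series:
        return self.bouts["t_start"] + pd.to_timedelta(self.bouts["duration_s"], unit="s")

    def subset(self, start, end) -> "BoutStream":
        """Bouts with t_start in [start, end); window clipped accordingly."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        mask = (self.bouts["t_start"] >= start) & (self.bouts["t_start"] < end)
        return BoutStream(
            animal_id=self.animal_id,
            bouts=self.bouts.loc[mask].reset_index(drop=True),
            window=(max(start, self.window[0]), min(end, self.window[1])),
            animal=self.animal,
        )


def _remap(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


def read_bout_log(
    path,
    schema: Mapping[str, str] | None = None,
    window: tuple | None = None,
    animals: Mapping[str, AnimalRecord] | None = None,
) -> dict[str, BoutStream]:
    """Read a bout log CSV into one :class:`BoutStream` per animal.

    Parameters
    ----------
    path
        Delimited text file with columns ``animal_id, timestamp,
        bout_duration_s, bout_mass_g`` (remappable via ``schema``,
        a mapping from canonical name to the file's column name).
    window
        Recording window (start, end); defaults to the span of the data
        across all animals, so co-recorded animals share one window.
    animals
        Optional metadata records to attach to each stream.

    Raises
    ------
    SchemaError
        A required column is absent.
    ValidationError
        Unparseable timestamps, negative masses/durations, or duplicate
        timestamps within one animal; offending file rows are listed
        (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path, comment="#")
    df = _remap(df, schema)
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    # file row numbers: header is row 1, first data row is row 2
    rownum = df.index.to_numpy() + 2
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = []
    if ts.isna().any():
        bad += [f"row {r}: unparseable timestamp" for r in rownum[ts.isna().to_numpy()]]
    mass = pd.to_numeric(df["bout_mass_g"], errors="coerce")
    dur = pd.to_numeric(df["bout_duration_s"], errors="coerce")
    for name, col in (("bout_mass_g", mass), ("bout_duration_s", dur)):
        nan = col.isna().to_numpy()
        if nan.any():
            bad += [f"row {r}: non-numeric {name}" for r in rownum[nan]]
        neg = (col < 0).to_numpy()
        if neg.any():
            bad += [f"row {r}: negative {name}" for r in rownum[neg]]
    dup = df.assign(_ts=ts).duplicated(subset=["animal_id", "_ts"], keep=False) & ~ts.isna()
    if dup.any():
        first = df.assign(_ts=ts).duplicated(subset=["animal_id", "_ts"], keep="first")
        bad += [
            f"row {r}: duplicate timestamp for animal"
            for r in rownum[(dup & first).to_numpy()]
        ]
    if bad:
        raise ValidationError(f"{path}: invalid rows:\n  " + "\n  ".join(sorted(bad)))

    df = df.assign(t_start=ts, duration_s=dur.astype(float), mass_g=mass.astype(float))
    df = df.sort_values(["animal_id", "t_start"], kind="stable")
    if window is None:
        t_end = df["t_start"] + pd.to_timedelta(df["duration_s"], unit="s")
        window = (df["t_start"].min(), t_end.max())
    streams: dict[str, BoutStream] = {}
    for aid, grp in df.groupby("animal_id", sort=True):
        streams[str(aid)] = BoutStream(
            animal_id=str(aid),
            bouts=grp[["t_start", "duration_s", "mass_g"]].reset_index(drop=True),
            window=window,
            animal=animals.get(str(aid)) if animals else None,
        )
    return streams


def read_body_weights(path, schema: Mapping[str, str] | None = None) -> dict[str, pd.DataFrame]:
    """Read a body-weight CSV (`animal_id, timestamp, bw_g`) per animal."""
    df = pd.read_csv(path, comment="#")
    df = _remap(df, schema)
    missing = [c for c in BW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = {}
    for aid, grp in df.groupby("animal_id", sort=True):
        out[str(aid)] = grp[["timestamp", "bw_g"]].sort_values("timestamp").reset_index(drop=True)
    return out


def read_metadata(
    path,
    body_weights: Mapping[str, pd.DataFrame] | None = None,
    schema: Mapping[str, str] | None = None,
) -> dict[str, AnimalRecord]:
    """Read animal metadata (`animal_id, genotype, sex, age_weeks`)."""
    df = pd.read_csv(path, comment="#")
    df = _remap(df, schema)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = {}
    for _, row in df.iterrows():
        aid = str(row["animal_id"])
        records[aid] = AnimalRecord(
            animal_id=aid,
            genotype=str(row["genotype"]),
            sex=str(row["sex"]),
            age_weeks=int(row["age_weeks"]),
            body_weight=body_weights.get(aid) if body_weights else None,
        )
    return records


def mean_body_weight(animal: AnimalRecord, window: tuple) -> float:
    """Arithmetic mean of the body weights measured inside ``window``.

    The mean body weight over the recording window is the denominator used
    to adjust net energy intake to body mass (kCal/gBW).
    """
    if animal.body_weight is None or animal.body_weight.empty:
        raise ValidationError(
            f"animal {animal.animal_id}: no body-weight measurements; supply at "
            "least one BW value"
        )
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    bw = animal.body_weight
    sel = bw[(bw["timestamp"] >= lo) & (bw["timestamp"] <= hi)]
    if sel.empty:
        raise ValidationError(
            f"animal {animal.animal_id}: no body-weight measurements inside "
            f"[{lo}, {hi}]; widen the window or supply a single in-window BW"
        )
    return float(sel["bw_g"].mean())


def write_table(df: pd.DataFrame, path, config_id: str | None = None) -> None:
    """Write a result table as CSV, embedding the config snapshot id.

    The id is written as a leading ``#``-comment line; all package readers
    pass ``comment='#'`` so round-trips are lossless.
    """
    with open(path, "w") as fh:
        if config_id is not None:
            fh.write(f"# config_id={config_id}\n")
        df.to_csv(fh, index=False)
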