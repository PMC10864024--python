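"""Meal segmentation: partition a bout stream into meals and intermeal intervals.

Operational definitions
-----------------------
A *meal* is a cluster of feeding bouts in which consecutive bouts are
separated by less than the IMI threshold (default 5 min), with total mass at
least the minimum meal size (default 0.050 g). Clusters below the mass
criterion are *subthreshold* (nibbling): their mass counts toward total
intake but they carry no meal-level metrics and they do not interrupt an
intermeal interval.

The gap between two bouts is end-to-start: ``t_start[i+1] - (t_start[i] +
duration[i])``. A gap < threshold joins bouts into one cluster; a gap >=
threshold separates clusters. The *intermeal interval* (IMI) runs from the
end of the last bout of one qualifying meal to the start of the first bout
of the next qualifying meal; by construction every IMI is >= the threshold.

Satiation is read out as meal size (kCal = mass x diet energy density) and
satiety as the IMI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Photoperiod, ProtocolConfig, photoperiods_of
from .io import BoutStream, ValidationError

__all__ = [
    "MealSeries",
    "cluster_bouts",
    "segment_meals",
    "feeding_rate",
    "meals_table",
]

CLUSTER_COLUMNS = [
    "t_first",
    "t_last",
    "n_bouts",
    "mass_g",
    "size_kcal",
    "eating_time_s",
    "span_s",
    "qualifies",
    "photoperiod",
    "first_bout",
    "last_bout",
]


def cluster_bouts(stream: BoutStream, cfg: ProtocolConfig) -> pd.DataFrame:
    """Cluster time-ordered bouts by the end-to-start gap criterion.

    Returns one row per cluster with columns :data:`CLUSTER_COLUMNS`.
    ``t_first`` is the first bout's start, ``t_last`` the last bout's end;
    ``span_s = t_last - t_first`` and ``eating_time_s`` is the summed bout
    duration. ``qualifies`` flags clusters with mass >= the minimum meal
    size. The photoperiod label is that of ``t_first`` (meals straddling a
    light transition are not split).

    Raises
    ------
    ValidationError
        If any consecutive bouts overlap (negative gap).
    """
    b = stream.bouts
    if b.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    # exact integer-nanosecond gap arithmetic (float seconds since the Unix
    # epoch cannot resolve below ~microseconds)
    start_ns = b["t_start"].astype("int64").to_numpy()
    dur = b["duration_s"].to_numpy(dtype=float)
    t_end = b["t_start"] + pd.to_timedelta(dur, unit="s")
    end_ns = t_end.astype("int64").to_numpy()
    gaps_ns = start_ns[1:] - end_ns[:-1]
    if (gaps_ns < 0).any():
        idx = np.nonzero(gaps_ns < 0)[0]
        raise ValidationError(
            f"animal {stream.animal_id}: overlapping bouts at positions "
            f"{idx.tolist()[:10]} (negative inter-bout gap)"
        )
    thr_ns = int(round(cfg.imi_threshold_s * 1e9))
    cid = np.concatenate([[0], np.cumsum(gaps_ns >= thr_ns)])
    mass = b["mass_g"].to_numpy(dtype=float)

    df = pd.DataFrame(
        {
            "cid": cid,
            "t_first": b["t_start"].to_numpy(),
            "t_last": t_end.to_numpy(),
            "dur": dur,
            "mass": mass,
            "idx": np.arange(len(b)),
        }
    )
    agg = df.groupby("cid").agg(
        t_first=("t_first", "first"),
        t_last=("t_last", "last"),
        n_bouts=("idx", "size"),
        mass_g=("mass", "sum"),
        eating_time_s=("dur", "sum"),
        first_bout=("idx", "first"),
        last_bout=("idx", "last"),
    )
    span_s = (agg["t_last"].astype("int64") - agg["t_first"].astype("int64")) / 1e9
    out = pd.DataFrame(
        {
            "t_first": agg["t_first"],
            "t_last": agg["t_last"],
            "n_bouts": agg["n_bouts"].astype(int),
            "mass_g": agg["mass_g"],
            "size_kcal": agg["mass_g"] * cfg.energy_density_kcal_per_g,
            "eating_time_s": agg["eating_time_s"],
            "span_s": span_s,
            "qualifies": agg["mass_g"] >= cfg.min_meal_mass_g,
            "photoperiod": photoperiods_of(agg["t_first"], cfg),
            "first_bout": agg["first_bout"].astype(int),
            "last_bout": agg["last_bout"].astype(int),
        }
    ).reset_index(drop=True)
    return out


@dataclass
class MealSeries:
    """Segmented meals, subthreshold clusters, and IMIs of one animal.

    ``meals`` holds the qualifying clusters (columns of
    :func:`cluster_bouts` plus ``meal_index``, ``duration_s``,
    ``feeding_rate_kcal_s`` and ``imi_to_next_s``); ``subthreshold`` the
    non-qualifying clusters; ``imis`` one row per interval between
    consecutive qualifying meals (``prev_meal_index``, ``t_start``,
    ``t_end``, ``imi_s``, ``photoperiod`` of the interval start).
    Subthreshold clusters inside an interval do not break it.
    """

    animal_id: str
    meals: pd.DataFrame
    subthreshold: pd.DataFrame
    imis: pd.DataFrame
    config: ProtocolConfig

    @property
    def total_mass_g(self) -> float:
        return float(self.meals["mass_g"].sum() + self.subthreshold["mass_g"].sum())

    @property
    def total_intake_kcal(self) -> float:
        return self.total_mass_g * self.config.energy_density_kcal_per_g


def feeding_rate(size_kcal, duration_s):
    """Feeding rate = meal size / meal duration (kCal/s).

    Zero or negative durations yield NaN (an undefined-rate marker that is
    excluded from averages), never a division error.
    """
    size = np.asarray(size_kcal, dtype=float)
    dur = np.asarray(duration_s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(dur > 0, size / np.where(dur > 0, dur, 1.0), np.nan)
    if np.ndim(size_kcal) == 0 and np.ndim(duration_s) == 0:
        return float(rate) if dur > 0 else float("nan")
    return rate


def segment_meals(stream: BoutStream, cfg: ProtocolConfig) -> MealSeries:
    """Segment a bout stream into qualifying meals, nibbles, and IMIs."""
    clusters = cluster_bouts(stream, cfg)
    if clusters.empty:
        empty_meals = pd.DataFrame(
            columns=CLUSTER_COLUMNS
            + ["meal_index", "duration_s", "feeding_rate_kcal_s", "imi_to_next_s"]
        )
        empty_imis = pd.DataFrame(
            columns=["prev_meal_index", "t_start", "t_end", "imi_s", "photoperiod"]
        )
        return MealSeries(stream.animal_id, empty_meals, clusters.copy(), empty_imis, cfg)

    meals = clusters[clusters["qualifies"]].reset_index(drop=True).copy()
    sub = clusters[~clusters["qualifies"]].reset_index(drop=True).copy()
    meals["meal_index"] = np.arange(len(meals))
    dur_col = "eating_time_s" if cfg.meal_duration_mode == "eating_time" else "span_s"
    meals["duration_s"] = meals[dur_col]
    meals["feeding_rate_kcal_s"] = feeding_rate(
        meals["size_kcal"].to_numpy(), meals["duration_s"].to_numpy()
    )

    if len(meals) >= 2:
        t_end_prev = meals["t_last"].iloc[:-1].reset_index(drop=True)
        t_start_next = meals["t_first"].iloc[1:].reset_index(drop=True)
        imi_s = (t_start_next - t_end_prev).dt.total_seconds()
        imis = pd.DataFrame(
            {
                "prev_meal_index": np.arange(len(meals) - 1),
                "t_start": t_end_prev,
                "t_end": t_start_next,
                "imi_s": imi_s,
                "photoperiod": photoperiods_of(t_end_prev, cfg),
            }
        )
    else:
        imis = pd.DataFrame(
            columns=["prev_meal_index", "t_start", "t_end", "imi_s", "photoperiod"]
        )
    meals["imi_to_next_s"] = (
        imis["imi_s"].reindex(range(len(meals))).to_numpy()
        if len(meals)
        else np.array([], dtype=float)
    )
    return MealSeries(stream.animal_id, meals, sub, imis, cfg)


def meals_table(series: MealSeries) -> pd.DataFrame:
    """Flat meals table in the documented output schema."""
    m = series.meals
    return pd.DataFrame(
        {
            "animal_id": series.animal_id,
            "meal_index": m["meal_index"] if len(m) else pd.Series(dtype=int),
            "t_first": m["t_first"],
            "t_last": m["t_last"],
            "n_bouts": m["n_bouts"],
            "mass_g": m["mass_g"],
            "size_kcal": m["size_kcal"],
            "eating_time_s": m["eating_time_s"],
            "span_s": m["span_s"],
            "qualifies": m["qualifies"],
            "photoperiod": m["photoperiod"],
            "imi_to_next_s": m["imi_to_next_s"],
        }
    )
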