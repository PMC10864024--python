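"""Per-animal satiation/satiety summaries and circadian intake profiles.

Aggregates a segmented :class:`~mealpattern.segmentation.MealSeries` into
the standard meal-pattern readouts, stratified by photoperiod:

* meal frequency (meals per 24-h day, diurnal / nocturnal / daily),
* mean meal size (kCal) — the satiation readout,
* mean intermeal interval (min) — the satiety readout,
* mean eating time per meal (s) and mean feeding rate (kCal/s),
* energy intake (kCal/day), body-weight-adjusted intake (kCal/gBW/day),
  and cumulative intake over the window.

Total intake counts *all* food removed, including subthreshold nibbling
clusters; per-meal statistics are computed over qualifying meals only.
Strata with zero meals report a count of 0 and NaN means (missing, not
zero) so they do not bias group averages of per-meal quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Photoperiod, ProtocolConfig, zeitgeber_time, zeitgeber_hours
from .io import AnimalRecord, BoutStream, mean_body_weight
from .segmentation import MealSeries

__all__ = [
    "MicrostructureSummary",
    "summarize",
    "circadian_profile",
    "cumulative_intake",
    "summary_table",
]

STRATA = ("diurnal", "nocturnal", "daily")

SUMMARY_COLUMNS = [
    "meal_count_per_day",
    "mean_meal_size_kcal",
    "mean_imi_min",
    "mean_eating_time_s",
    "mean_feeding_rate_kcal_s",
    "intake_kcal_per_day",
    "intake_kcal_per_gbw_per_day",
    "cumulative_intake_kcal",
    "n_meals",
    "n_imis",
]


@dataclass
class MicrostructureSummary:
    """Per-animal meal-pattern summary over a time window.

    ``table`` is indexed by stratum ('diurnal', 'nocturnal', 'daily') with
    columns :data:`SUMMARY_COLUMNS`. ``days`` is the window length in 24-h
    days and ``mean_bw_g`` the window-mean body weight used for the
    kCal/gBW normalization.
    """

    animal_id: str
    window: tuple[pd.Timestamp, pd.Timestamp]
    days: float
    mean_bw_g: float
    table: pd.DataFrame

    def stratum(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _nanmean(x) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    return float(x.mean()) if x.size else float("nan")


def summarize(
    series: MealSeries,
    animal: AnimalRecord,
    window: tuple,
    cfg: ProtocolConfig,
) -> MicrostructureSummary:
    """Aggregate one animal's meal series into a stratified summary.

    Meals are assigned to the photoperiod of their first bout; an IMI to
    the photoperiod in which the interval begins. Counts are normalized per
    24-h day of the window, so diurnal + nocturnal frequencies add up to
    the daily frequency exactly.
    """
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    days = (hi - lo).total_seconds() / 86400.0
    if days <= 0:
        raise ValueError("window must have positive length")
    bw = mean_body_weight(animal, (lo, hi))
    ed = cfg.energy_density_kcal_per_g

    meals = series.meals
    meals = meals[(meals["t_first"] >= lo) & (meals["t_first"] < hi)]
    sub = series.subthreshold
    if len(sub):
        sub = sub[(sub["t_first"] >= lo) & (sub["t_first"] < hi)]
    imis = series.imis
    if len(imis):
        imis = imis[(imis["t_start"] >= lo) & (imis["t_start"] < hi)]

    rows = {}
    for stratum in STRATA:
        if stratum == "daily":
            m = meals
            s = sub
            iv = imis
        else:
            m = meals[meals["photoperiod"] == stratum]
            s = sub[sub["photoperiod"] == stratum] if len(sub) else sub
            iv = imis[imis["photoperiod"] == stratum] if len(imis) else imis
        intake_kcal = float(m["mass_g"].sum() + (s["mass_g"].sum() if len(s) else 0.0)) * ed
        rows[stratum] = {
            "meal_count_per_day": len(m) / days,
            "mean_meal_size_kcal": _nanmean(m["size_kcal"]) if len(m) else float("nan"),
            "mean_imi_min": _nanmean(iv["imi_s"]) / 60.0 if len(iv) else float("nan"),
            "mean_eating_time_s": _nanmean(m["eating_time_s"]) if len(m) else float("nan"),
            "mean_feeding_rate_kcal_s": _nanmean(m["feeding_rate_kcal_s"])
            if len(m)
            else float("nan"),
            "intake_kcal_per_day": intake_kcal / days,
            "intake_kcal_per_gbw_per_day": intake_kcal / days / bw,
            "cumulative_intake_kcal": intake_kcal,
            "n_meals": len(m),
            "n_imis": len(iv),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(STRATA), SUMMARY_COLUMNS]
    return MicrostructureSummary(
        animal_id=series.animal_id, window=(lo, hi), days=days, mean_bw_g=bw, table=table
    )


def _bin_coverage_days(window, bin_width_h: float, cfg: ProtocolConfig) -> np.ndarray:
    """How many times (in days) each zeitgeber bin is covered by the window."""
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    n_bins = int(round(24.0 / bin_width_h))
    # continuous hours-since-lights-on axis anchored at the lights-on
    # immediately preceding the window start
    zt0 = zeitgeber_time(lo, cfg)
    total_h = (hi - lo).total_seconds() / 3600.0
    u0 = zt0
    u1 = zt0 + total_h
    cov = np.zeros(n_bins)
    k0 = math.floor(u0 / 24.0)
    k1 = math.ceil(u1 / 24.0)
    for k in range(k0, k1 + 1):
        for j in range(n_bins):
            a = 24.0 * k + j * bin_width_h
            b = a + bin_width_h
            overlap = min(b, u1) - max(a, u0)
            if overlap > 0:
                cov[j] += overlap / bin_width_h
    return cov


def circadian_profile(
    stream: BoutStream,
    animal: AnimalRecord,
    cfg: ProtocolConfig,
    bin_width_h: float = 1.0,
    window: tuple | None = None,
) -> pd.DataFrame:
    """Circadian pattern of energy intake across zeitgeber-time bins.

    All bouts (meals and nibbles alike) are accumulated into zeitgeber bins
    by their start time and averaged across recording days: each bin's
    total is divided by the number of days that bin was actually observed,
    so partial first/last days are weighted correctly. Returns a DataFrame
    with ``zt_bin_left``, ``mean_intake_kcal`` and
    ``mean_intake_kcal_per_gbw`` per bin; bins never observed are NaN.
    """
    if abs((24.0 / bin_width_h) - round(24.0 / bin_width_h)) > 1e-9:
        raise ValueError("bin_width_h must divide 24")
    if window is None:
        window = stream.window
    bw = mean_body_weight(animal, window)
    n_bins = int(round(24.0 / bin_width_h))
    b = stream.bouts
    b = b[(b["t_start"] >= pd.Timestamp(window[0])) & (b["t_start"] < pd.Timestamp(window[1]))]
    totals = np.zeros(n_bins)
    if len(b):
        zt = zeitgeber_hours(b["t_start"], cfg)
        idx = np.minimum((zt / bin_width_h).astype(int), n_bins - 1)
        np.add.at(totals, idx, b["mass_g"].to_numpy() * cfg.energy_density_kcal_per_g)
    cov = _bin_coverage_days(window, bin_width_h, cfg)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_kcal = np.where(cov > 0, totals / np.where(cov > 0, cov, 1.0), np.nan)
    return pd.DataFrame(
        {
            "zt_bin_left": np.arange(n_bins) * bin_width_h,
            "mean_intake_kcal": mean_kcal,
            "mean_intake_kcal_per_gbw": mean_kcal / bw,
            "coverage_days": cov,
        }
    )


def cumulative_intake(stream: BoutStream, cfg: ProtocolConfig) -> pd.DataFrame:
    """Right-continuous cumulative energy intake (kCal) over time.

    Each bout contributes its full caloric content as a step at the bout
    start. The final value equals total window intake.
    """
    b = stream.bouts
    if b.empty:
        return pd.DataFrame({"t": pd.Series(dtype="datetime64[ns]"), "cum_kcal": pd.Series(dtype=float)})
    return pd.DataFrame(
        {
            "t": b["t_start"].reset_index(drop=True),
            "cum_kcal": (b["mass_g"] * cfg.energy_density_kcal_per_g).cumsum().reset_index(drop=True),
        }
    )


def summary_table(summaries: list[MicrostructureSummary]) -> pd.DataFrame:
    """Long-format cohort table: one row per animal x stratum."""
    rows = []
    for s in summaries:
        for stratum in STRATA:
            row = {"animal_id": s.animal_id, "stratum": stratum, "days": s.days, "mean_bw_g": s.mean_bw_g}
            row.update(s.table.loc[stratum].to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
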