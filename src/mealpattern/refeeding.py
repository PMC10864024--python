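"""Fasting-refeeding analysis: body-weight loss/regain and satiety kinetics.

After an overnight fast (default 16:00 to 08:00, a 16-h deprivation), mice
are allowed to refeed and their feeding microstructure is monitored for
24 h. The satiety response is quantified as the time-binned mean intermeal
interval (IMI) expressed relative to the animal's own ad libitum nocturnal
baseline (paired normalization). The canonical response has three
components:

1. *initial suppression* — markedly shortened IMIs (reduced satiety) in the
   first bin(s) after refeeding,
2. *recovery* — a gradual return of the relative IMI to the ad libitum
   baseline, and
3. *late-scotophase overshoot* — IMI lengthening above baseline (increased
   satiety) toward the end of the dark phase.

Meals during refeeding are re-segmented with the identical protocol
configuration used for the ad libitum analysis; the fast itself is never
counted as an IMI (the first post-refeed meal has no preceding interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ProtocolConfig, zeitgeber_time
from .io import AnimalRecord, BoutStream, ValidationError
from .metrics import MicrostructureSummary
from .segmentation import MealSeries, segment_meals

__all__ = [
    "RefeedingProfile",
    "SatietyKinetics",
    "find_fast_window",
    "analyze_refeeding",
    "classify_kinetics",
    "average_profiles",
    "refeed_table",
]


@dataclass
class RefeedingProfile:
    """Per-animal refeeding response.

    ``imi_bins`` has one row per refeed bin: ``bin_left_h``, ``bin_right_h``
    (hours since refeed), ``mean_imi_min``, ``n_imis`` and ``rel_imi``
    (mean IMI divided by the animal's ad libitum nocturnal baseline IMI).
    Bins with no interval are NaN (missing), never zero.
    """

    animal_id: str
    refeed_time: pd.Timestamp
    fast_begin: pd.Timestamp
    baseline_imi_min: float
    imi_bins: pd.DataFrame
    intake_curve: pd.DataFrame
    meal_size_refeed_kcal: float
    config: ProtocolConfig
    bw_prefast_g: float | None = None
    bw_postfast_g: float | None = None
    bw_loss_pct: float | None = None
    bw_series: pd.DataFrame | None = None
    fast_violations: pd.DataFrame | None = None
    meals: MealSeries | None = None


@dataclass
class SatietyKinetics:
    """Three-component classification of a refeeding satiety response."""

    initial_suppression: float
    recovery_time_h: float
    overshoot: bool
    overshoot_magnitude: float
    tolerance: float
    overshoot_margin: float


def find_fast_window(
    stream: BoutStream, cfg: ProtocolConfig, refeed_date=None
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Locate the fast window (fast_start -> next refeed_start) in a stream.

    If ``refeed_date`` (the calendar date of refeeding) is given, the window
    is constructed directly. Otherwise every candidate fast window inside
    the recording window is scored by the number of bouts it contains and
    the first bout-free candidate whose refeed monitoring period fits in
    the recording window is returned.
    """
    lo, hi = stream.window

    def _window_for(refeed_day: pd.Timestamp):
        refeed = refeed_day.normalize() + pd.Timedelta(
            hours=cfg.refeed_start.hour, minutes=cfg.refeed_start.minute
        )
        fast_begin = (refeed_day.normalize() - pd.Timedelta(days=1)) + pd.Timedelta(
            hours=cfg.fast_start.hour, minutes=cfg.fast_start.minute
        )
        return fast_begin, refeed

    if refeed_date is not None:
        return _window_for(pd.Timestamp(refeed_date))

    t = stream.bouts["t_start"]
    best = None
    day = lo.normalize()
    while day <= hi.normalize() + pd.Timedelta(days=1):
        fast_begin, refeed = _window_for(day)
        day += pd.Timedelta(days=1)
        if fast_begin < lo:
            continue
        if refeed + pd.Timedelta(hours=cfg.refeed_monitor_h) > hi + pd.Timedelta(seconds=1):
            continue
        n_inside = int(((t >= fast_begin) & (t < refeed)).sum())
        if n_inside == 0:
            return fast_begin, refeed
        if best is None or n_inside < best[0]:
            best = (n_inside, fast_begin, refeed)
    if best is None:
        raise ValidationError(
            f"animal {stream.animal_id}: recording window cannot contain a "
            "full fast + refeed monitoring period"
        )
    return best[1], best[2]


def _bw_at(animal: AnimalRecord, when: pd.Timestamp, tol_h: float = 1.0) -> float | None:
    if animal is None or animal.body_weight is None or animal.body_weight.empty:
        return None
    bw = animal.body_weight
    dt = (bw["timestamp"] - when).abs()
    i = dt.idxmin()
    if dt.loc[i] <= pd.Timedelta(hours=tol_h):
        return float(bw.loc[i, "bw_g"])
    return None


def analyze_refeeding(
    stream: BoutStream,
    baseline: MicrostructureSummary,
    animal: AnimalRecord,
    cfg: ProtocolConfig,
    refeed_date=None,
) -> RefeedingProfile:
    """Compute a :class:`RefeedingProfile` from a refeeding-day bout stream.

    ``baseline`` must carry a defined nocturnal mean IMI (the animal's own
    ad libitum value); all relative quantities use this paired baseline.
    IMIs are assigned to the 2-h bin containing the interval's *start*.
    Bouts found inside the declared fast window indicate a food-access
    error in the data; they are reported in ``fast_violations`` and a
    warning is raised, but the analysis proceeds.
    """
    fast_begin, refeed = find_fast_window(stream, cfg, refeed_date=refeed_date)
    baseline_imi = float(baseline.table.loc["nocturnal", "mean_imi_min"])
    if not np.isfinite(baseline_imi) or baseline_imi <= 0:
        raise ValidationError(
            f"animal {stream.animal_id}: baseline summary has no defined "
            "nocturnal mean IMI"
        )

    t = stream.bouts["t_start"]
    viol = stream.bouts[(t >= fast_begin) & (t < refeed)]
    if len(viol):
        warnings.warn(
            f"animal {stream.animal_id}: {len(viol)} bouts inside the declared "
            f"fast window [{fast_begin} .. {refeed}] (food-access error)",
            stacklevel=2,
        )

    monitor_end = refeed + pd.Timedelta(hours=cfg.refeed_monitor_h)
    refeed_stream = stream.subset(refeed, monitor_end)
    series = segment_meals(refeed_stream, cfg)
    assert series.config == cfg  # re-segmentation uses the identical thresholds

    n_bins = cfg.n_refeed_bins
    edges = np.arange(n_bins + 1) * cfg.refeed_bin_h
    mean_imi = np.full(n_bins, np.nan)
    n_imis = np.zeros(n_bins, dtype=int)
    if len(series.imis):
        h = (series.imis["t_start"] - refeed).dt.total_seconds().to_numpy() / 3600.0
        which = np.digitize(h, edges) - 1
        ok = (which >= 0) & (which < n_bins)
        for j in range(n_bins):
            vals = series.imis["imi_s"].to_numpy()[ok & (which == j)] / 60.0
            if vals.size:
                mean_imi[j] = vals.mean()
                n_imis[j] = vals.size
    imi_bins = pd.DataFrame(
        {
            "bin_left_h": edges[:-1],
            "bin_right_h": edges[1:],
            "mean_imi_min": mean_imi,
            "n_imis": n_imis,
            "rel_imi": mean_imi / baseline_imi,
        }
    )

    bw_pre = _bw_at(animal, fast_begin)
    bw_post = _bw_at(animal, refeed)
    loss_pct = None
    if bw_pre is None or bw_post is None:
        warnings.warn(
            f"animal {stream.animal_id}: missing prefast or postfast body "
            "weight; BW fields omitted from refeeding profile",
            stacklevel=2,
        )
    else:
        loss_pct = 100.0 * (bw_pre - bw_post) / bw_pre

    bw_series = None
    if animal is not None and animal.body_weight is not None and bw_pre is not None:
        bw = animal.body_weight
        sel = bw[(bw["timestamp"] >= refeed) & (bw["timestamp"] <= monitor_end)]
        if len(sel):
            bw_series = pd.DataFrame(
                {
                    "hours_since_refeed": (sel["timestamp"] - refeed).dt.total_seconds() / 3600.0,
                    "bw_g": sel["bw_g"].to_numpy(),
                    "pct_of_prefast": 100.0 * sel["bw_g"].to_numpy() / bw_pre,
                }
            )

    b = refeed_stream.bouts
    norm_bw = bw_pre if bw_pre is not None else (bw_post or np.nan)
    kcal = (b["mass_g"] * cfg.energy_density_kcal_per_g).cumsum()
    intake_curve = pd.DataFrame(
        {
            "hours_since_refeed": (b["t_start"] - refeed).dt.total_seconds() / 3600.0,
            "cum_kcal": kcal.to_numpy(),
            "cum_kcal_per_gbw": kcal.to_numpy() / norm_bw if norm_bw else np.nan,
        }
    )

    meal_size = float(series.meals["size_kcal"].mean()) if len(series.meals) else float("nan")

    return RefeedingProfile(
        animal_id=stream.animal_id,
        refeed_time=refeed,
        fast_begin=fast_begin,
        baseline_imi_min=baseline_imi,
        imi_bins=imi_bins,
        intake_curve=intake_curve,
        meal_size_refeed_kcal=meal_size,
        config=cfg,
        bw_prefast_g=bw_pre,
        bw_postfast_g=bw_post,
        bw_loss_pct=loss_pct,
        bw_series=bw_series,
        fast_violations=viol.reset_index(drop=True),
        meals=series,
    )


def _late_scotophase_bins(profile: RefeedingProfile, window_h: float) -> np.ndarray:
    """Indices of bins with >=50% overlap with the last ``window_h`` hours
    of the scotophase inside the monitoring period."""
    cfg = profile.config
    zt0 = zeitgeber_time(profile.refeed_time, cfg)
    # scotophase on the ZT axis is [light_hours, 24); find its last end
    # within [0, monitor) hours since refeed
    ends = []
    for k in range(-1, int(cfg.refeed_monitor_h // 24) + 2):
        end_h = 24.0 * k + (24.0 - zt0)  # hours since refeed at which ZT wraps to 0
        if 0 < end_h <= cfg.refeed_monitor_h:
            ends.append(end_h)
    if not ends:
        return np.array([], dtype=int)
    sc_end = max(ends)
    sc_last = (max(sc_end - window_h, 0.0), sc_end)
    left = profile.imi_bins["bin_left_h"].to_numpy()
    right = profile.imi_bins["bin_right_h"].to_numpy()
    overlap = np.minimum(right, sc_last[1]) - np.maximum(left, sc_last[0])
    return np.nonzero(overlap >= 0.5 * (right - left))[0]


def classify_kinetics(
    profile: RefeedingProfile,
    tolerance: float = 0.9,
    overshoot_margin: float | None = None,
    overshoot_window_h: float = 4.0,
) -> SatietyKinetics:
    """Classify a refeeding profile into the three satiety components.

    * ``initial_suppression`` = 1 - relative IMI of the first non-missing
      bin (a fraction; >0.6 corresponds to the canonical strong first-2-h
      response).
    * ``recovery_time_h`` = left edge of the first non-missing bin whose
      relative IMI is at least ``tolerance`` (default 0.9); 0.0 means
      immediate recovery, NaN means never recovered within the window.
    * ``overshoot`` is assessed over the bins covering the last
      ``overshoot_window_h`` hours of the scotophase: the magnitude is the
      mean relative IMI there minus 1, flagged when it exceeds
      ``overshoot_margin`` (default ``1 - tolerance``).

    Deterministic given the profile and parameters.
    """
    if overshoot_margin is None:
        overshoot_margin = 1.0 - tolerance
    rel = profile.imi_bins["rel_imi"].to_numpy(dtype=float)
    left = profile.imi_bins["bin_left_h"].to_numpy(dtype=float)
    ok = np.isfinite(rel)
    if ok.sum() == 0:
        raise ValidationError("all refeed bins are missing; cannot classify")
    if ok.sum() < 2:
        raise ValidationError("need at least 2 non-missing refeed bins to classify")

    first = int(np.nonzero(ok)[0][0])
    suppression = 1.0 - rel[first]

    recovered = ok & (rel >= tolerance)
    if recovered.any():
        j = int(np.nonzero(recovered)[0][0])
        recovery_h = 0.0 if j == first else float(left[j])
    else:
        recovery_h = float("nan")

    sc_bins = _late_scotophase_bins(profile, overshoot_window_h)
    sc_vals = rel[sc_bins] if len(sc_bins) else np.array([])
    sc_vals = sc_vals[np.isfinite(sc_vals)]
    if sc_vals.size:
        magnitude = float(sc_vals.mean() - 1.0)
        overshoot = magnitude > overshoot_margin
    else:
        magnitude = float("nan")
        overshoot = False

    return SatietyKinetics(
        initial_suppression=float(suppression),
        recovery_time_h=recovery_h,
        overshoot=bool(overshoot),
        overshoot_magnitude=magnitude,
        tolerance=tolerance,
        overshoot_margin=overshoot_margin,
    )


def average_profiles(profiles: list[RefeedingProfile]) -> RefeedingProfile:
    """Group-mean refeeding profile (unweighted across animals, as cohort
    figures average mice). Bins missing in an animal are ignored for that
    bin; the pooled ``n_imis`` is the total interval count."""
    if not profiles:
        raise ValueError("no profiles to average")
    ref = profiles[0]
    rels = np.vstack([p.imi_bins["rel_imi"].to_numpy(dtype=float) for p in profiles])
    means = np.vstack([p.imi_bins["mean_imi_min"].to_numpy(dtype=float) for p in profiles])
    ns = np.vstack([p.imi_bins["n_imis"].to_numpy() for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rel_mean = np.nanmean(rels, axis=0)
        imi_mean = np.nanmean(means, axis=0)
    bins = ref.imi_bins.copy()
    bins["mean_imi_min"] = imi_mean
    bins["n_imis"] = ns.sum(axis=0)
    bins["rel_imi"] = rel_mean
    return RefeedingProfile(
        animal_id="pooled",
        refeed_time=ref.refeed_time,
        fast_begin=ref.fast_begin,
        baseline_imi_min=float(np.mean([p.baseline_imi_min for p in profiles])),
        imi_bins=bins,
        intake_curve=ref.intake_curve.iloc[0:0],
        meal_size_refeed_kcal=float(
            np.nanmean([p.meal_size_refeed_kcal for p in profiles])
        ),
        config=ref.config,
    )


def refeed_table(profile: RefeedingProfile, kinetics: SatietyKinetics | None = None) -> pd.DataFrame:
    """Flat per-bin report with BW and kinetics columns repeated per row."""
    df = profile.imi_bins.copy()
    df.insert(0, "animal_id", profile.animal_id)
    df["baseline_imi_min"] = profile.baseline_imi_min
    df["bw_prefast_g"] = profile.bw_prefast_g
    df["bw_postfast_g"] = profile.bw_postfast_g
    df["bw_loss_pct"] = profile.bw_loss_pct
    df["meal_size_refeed_kcal"] = profile.meal_size_refeed_kcal
    if kinetics is not None:
        df["initial_suppression"] = kinetics.initial_suppression
        df["recovery_time_h"] = kinetics.recovery_time_h
        df["overshoot"] = kinetics.overshoot
        df["overshoot_magnitude"] = kinetics.overshoot_magnitude
    return df
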