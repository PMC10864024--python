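"""Synthetic bout-stream generator with ground truth.

Emulates a home-cage feeding monitor's event stream as an alternating
renewal process per animal: an intermeal interval (IMI) is drawn from a
photoperiod-specific gamma distribution at the current clock time, then a
meal is emitted as a cluster of bouts — a gamma meal size split across
1 + Poisson bouts, with truncated-exponential within-meal gaps and bout
durations set by a constant intake rate. Isolated subthreshold "nibble"
bouts are superposed. Circadian modulation is two-stratum (distinct
diurnal/nocturnal parameter sets), matching how meal-pattern studies report
their data; there is no continuous oscillator.

Calibration anchors: the nocturnal IMI scale (~70 min) matches the
published ad libitum value for adult male mice; the meal-size and
meals-per-day scales are set so a default animal eats ~12 meals and
~12 kCal per day (~0.4 kCal/gBW/day at 30 g). The diurnal IMI scale is not
anchored by any published value and defaults to 3x the nocturnal scale.

In *recoverable* mode (the default) the generator constructively
guarantees that segmentation can recover the truth table exactly:
between-meal gaps >= the IMI threshold, within-meal gaps strictly below
it, meal masses >= the minimum meal size, and nibbles placed with at
least a threshold of clearance on both sides.

A scripted fasting/refeeding episode can be appended: the fast window is
bout-free by construction and post-refeed IMIs are drawn with a
three-component multiplier curve (initial suppression, linear recovery,
late-scotophase overshoot) applied to the nocturnal baseline mean.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import Photoperiod, ProtocolConfig, photoperiod_of, zeitgeber_time
from .io import AnimalRecord, BoutStream, MealPatternError

__all__ = [
    "ConfigurationError",
    "RefeedScenario",
    "GeneratorSpec",
    "SyntheticGroundTruth",
    "simulate",
    "simulate_refeed",
    "preset_cohort",
]

EPOCH = pd.Timestamp("2024-01-01")  # arbitrary fixed anchor date


class ConfigurationError(MealPatternError):
    """Generator spec is internally inconsistent or incompatible with cfg."""


@dataclass(frozen=True)
class RefeedScenario:
    """Injected three-component satiety response to refeeding.

    ``suppression`` is the fractional IMI shortening in the first 2 h
    (0.7 = IMIs at 30% of baseline); ``recovery_h`` the hour (since
    refeeding) at which the linear ramp reaches baseline; the multiplier
    equals ``overshoot_frac`` during the last ``overshoot_span_h`` hours of
    the scotophase (1.0 = no overshoot). ``imi_shape`` is the gamma shape of
    post-refeed IMIs: refeeding behavior is strongly entrained, so the
    default dispersion (CV 20%) is tighter than ad libitum.
    """

    suppression: float = 0.7
    recovery_h: float = 7.0
    overshoot_frac: float = 1.25
    overshoot_span_h: float = 4.0
    imi_shape: float = 25.0
    first_meal_latency_mean_s: float = 120.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.suppression < 1.0:
            raise ConfigurationError("suppression must be in [0, 1)")
        if self.recovery_h <= 2.0:
            raise ConfigurationError("recovery_h must exceed the first 2-h bin")
        if self.overshoot_frac <= 0:
            raise ConfigurationError("overshoot_frac must be positive")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic cohort; the seed fully determines output."""

    seed: int = 0
    n_animals: int = 10
    days: int = 14
    nocturnal_imi_mean_min: float = 70.0
    nocturnal_imi_shape: float = 4.0
    diurnal_imi_mean_min: float = 210.0
    diurnal_imi_shape: float = 4.0
    meal_size_mean_kcal: float = 0.8
    meal_size_shape: float = 6.0
    extra_bouts_mean: float = 3.0
    within_gap_mean_s: float = 60.0
    intake_rate_kcal_s: float = 0.0015
    nibble_rate_per_day: float = 5.0
    nibble_mass_range_g: tuple = (0.005, 0.045)
    recoverable: bool = True
    genotype: str = "control"
    sex: str = "male"
    age_weeks: int = 10
    bw_initial_g: float = 30.0
    bw_subject_sd_g: float = 1.5
    bw_drift_g_per_day: float = 0.03
    fast_loss_frac: float = 0.10
    regain_days: float = 2.0
    refeed: RefeedScenario | None = None

    def __post_init__(self) -> None:
        for name in (
            "nocturnal_imi_mean_min",
            "nocturnal_imi_shape",
            "diurnal_imi_mean_min",
            "diurnal_imi_shape",
            "meal_size_mean_kcal",
            "meal_size_shape",
            "within_gap_mean_s",
            "intake_rate_kcal_s",
            "bw_initial_g",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.extra_bouts_mean < 0 or self.nibble_rate_per_day < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.n_animals < 1 or self.days < 1:
            raise ConfigurationError("n_animals and days must be >= 1")


@dataclass
class SyntheticGroundTruth:
    """True meal/IMI/nibble tables against which segmentation is scored."""

    true_meals: pd.DataFrame
    true_imis: pd.DataFrame
    nibbles: pd.DataFrame
    spec: GeneratorSpec
    extras: dict = field(default_factory=dict)


def _validate(spec: GeneratorSpec, cfg: ProtocolConfig) -> None:
    if spec.recoverable:
        mean_mass = spec.meal_size_mean_kcal / cfg.energy_density_kcal_per_g
        if mean_mass < cfg.min_meal_mass_g:
            raise ConfigurationError(
                "recoverable mode requires mean meal mass >= min_meal_mass_g "
                f"({mean_mass:.3f} g < {cfg.min_meal_mass_g} g)"
            )
        if spec.within_gap_mean_s >= cfg.imi_threshold_s:
            raise ConfigurationError(
                "recoverable mode requires within_gap_mean_s below the IMI threshold"
            )
        lo, hi = spec.nibble_mass_range_g
        if hi >= cfg.min_meal_mass_g:
            raise ConfigurationError(
                "nibble masses must stay below min_meal_mass_g in recoverable mode"
            )


def _gamma(rng, mean: float, shape: float) -> float:
    return float(rng.gamma(shape, mean / shape))


def _trunc_exp(rng, mean: float, hi: float, size: int) -> np.ndarray:
    """Exponential(mean) truncated to (0, hi) via inverse CDF."""
    u = rng.random(size)
    return -mean * np.log1p(-u * (1.0 - math.exp(-hi / mean)))


class _AnimalSim:
    """Stateful single-animal bout emitter (seconds since window start)."""

    def __init__(self, rng, spec: GeneratorSpec, cfg: ProtocolConfig, t0: pd.Timestamp):
        self.rng = rng
        self.spec = spec
        self.cfg = cfg
        self.t0 = t0
        self.bout_rows: list[tuple] = []  # (t_s, dur_s, mass_g)
        self.meal_rows: list[dict] = []
        self.imi_rows: list[dict] = []
        self.occupied: list[tuple] = []  # sorted (start_s, end_s) of meals/nibbles

    def _draw_imi(self, at_s: float) -> float:
        pp = photoperiod_of(self.t0 + pd.Timedelta(seconds=at_s), self.cfg)
        if pp is Photoperiod.NOCTURNAL:
            mean, shape = self.spec.nocturnal_imi_mean_min * 60.0, self.spec.nocturnal_imi_shape
        else:
            mean, shape = self.spec.diurnal_imi_mean_min * 60.0, self.spec.diurnal_imi_shape
        imi = _gamma(self.rng, mean, shape)
        if self.spec.recoverable:
            # 1 us guard: emitted timestamps are nanosecond-quantized, so a
            # gap must clear the threshold with margin to stay separating
            while imi < self.cfg.imi_threshold_s + 1e-6:
                imi = _gamma(self.rng, mean, shape)
        return imi

    def _draw_meal_bouts(self, t_first_s: float):
        """Returns (starts, durs, masses, end_s) of one meal's bouts."""
        rng, spec, cfg = self.rng, self.spec, self.cfg
        size = _gamma(rng, spec.meal_size_mean_kcal, spec.meal_size_shape)
        mass = size / cfg.energy_density_kcal_per_g
        if spec.recoverable:
            while mass < cfg.min_meal_mass_g:
                size = _gamma(rng, spec.meal_size_mean_kcal, spec.meal_size_shape)
                mass = size / cfg.energy_density_kcal_per_g
        n_b = 1 + int(rng.poisson(spec.extra_bouts_mean))
        fracs = rng.dirichlet(np.full(n_b, 2.0))
        masses = mass * fracs
        durs = masses * cfg.energy_density_kcal_per_g / spec.intake_rate_kcal_s
        gap_hi = min(0.9 * cfg.imi_threshold_s, cfg.imi_threshold_s - 1.0)
        gaps = _trunc_exp(rng, spec.within_gap_mean_s, gap_hi, n_b - 1)
        starts = np.empty(n_b)
        starts[0] = t_first_s
        for i in range(1, n_b):
            starts[i] = starts[i - 1] + durs[i - 1] + gaps[i - 1]
        return starts, durs, masses, float(starts[-1] + durs[-1])

    def emit_meals(self, from_s: float, until_s: float, imi_fn=None, first_gap_s=None):
        """Alternating renewal from ``from_s``; meals must end by ``until_s``.

        ``imi_fn(at_s)`` overrides the IMI draw (used for refeed curves);
        ``first_gap_s`` overrides the initial latency (not a true IMI).
        Returns the number of meals emitted.
        """
        t = from_s
        n_before = len(self.meal_rows)
        first = True
        while True:
            if first and first_gap_s is not None:
                gap = first_gap_s
            elif imi_fn is not None:
                gap = imi_fn(t)
            else:
                gap = self._draw_imi(t)
            t_first = t + gap
            starts, durs, masses, end_s = self._draw_meal_bouts(t_first)
            if end_s > until_s:
                break
            idx = len(self.meal_rows)
            if not first and idx > 0 and self.meal_rows[idx - 1]["_end_s"] == t:
                # gap follows a real meal: record it as a true IMI
                self.imi_rows.append(
                    {
                        "prev_meal_index": self.meal_rows[idx - 1]["meal_index"],
                        "imi_s": gap,
                        "photoperiod": photoperiod_of(
                            self.t0 + pd.Timedelta(seconds=t), self.cfg
                        ).value,
                    }
                )
            for s, d, m in zip(starts, durs, masses):
                self.bout_rows.append((s, d, m))
            self.meal_rows.append(
                {
                    "meal_index": idx,
                    "_start_s": t_first,
                    "_end_s": end_s,
                    "n_bouts": len(starts),
                    "mass_g": float(masses.sum()),
                    "eating_time_s": float(durs.sum()),
                    "span_s": end_s - t_first,
                    "photoperiod": photoperiod_of(
                        self.t0 + pd.Timedelta(seconds=t_first), self.cfg
                    ).value,
                }
            )
            insort(self.occupied, (t_first, end_s))
            t = end_s
            first = False
        return len(self.meal_rows) - n_before

    def superpose_nibbles(self, lo_s: float, hi_s: float) -> list[dict]:
        rng, spec, cfg = self.rng, self.spec, self.cfg
        days = (hi_s - lo_s) / 86400.0
        n = int(rng.poisson(spec.nibble_rate_per_day * days))
        margin = cfg.imi_threshold_s + 1.0
        out = []
        for _ in range(n):
            mass = float(rng.uniform(*spec.nibble_mass_range_g))
            dur = mass * cfg.energy_density_kcal_per_g / spec.intake_rate_kcal_s
            placed = False
            for _try in range(200):
                t = float(rng.uniform(lo_s, hi_s - dur))
                if not spec.recoverable:
                    placed = True
                    break
                j = bisect_left(self.occupied, (t, t))
                ok_prev = j == 0 or t - self.occupied[j - 1][1] >= margin
                ok_next = j == len(self.occupied) or self.occupied[j][0] - (t + dur) >= margin
                if ok_prev and ok_next:
                    placed = True
                    break
            if placed:
                self.bout_rows.append((t, dur, mass))
                insort(self.occupied, (t, t + dur))
                out.append({"t_start_s": t, "duration_s": dur, "mass_g": mass})
        return out

    def to_stream(self, animal: AnimalRecord, window) -> BoutStream:
        rows = sorted(self.bout_rows)
        bouts = pd.DataFrame(
            {
                "t_start": [self.t0 + pd.Timedelta(seconds=s) for s, _, _ in rows],
                "duration_s": [d for _, d, _ in rows],
                "mass_g": [m for _, _, m in rows],
            }
        )
        return BoutStream(animal_id=animal.animal_id, bouts=bouts, window=window, animal=animal)

    def truth_frames(self, animal_id: str):
        meals = pd.DataFrame(self.meal_rows)
        if len(meals):
            meals["t_first"] = self.t0 + pd.to_timedelta(meals.pop("_start_s"), unit="s")
            meals["t_last"] = self.t0 + pd.to_timedelta(meals.pop("_end_s"), unit="s")
            meals.insert(0, "animal_id", animal_id)
        imis = pd.DataFrame(self.imi_rows)
        if len(imis):
            imis.insert(0, "animal_id", animal_id)
        return meals, imis


def _bw_record(rng, spec: GeneratorSpec, t0: pd.Timestamp, days: int, animal_id: str) -> AnimalRecord:
    initial = spec.bw_initial_g + float(rng.normal(0.0, spec.bw_subject_sd_g))
    ts = [t0 + pd.Timedelta(days=k) for k in range(days + 1)]
    w = [initial + spec.bw_drift_g_per_day * k for k in range(days + 1)]
    return AnimalRecord(
        animal_id=animal_id,
        genotype=spec.genotype,
        sex=spec.sex,
        age_weeks=spec.age_weeks,
        body_weight=pd.DataFrame({"timestamp": ts, "bw_g": w}),
    )


def simulate(
    spec: GeneratorSpec, cfg: ProtocolConfig
) -> tuple[dict[str, BoutStream], SyntheticGroundTruth]:
    """Generate an ad libitum cohort of bout streams with ground truth.

    The recording window starts at lights-on (zeitgeber 0) of a fixed
    anchor date and lasts ``spec.days`` days. Identical seed and spec give
    bit-identical output; animals use independent spawned substreams.
    """
    _validate(spec, cfg)
    t0 = EPOCH.normalize() + pd.Timedelta(
        hours=cfg.lights_on.hour, minutes=cfg.lights_on.minute
    )
    window = (t0, t0 + pd.Timedelta(days=spec.days))
    total_s = spec.days * 86400.0

    children = np.random.SeedSequence(spec.seed).spawn(spec.n_animals)
    streams: dict[str, BoutStream] = {}
    all_meals, all_imis, all_nibbles = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        aid = f"A{i + 1:02d}"
        animal = _bw_record(rng, spec, t0, spec.days, aid)
        sim = _AnimalSim(rng, spec, cfg, t0)
        sim.emit_meals(0.0, total_s)
        nibbles = sim.superpose_nibbles(0.0, total_s)
        streams[aid] = sim.to_stream(animal, window)
        meals, imis = sim.truth_frames(aid)
        all_meals.append(meals)
        all_imis.append(imis)
        for row in nibbles:
            row["animal_id"] = aid
        all_nibbles.extend(nibbles)

    def _cat(frames):
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    true_meals = _cat(all_meals)
    if len(true_meals):
        true_meals["size_kcal"] = true_meals["mass_g"] * cfg.energy_density_kcal_per_g
    truth = SyntheticGroundTruth(
        true_meals=true_meals,
        true_imis=_cat(all_imis),
        nibbles=pd.DataFrame(all_nibbles),
        spec=spec,
    )
    return streams, truth


def _scotophase_end_h(refeed_time: pd.Timestamp, monitor_h: float, cfg: ProtocolConfig) -> float:
    zt0 = zeitgeber_time(refeed_time, cfg)
    ends = [
        24.0 * k + (24.0 - zt0)
        for k in range(-1, int(monitor_h // 24) + 2)
        if 0 < 24.0 * k + (24.0 - zt0) <= monitor_h
    ]
    return max(ends) if ends else float("nan")


def _multiplier(h: float, sc: RefeedScenario, sc_end_h: float) -> float:
    if h < 2.0:
        m = 1.0 - sc.suppression
    elif h < sc.recovery_h:
        m = (1.0 - sc.suppression) + sc.suppression * (h - 2.0) / (sc.recovery_h - 2.0)
    else:
        m = 1.0
    if np.isfinite(sc_end_h) and sc_end_h - sc.overshoot_span_h <= h < sc_end_h:
        m = sc.overshoot_frac
    return m


def simulate_refeed(
    spec: GeneratorSpec, cfg: ProtocolConfig
) -> tuple[BoutStream, SyntheticGroundTruth]:
    """Generate one animal's stream with baseline, scripted fast, and refeed.

    Timeline: ``spec.days`` ad libitum days from lights-on, a bout-free
    fast from ``cfg.fast_start`` of the last baseline day to
    ``cfg.refeed_start`` next morning, then ``cfg.refeed_monitor_h`` hours
    of refeeding in which IMIs are drawn from the nocturnal baseline
    distribution scaled by the injected three-component multiplier curve.
    """
    if spec.refeed is None:
        raise ConfigurationError("spec.refeed scenario is required for simulate_refeed")
    _validate(spec, cfg)
    sc = spec.refeed
    t0 = EPOCH.normalize() + pd.Timedelta(
        hours=cfg.lights_on.hour, minutes=cfg.lights_on.minute
    )
    day0 = t0.normalize()
    fast_begin = day0 + pd.Timedelta(days=spec.days) + pd.Timedelta(
        hours=cfg.fast_start.hour, minutes=cfg.fast_start.minute
    )
    refeed = day0 + pd.Timedelta(days=spec.days + 1) + pd.Timedelta(
        hours=cfg.refeed_start.hour, minutes=cfg.refeed_start.minute
    )
    if refeed <= fast_begin:
        raise ConfigurationError("refeed_start must fall after fast_start overnight")
    monitor_end = refeed + pd.Timedelta(hours=cfg.refeed_monitor_h)
    window = (t0, monitor_end)
    fast_begin_s = (fast_begin - t0).total_seconds()
    refeed_s = (refeed - t0).total_seconds()
    monitor_end_s = (monitor_end - t0).total_seconds()

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    aid = "RF01"
    sim = _AnimalSim(rng, spec, cfg, t0)
    n_baseline = sim.emit_meals(0.0, fast_begin_s)
    nibbles = sim.superpose_nibbles(0.0, max(fast_begin_s - cfg.imi_threshold_s - 1.0, 0.0))

    sc_end_h = _scotophase_end_h(refeed, cfg.refeed_monitor_h, cfg)
    base_mean_s = spec.nocturnal_imi_mean_min * 60.0

    def refeed_imi(at_s: float) -> float:
        h = (at_s - refeed_s) / 3600.0
        mean = base_mean_s * _multiplier(h, sc, sc_end_h)
        imi = _gamma(rng, mean, sc.imi_shape)
        if spec.recoverable:
            while imi < cfg.imi_threshold_s + 1e-6:
                imi = _gamma(rng, mean, sc.imi_shape)
        return imi

    latency = float(
        _trunc_exp(rng, sc.first_meal_latency_mean_s, 4.0 * sc.first_meal_latency_mean_s, 1)[0]
    )
    sim.emit_meals(refeed_s, monitor_end_s, imi_fn=refeed_imi, first_gap_s=latency)

    # body weight: daily baseline, prefast/postfast anchors, linear regain
    initial = spec.bw_initial_g + float(rng.normal(0.0, spec.bw_subject_sd_g))
    rows = [(t0 + pd.Timedelta(days=k), initial + spec.bw_drift_g_per_day * k)
            for k in range(spec.days)]
    prefast = initial + spec.bw_drift_g_per_day * spec.days
    postfast = prefast * (1.0 - spec.fast_loss_frac)
    rows.append((fast_begin, prefast))
    rows.append((refeed, postfast))
    for h in (6.0, 12.0, 18.0, 24.0):
        frac = min(h / (24.0 * spec.regain_days), 1.0)
        rows.append((refeed + pd.Timedelta(hours=h), postfast + (prefast - postfast) * frac))
    animal = AnimalRecord(
        animal_id=aid,
        genotype=spec.genotype,
        sex=spec.sex,
        age_weeks=spec.age_weeks,
        body_weight=pd.DataFrame(rows, columns=["timestamp", "bw_g"]),
    )

    stream = sim.to_stream(animal, window)
    meals, imis = sim.truth_frames(aid)
    if len(meals):
        meals["size_kcal"] = meals["mass_g"] * cfg.energy_density_kcal_per_g
    nib = pd.DataFrame(nibbles)
    if len(nib):
        nib["animal_id"] = aid
    truth = SyntheticGroundTruth(
        true_meals=meals,
        true_imis=imis,
        nibbles=nib,
        spec=spec,
        extras={
            "suppression": sc.suppression,
            "recovery_h": sc.recovery_h,
            "overshoot_frac": sc.overshoot_frac,
            "overshoot_window_h": (sc_end_h - sc.overshoot_span_h, sc_end_h),
            "fast_begin": fast_begin,
            "refeed_time": refeed,
            "n_baseline_meals": n_baseline,
            "baseline_imi_mean_min": spec.nocturnal_imi_mean_min,
        },
    )
    return stream, truth


def preset_cohort(seed: int = 0) -> dict[tuple, GeneratorSpec]:
    """Qualitative presets for the six cohort cells per sex
    (genotype x age 10/20/30 wk): knockouts eat larger, fewer meals with an
    unchanged ad libitum IMI; older mice eat larger meals. Calibration is
    qualitative (scales only), not a ground-truth reconstruction of any
    published cohort."""
    cells = {}
    k = 0
    for sex in ("male", "female"):
        for genotype in ("control", "knockout"):
            for age in (10, 20, 30):
                size = 0.8
                diurnal = 210.0
                if genotype == "knockout":
                    size *= 1.3
                    diurnal *= 1.2
                if age >= 30:
                    size *= 1.2
                if sex == "female":
                    size *= 0.9
                cells[(genotype, sex, age)] = GeneratorSpec(
                    seed=seed + k,
                    genotype=genotype,
                    sex=sex,
                    age_weeks=age,
                    meal_size_mean_kcal=size,
                    diurnal_imi_mean_min=diurnal,
                    bw_initial_g=25.0 if sex == "female" else 30.0,
                )
                k += 1
    return cells
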