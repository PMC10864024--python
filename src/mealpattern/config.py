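"""Protocol configuration and circadian time conventions.

The experimental protocol is parameterized by a small set of operational
constants: the intermeal-interval (IMI) threshold that separates bout
clusters into distinct meals, the minimum mass for a cluster to count as a
meal, the caloric density of the diet, the light schedule, and the
fasting/refeeding clock times. Every other module takes a
:class:`ProtocolConfig` so that thresholds have a single source of truth.

Time conventions
----------------
Zeitgeber time (ZT) is hours elapsed since the most recent lights-on
(ZT 0 = lights-on). With the default 06:30/18:30 schedule the photophase
(diurnal period) is ZT [0, 12) and the scotophase (nocturnal period) is
ZT [12, 24). Light transitions use half-open intervals so the two
photoperiods partition the day exactly. Days for daily metrics start at
lights-on, matching the circadian axis used for intake profiles.
"""

from __future__ import annotations

import datetime as _dt
import enum
import hashlib
import json
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Photoperiod",
    "ProtocolConfig",
    "zeitgeber_time",
    "zeitgeber_hours",
    "photoperiod_of",
    "photoperiods_of",
]

_MIN_PER_DAY = 24 * 60


class Photoperiod(str, enum.Enum):
    """Light-cycle stratum of an event or interval."""

    DIURNAL = "diurnal"
    NOCTURNAL = "nocturnal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _parse_clock(value) -> _dt.time:
    if isinstance(value, _dt.time):
        return value
    if isinstance(value, str):
        hh, mm = value.split(":")[:2]
        return _dt.time(int(hh), int(mm))
    raise TypeError(f"cannot interpret {value!r} as a clock time")


def _clock_minutes(t: _dt.time) -> float:
    return t.hour * 60 + t.minute + t.second / 60.0


@dataclass(frozen=True)
class ProtocolConfig:
    """Fixed operational parameters of the feeding-microstructure protocol.

    Parameters
    ----------
    imi_threshold_s
        Minimum intermeal interval in seconds. Bout gaps shorter than this
        belong to the same meal; gaps at least this long separate meals.
        Default 300 s (5 min).
    min_meal_mass_g
        Minimum total cluster mass (grams) for a cluster to qualify as a
        meal. Default 0.050 g. No maximum meal size is imposed.
    energy_density_kcal_per_g
        Caloric density of the diet; default 3.0 kCal/g (standard chow).
    lights_on, lights_off
        Clock times of the light transitions; default 06:30 / 18:30
        (12:12 schedule).
    recording_days
        Nominal length of the ad libitum recording window (days).
    fast_start, refeed_start
        Clock times bracketing the overnight fast (default 16:00 on the
        fast day to 08:00 the next morning, i.e. a 16-h fast).
    refeed_monitor_h, refeed_bin_h
        Duration of the post-refeed monitoring window and of the IMI
        binning grid within it (default 24 h in 2-h bins).
    meal_duration_mode
        Which quantity is reported as "meal duration": ``"eating_time"``
        (sum of member bout durations, the default) or ``"span"`` (first
        bout start to last bout end).
    """

    imi_threshold_s: float = 300.0
    min_meal_mass_g: float = 0.050
    energy_density_kcal_per_g: float = 3.0
    lights_on: _dt.time = _dt.time(6, 30)
    lights_off: _dt.time = _dt.time(18, 30)
    recording_days: int = 14
    fast_start: _dt.time = _dt.time(16, 0)
    refeed_start: _dt.time = _dt.time(8, 0)
    refeed_monitor_h: float = 24.0
    refeed_bin_h: float = 2.0
    meal_duration_mode: str = "eating_time"

    def __post_init__(self) -> None:
        object.__setattr__(self, "lights_on", _parse_clock(self.lights_on))
        object.__setattr__(self, "lights_off", _parse_clock(self.lights_off))
        object.__setattr__(self, "fast_start", _parse_clock(self.fast_start))
        object.__setattr__(self, "refeed_start", _parse_clock(self.refeed_start))
        if self.imi_threshold_s <= 0:
            raise ValueError("imi_threshold_s must be positive")
        if self.min_meal_mass_g < 0:
            raise ValueError("min_meal_mass_g must be non-negative")
        if self.energy_density_kcal_per_g <= 0:
            raise ValueError("energy_density_kcal_per_g must be positive")
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")
        if self.refeed_monitor_h <= 0 or self.refeed_bin_h <= 0:
            raise ValueError("refeed window and bin must be positive")
        ratio = self.refeed_monitor_h / self.refeed_bin_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("refeed_monitor_h must be a multiple of refeed_bin_h")
        if self.meal_duration_mode not in ("eating_time", "span"):
            raise ValueError("meal_duration_mode must be 'eating_time' or 'span'")

    # -- photoperiod geometry -------------------------------------------------

    @property
    def light_hours(self) -> float:
        """Length of the photophase in hours (12.0 for the default schedule)."""
        on = _clock_minutes(self.lights_on)
        off = _clock_minutes(self.lights_off)
        return ((off - on) % _MIN_PER_DAY) / 60.0

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.light_hours

    @property
    def n_refeed_bins(self) -> int:
        return int(round(self.refeed_monitor_h / self.refeed_bin_h))

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.strftime("%H:%M") if isinstance(v, _dt.time) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_id(self) -> str:
        """Short stable hash of the config, embedded in output tables."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def with_overrides(self, **kwargs) -> "ProtocolConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def zeitgeber_time(t, cfg: ProtocolConfig) -> float:
    """Hours since the most recent lights-on, in [0, 24).

    Continuous across midnight: ZT is a function of clock time alone.
    """
    ts = pd.Timestamp(t)
    minutes = _clock_minutes(_dt.time(ts.hour, ts.minute, ts.second)) + ts.microsecond / 60e6
    zt_min = (minutes - _clock_minutes(cfg.lights_on)) % _MIN_PER_DAY
    return zt_min / 60.0


def zeitgeber_hours(times, cfg: ProtocolConfig) -> np.ndarray:
    """Vectorized :func:`zeitgeber_time` over an array of timestamps."""
    idx = pd.DatetimeIndex(times)
    minutes = (
        idx.hour * 60.0
        + idx.minute
        + idx.second / 60.0
        + idx.microsecond / 60e6
    )
    zt_min = (minutes - _clock_minutes(cfg.lights_on)) % _MIN_PER_DAY
    return np.asarray(zt_min / 60.0)


def photoperiod_of(t, cfg: ProtocolConfig) -> Photoperiod:
    """Photoperiod label of an instant (half-open [lights_on, lights_off))."""
    zt = zeitgeber_time(t, cfg)
    return Photoperiod.DIURNAL if zt < cfg.light_hours else Photoperiod.NOCTURNAL


def photoperiods_of(times, cfg: ProtocolConfig) -> np.ndarray:
    """Vectorized photoperiod labels (array of 'diurnal'/'nocturnal' strings)."""
    zt = zeitgeber_hours(times, cfg)
    return np.where(zt < cfg.light_hours, Photoperiod.DIURNAL.value, Photoperiod.NOCTURNAL.value)
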