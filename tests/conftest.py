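import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mealpattern import AnimalRecord, BoutStream, GeneratorSpec, ProtocolConfig, simulate

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")

BASE = pd.Timestamp("2024-01-01 06:30")  # lights-on of an arbitrary day


@pytest.fixture(scope="session")
def cfg() -> ProtocolConfig:
    return ProtocolConfig()


def build_stream(offsets_s, durations_s, masses_g, base=BASE, window_days=14, animal=None):
    """Construct a BoutStream from offsets (seconds since lights-on)."""
    bouts = pd.DataFrame(
        {
            "t_start": [base + pd.Timedelta(seconds=float(s)) for s in offsets_s],
            "duration_s": np.asarray(durations_s, dtype=float),
            "mass_g": np.asarray(masses_g, dtype=float),
        }
    )
    return BoutStream(
        animal_id="T01",
        bouts=bouts,
        window=(base, base + pd.Timedelta(days=window_days)),
        animal=animal,
    )


@pytest.fixture
def make_stream():
    return build_stream


@pytest.fixture
def simple_animal():
    return AnimalRecord(
        animal_id="T01",
        body_weight=pd.DataFrame(
            {"timestamp": [BASE, BASE + pd.Timedelta(days=14)], "bw_g": [30.0, 30.0]}
        ),
    )


@pytest.fixture(scope="session")
def small_cohort(cfg):
    """3 animals x 3 days, recoverable mode with nibbles."""
    spec = GeneratorSpec(seed=42, n_animals=3, days=3)
    return simulate(spec, cfg)
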