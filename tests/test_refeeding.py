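import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mealpattern import (
    GeneratorSpec,
    ProtocolConfig,
    RefeedScenario,
    RefeedingProfile,
    ValidationError,
    analyze_refeeding,
    average_profiles,
    classify_kinetics,
    find_fast_window,
    segment_meals,
    simulate_refeed,
    summarize,
)

REFEED = pd.Timestamp("2024-01-16 08:00")


def make_profile(rel, cfg, baseline_min=70.0):
    """Build a profile directly from relative-IMI bin values (NaN = missing)."""
    rel = np.asarray(rel, dtype=float)
    edges = np.arange(len(rel) + 1) * cfg.refeed_bin_h
    bins = pd.DataFrame(
        {
            "bin_left_h": edges[:-1],
            "bin_right_h": edges[1:],
            "mean_imi_min": rel * baseline_min,
            "n_imis": np.where(np.isfinite(rel), 3, 0),
            "rel_imi": rel,
        }
    )
    return RefeedingProfile(
        animal_id="P01",
        refeed_time=REFEED,
        fast_begin=REFEED - pd.Timedelta(hours=16),
        baseline_imi_min=baseline_min,
        imi_bins=bins,
        intake_curve=pd.DataFrame(),
        meal_size_refeed_kcal=0.8,
        config=cfg,
    )


def test_flat_profile_is_null_response(cfg):
    kin = classify_kinetics(make_profile([1.0] * 12, cfg))
    assert kin.initial_suppression == pytest.approx(0.0)
    assert kin.recovery_time_h == 0.0
    assert not kin.overshoot


def test_step_profile(cfg):
    """0.4 in bins 1-3 then 1.0: suppression 0.6, recovery in the 6-8 h bin."""
    rel = [0.4, 0.4, 0.4] + [1.0] * 9
    kin = classify_kinetics(make_profile(rel, cfg))
    assert kin.initial_suppression == pytest.approx(0.6)
    assert kin.recovery_time_h == pytest.approx(6.0)
    assert not kin.overshoot


def test_first_bin_suppression_example(cfg):
    """Baseline 70 min, first-bin mean 21 min -> relative 0.30, suppression 0.70."""
    rel = [21.0 / 70.0] + [1.0] * 11
    profile = make_profile(rel, cfg)
    assert profile.imi_bins.loc[0, "rel_imi"] == pytest.approx(0.30)
    kin = classify_kinetics(profile)
    assert kin.initial_suppression == pytest.approx(0.70)
    assert kin.initial_suppression > 0.60  # the canonical strong first-2-h response


def test_overshoot_detected_in_late_scotophase(cfg):
    """Refeed at 08:00: scotophase ends 22.5 h later; elevated bins there flag."""
    rel = [1.0] * 12
    rel[9] = 1.3  # 18-20 h
    rel[10] = 1.3  # 20-22 h
    kin = classify_kinetics(make_profile(rel, cfg))
    assert kin.overshoot
    assert kin.overshoot_magnitude == pytest.approx(0.3)
    # elevation outside the late scotophase does not count
    rel2 = [1.0] * 12
    rel2[3] = 1.5
    assert not classify_kinetics(make_profile(rel2, cfg)).overshoot


def test_classify_requires_bins(cfg):
    with pytest.raises(ValidationError):
        classify_kinetics(make_profile([np.nan] * 12, cfg))
    with pytest.raises(ValidationError):
        classify_kinetics(make_profile([0.5] + [np.nan] * 11, cfg))


def brute_force_kinetics(rel, tolerance, sc_bins):
    """Independent bin-scan oracle for the classifier."""
    rel = np.asarray(rel, dtype=float)
    ok = np.nonzero(np.isfinite(rel))[0]
    first = ok[0]
    suppression = 1.0 - rel[first]
    recovery = np.nan
    for j in ok:
        if rel[j] >= tolerance:
            recovery = 0.0 if j == first else 2.0 * j
            break
    sc_vals = [rel[j] for j in sc_bins if np.isfinite(rel[j])]
    mag = float(np.mean(sc_vals) - 1.0) if sc_vals else np.nan
    return suppression, recovery, mag


@given(
    rel=st.lists(
        st.one_of(st.floats(0.05, 2.0), st.just(float("nan"))), min_size=12, max_size=12
    )
)
def test_classifier_matches_bin_scan_oracle(rel):
    cfg = ProtocolConfig()
    if np.isfinite(np.asarray(rel, dtype=float)).sum() < 2:
        return
    profile = make_profile(rel, cfg)
    kin = classify_kinetics(profile)
    sup, rec, mag = brute_force_kinetics(rel, 0.9, sc_bins=[9, 10])
    assert kin.initial_suppression == pytest.approx(sup)
    if np.isnan(rec):
        assert np.isnan(kin.recovery_time_h)
    else:
        assert kin.recovery_time_h == pytest.approx(rec)
    if np.isnan(mag):
        assert not kin.overshoot
    else:
        assert kin.overshoot_magnitude == pytest.approx(mag)
        assert kin.overshoot == (mag > 1.0 - 0.9)


def test_paired_normalization_invariance(cfg):
    """Scaling an animal's baseline and refeed IMIs by a common factor
    leaves the relative profile and its classification unchanged."""
    rel = [0.3, 0.5, 0.9, 1.0] + [1.0] * 8
    p1 = make_profile(rel, cfg, baseline_min=70.0)
    p2 = make_profile(rel, cfg, baseline_min=140.0)  # IMIs and baseline both doubled
    np.testing.assert_allclose(p2.imi_bins["rel_imi"], p1.imi_bins["rel_imi"])
    k1, k2 = classify_kinetics(p1), classify_kinetics(p2)
    assert k1.initial_suppression == k2.initial_suppression
    assert k1.recovery_time_h == k2.recovery_time_h


@pytest.fixture(scope="module")
def refeed_sim(cfg):
    spec = GeneratorSpec(seed=11, days=7, refeed=RefeedScenario())
    return simulate_refeed(spec, cfg), spec


def test_bw_loss_pct(cfg, refeed_sim):
    (stream, truth), spec = refeed_sim
    base_end = truth.extras["fast_begin"]
    base = summarize(
        segment_meals(stream.subset(stream.window[0], base_end), cfg),
        stream.animal, (stream.window[0], base_end), cfg,
    )
    prof = analyze_refeeding(stream, base, stream.animal, cfg)
    assert prof.bw_loss_pct == pytest.approx(100.0 * spec.fast_loss_frac)
    assert prof.bw_prefast_g is not None and prof.bw_postfast_g is not None
    assert prof.bw_postfast_g == pytest.approx(
        prof.bw_prefast_g * (1 - spec.fast_loss_frac)
    )


def test_fast_window_bout_free_and_located(cfg, refeed_sim):
    (stream, truth), _ = refeed_sim
    fast_begin, refeed = find_fast_window(stream, cfg)
    assert fast_begin == truth.extras["fast_begin"]
    assert refeed == truth.extras["refeed_time"]
    t = stream.bouts["t_start"]
    assert ((t >= fast_begin) & (t < refeed)).sum() == 0
    assert (refeed - fast_begin) == pd.Timedelta(hours=16)


def test_fast_violations_reported(cfg, refeed_sim):
    (stream, truth), _ = refeed_sim
    bad = stream.bouts.copy()
    extra = pd.DataFrame(
        {
            "t_start": [truth.extras["fast_begin"] + pd.Timedelta(hours=2)],
            "duration_s": [30.0],
            "mass_g": [0.02],
        }
    )
    bad = pd.concat([bad, extra], ignore_index=True).sort_values("t_start")
    from mealpattern import BoutStream

    noisy = BoutStream(stream.animal_id, bad, stream.window, animal=stream.animal)
    base_end = truth.extras["fast_begin"]
    base = summarize(
        segment_meals(noisy.subset(noisy.window[0], base_end), cfg),
        noisy.animal, (noisy.window[0], base_end), cfg,
    )
    with pytest.warns(UserWarning, match="fast window"):
        prof = analyze_refeeding(
            noisy, base, noisy.animal, cfg, refeed_date=truth.extras["refeed_time"].date()
        )
    assert len(prof.fast_violations) == 1


def test_intake_curve_monotone(cfg, refeed_sim):
    (stream, truth), _ = refeed_sim
    base_end = truth.extras["fast_begin"]
    base = summarize(
        segment_meals(stream.subset(stream.window[0], base_end), cfg),
        stream.animal, (stream.window[0], base_end), cfg,
    )
    prof = analyze_refeeding(stream, base, stream.animal, cfg)
    assert prof.intake_curve["cum_kcal"].is_monotonic_increasing
    assert (prof.imi_bins["mean_imi_min"].dropna() >= cfg.imi_threshold_s / 60).all()


def test_injected_kinetics_recovered_pooled(cfg):
    """Pooling ~8 animals recovers the injected three-component curve."""
    scenario = RefeedScenario(suppression=0.7, recovery_h=7.0, overshoot_frac=1.25)
    profiles = []
    for k in range(8):
        spec = GeneratorSpec(seed=100 + k, days=7, refeed=scenario)
        stream, truth = simulate_refeed(spec, cfg)
        base_end = truth.extras["fast_begin"]
        base = summarize(
            segment_meals(stream.subset(stream.window[0], base_end), cfg),
            stream.animal, (stream.window[0], base_end), cfg,
        )
        profiles.append(analyze_refeeding(stream, base, stream.animal, cfg))
    kin = classify_kinetics(average_profiles(profiles))
    assert kin.initial_suppression == pytest.approx(0.7, abs=0.12)
    assert abs(kin.recovery_time_h - 6.0) <= cfg.refeed_bin_h  # 6-8 h bin
    assert kin.overshoot
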