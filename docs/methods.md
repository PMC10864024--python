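# Methods

## Scope

`mealpattern` implements the analysis layer of home-cage feeding
microstructure studies in mice: operational meal segmentation from
bout-level feeder logs, satiation/satiety metrics stratified by
photoperiod, circadian intake profiles, fasting–refeeding satiety
kinetics, and the group-statistics battery typically applied to such
data. Because raw event streams from these studies are generally not
deposited, the package ships a synthetic bout-stream generator with full
ground truth; every pipeline stage is validated against it.

## Operational definitions

A **bout** is one uninterrupted feeder visit (start time, duration, mass
of food removed). A **meal** is a cluster of bouts in which consecutive
bouts are separated by an end-to-start gap shorter than the intermeal
interval (IMI) threshold, with total cluster mass at least the minimum
meal size. Defaults follow the standard protocol for the HM-2 class of
monitors:

| parameter | default | unit | meaning |
|---|---|---|---|
| `imi_threshold_s` | 300 | s | smallest gap that separates two meals |
| `min_meal_mass_g` | 0.050 | g | smallest cluster mass that counts as a meal |
| `energy_density_kcal_per_g` | 3.0 | kCal/g | chow caloric density |
| `lights_on` / `lights_off` | 06:30 / 18:30 | clock | 12:12 photoperiod |
| `recording_days` | 14 | d | ad libitum window |
| `fast_start` / `refeed_start` | 16:00 / 08:00 | clock | 16-h overnight fast |
| `refeed_monitor_h` / `refeed_bin_h` | 24 / 2 | h | refeed observation grid |

**Satiation** (meal-terminating processes) is read out as meal size in
kCal (mass × energy density); **satiety** (meal-delaying processes) as
the IMI, measured from the end of the last bout of one qualifying meal
to the start of the first bout of the next.

Decisions taken where the operational definitions are silent (all
configurable or documented here):

* **Gap definition** — end-to-start, not start-to-start: the interval
  between feeding naturally excludes the eating time itself.
* **Threshold side** — a gap `< 300 s` joins, `>= 300 s` separates; the
  threshold is the smallest *separating* interval.
* **Meal duration** — reported as eating time (summed bout durations) by
  default; the cluster span (first start to last end) is retained and can
  be selected with `meal_duration_mode="span"`. The distinction matters
  for feeding rate = size / duration.
* **Subthreshold clusters** (nibbles) are transparent: their mass counts
  toward total intake (food removed is food eaten) but they contribute to
  no meal metric and do not interrupt an IMI. Whether a nibble should
  censor the surrounding interval is genuinely undecidable from the
  operational definitions; transparency keeps IMIs well defined and mass
  conserved.
* **Photoperiod of a meal** is that of its first bout; of an IMI, that of
  the interval's start. Meals straddling a light transition are not
  split, so counts stay additive. Light transitions use half-open
  intervals `[on, off)` so the two photoperiods partition the day.
* **Days** for per-day normalization start at lights-on (zeitgeber 0),
  matching the circadian axis, not at midnight.
* No maximum meal size is imposed.

Exact invariants maintained by construction and asserted in tests: total
bout mass = meal mass + subthreshold mass; every reported IMI >= the
threshold; `eating_time <= span` for multi-bout meals; cluster count is
non-increasing in the threshold (meal count is *not* monotone once the
mass criterion is active, because merging two nibbles can create a meal —
documented and tested as a constructed example).

Gap comparisons are performed in integer nanoseconds (the native
resolution of the timestamps); converting absolute epoch times to float
seconds would lose sub-microsecond precision and was observed to perturb
gap classification in round-trip tests.

## Microstructure summaries

Per animal and per stratum (diurnal / nocturnal / daily): meal frequency
(meals per 24-h day; diurnal + nocturnal = daily exactly), mean meal size
(kCal), mean IMI (min), mean eating time (s), mean feeding rate (kCal/s),
energy intake (kCal/day), body-weight-adjusted intake (kCal/gBW/day,
using the window-mean body weight), and cumulative intake. Strata with
zero meals propagate NaN (missing), not zero, into per-meal means so they
cannot bias group averages. The circadian profile accumulates *all* bout
intake into zeitgeber-time bins and divides each bin by the number of
days it was actually observed, so partial first/last days are weighted
correctly; the profile's integral reproduces total window intake.

Energy is stored internally in kCal throughout. Published figure axes in
this literature sometimes alternate between "Cal" and "kCal" labels for
the same quantities without stating a conversion; this package treats
both as kCal-denominated and leaves display conversion to the caller.

## Fasting–refeeding analysis

Body-weight loss is `100 x (prefast - postfast) / prefast`, with weights
taken at the fast start and immediately before refeeding (nearest
measurement within 1 h). Meals during the 24-h refeed window are
re-segmented with the *identical* configuration as the ad libitum
analysis. IMIs are assigned to the 2-h bin containing the interval's
start (midpoint or overlap-weighted pooling would be defensible
alternatives; start-of-interval was chosen and is the only binning the
package applies). Each bin's mean IMI is normalized to the animal's own
14-day ad libitum **nocturnal** mean IMI — a paired, within-animal
normalization; group dashed-line baselines are not used. The fast itself
is never counted as an IMI, and bouts detected inside the declared fast
window are reported as food-access violations.

`classify_kinetics` reduces the relative-IMI profile to the canonical
three components:

1. **initial suppression** = 1 − relative IMI of the first non-missing
   bin (values > 0.6 correspond to the strong first-2-h response);
2. **recovery time** = left edge of the first bin whose relative IMI
   reaches the recovery tolerance (default 0.9; exposed because the
   literature brackets recovery only as "6–8 h");
3. **overshoot** = mean relative IMI over the bins covering the last 4 h
   of the scotophase, minus 1, flagged when it exceeds the overshoot
   margin (default `1 - tolerance` = 0.1). The mean over the late-night
   window, rather than a per-bin maximum, keeps the false-positive rate
   of the flag low when bins hold only one or two intervals.

## Synthetic generator

The generator emulates the statistical structure the analysis consumes,
as an alternating renewal process per animal: draw an IMI from the
photoperiod-specific distribution in force at the current clock time,
then emit a meal; repeat. Distribution families (none are specified by
the protocol; chosen for positivity and tractable means):

* IMI ~ gamma; nocturnal mean 70 min (anchored to the published ad
  libitum value for adult male mice), shape 4 (CV 50%, typical of
  free-feeding interval data). The **diurnal scale is unanchored**: no
  published diurnal IMI exists for this protocol, so the default is 3x
  the nocturnal mean (210 min), which yields ~12–13 meals/day overall,
  inside the published 13–16 meals/day range.
* Meal size ~ gamma, mean 0.8 kCal (0.27 g), shape 6 — ~12 kCal/day,
  i.e. ~0.4 kCal/gBW/day at 30 g, matching the scale of adjusted-intake
  data in this literature.
* Bouts per meal = 1 + Poisson(3); bout masses split by a symmetric
  Dirichlet; within-meal gaps ~ exponential (mean 60 s) truncated below
  90% of the IMI threshold; bout durations = bout energy / intake rate
  (default 1.5 Cal/s, giving ~9 min of eating per 0.8-kCal meal).
* Nibbles: Poisson (5/day) isolated subthreshold bouts, 5–45 mg.
* Body weight is bookkeeping only (linear drift, scripted fast loss and
  linear regain), not an energy-balance model.

Circadian modulation is two-stratum (distinct diurnal/nocturnal
parameter sets), matching two-stratum reporting; there is no continuous
oscillator, no ultradian structure beyond the renewal process, no
feeder-hardware artifacts (missed transponder reads, balance drift), and
no day-to-day behavioral drift. A green parameter-recovery test
therefore establishes correctness of the *pipeline arithmetic*, not
realism of mouse behavior.

In **recoverable mode** (default) the generator resamples draws so that
between-meal gaps clear the threshold (with a 1 µs guard above it,
because emitted timestamps are nanosecond-quantized), within-meal gaps
stay below it, meal masses meet the minimum, and nibbles keep a full
threshold of clearance on both sides. Segmentation then provably
reproduces the truth table exactly, which is what the exact-recovery
tests assert (meal masses to 1e-9 g; IMIs to 1 µs, the quantization
limit).

The scripted refeeding episode draws post-refeed IMIs as the nocturnal
baseline mean times a three-component multiplier curve: `1 - s` before
2 h, a linear ramp to 1 at the recovery hour, 1 thereafter, and the
overshoot factor during the last 4 h of the scotophase. Post-refeed IMIs
use gamma shape 25 (CV 20%), tighter than ad libitum, reflecting the
strong entrainment of post-fast feeding; this choice was fixed before
any recovery test was run. The first meal latency after refeeding is a
short truncated-exponential draw (mean 2 min) and is never counted as an
IMI.

Determinism: one master seed; animals receive independent spawned
substreams (`numpy.random.SeedSequence`), so output is bit-identical
under a fixed seed and animals are statistically independent.

## Statistics

One-way ANOVA via scipy; two-way ANOVA via statsmodels OLS with Type II
sums of squares (interaction included by default, removable — published
methods rarely state whether interactions were fitted). Tukey-Kramer
all-pairs comparisons are computed directly on
`scipy.stats.studentized_range` with the unequal-n harmonic adjustment;
statsmodels' equivalent routine is the independent cross-check in the
test suite (the direct route is ~5x faster because the critical value is
cached, which matters for simulation-based calibration). Shapiro-Wilk
and pairwise two-sided variance-F screening are *reported, never
gating*: the analysis does not silently switch to nonparametric
alternatives. Grubbs' test flags at most one outlier per group per pass
(no iterative stripping), using the two-sided t-based critical value;
under null simulations its flag rate and the Tukey-Kramer family-wise
error sit at the nominal 5% (calibration tests). Missing responses are
excluded listwise per response, mirroring a priori exclusion of animals
lost before study end.

## Numerical and degenerate-input choices

* Feeding rate of a zero-duration meal is NaN (undefined marker), never
  a division error, and is excluded from averages.
* Empty strata, empty bins, and missing body weights propagate as
  missing values with warnings, not as zeros.
* Recovery tolerance 0.9 and overshoot margin 0.1 are symmetric around
  baseline; both are parameters of `classify_kinetics`.
* Threshold ties: a gap exactly equal to the threshold separates meals
  (the threshold is a minimum IMI).

## Known limitations

* Group-housed cages are assumed pre-resolved to individual animals by
  the monitor's transponders; no cage-level demixing is attempted.
* No drinking, locomotor, or energy-expenditure channels.
* The generator's cohort presets (genotype x sex x age) are qualitative
  scale adjustments for demonstration, not reconstructions of any
  published cohort; published group values derive from raw recordings
  that are not publicly available.
* Two-way designs with empty cells are rejected rather than refitted on
  a reduced model.
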