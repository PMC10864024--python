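# mealpattern

Meal pattern analysis of home-cage feeding-event streams in mice.

Feeding monitors (HM-2-class home cages) log one record per feeding
*bout*: animal id, start time, duration, and the mass of food removed.
Behavioral phenotyping asks two questions of such streams: how big are
meals (**satiation** — the processes that terminate a meal) and how long
do animals wait between meals (**satiety** — the processes that delay the
next one). `mealpattern` turns raw bout logs into those readouts for
researchers studying ingestive behavior, circadian intake, and
fasting-induced hyperphagia.

## The core computation

A meal is defined operationally. With bout end-to-start gaps
`g_i = t_start[i+1] − (t_start[i] + dur[i])`:

* bouts with `g < T_IMI` (default 5 min) belong to the same cluster;
* a cluster is a **meal** iff its total mass `m ≥ m_min` (default
  0.050 g); smaller clusters are nibbling, which counts toward intake but
  toward no meal metric;
* meal size `= m × ρ` (kCal, diet energy density ρ = 3.0 kCal/g); the
  **intermeal interval** (IMI) runs from the end of one qualifying meal
  to the start of the next, so every IMI ≥ T_IMI.

On top of segmentation the package computes per-animal, per-photoperiod
summaries (meal frequency, mean meal size, mean IMI, eating time, feeding
rate = size/duration, absolute and BW-adjusted intake), circadian intake
profiles on the zeitgeber axis (ZT 0 = lights-on, 06:30 by default), and
fasting–refeeding satiety kinetics: 2-h-binned IMIs after a 16-h fast,
normalized to each animal's own ad libitum nocturnal baseline and
classified into initial suppression, recovery time, and late-scotophase
overshoot. A statistics module provides one/two-way ANOVA with the
Tukey-Kramer post hoc, Shapiro-Wilk and variance-F screening, and Grubbs
single-outlier detection.

Because raw recordings in this literature are rarely deposited, a
synthetic generator (`mealpattern.synth`) emits bout streams as an
alternating renewal process with photoperiod-specific gamma IMIs
(nocturnal mean 70 min), gamma meal sizes, Poisson bout counts and
scripted fasting/refeeding episodes — with full ground truth, so the
whole pipeline is testable offline. See `docs/methods.md` for the model,
its assumptions, and every default.

## Worked example

```python
from mealpattern import (ProtocolConfig, GeneratorSpec, simulate,
                         segment_meals, summarize, summary_table)

cfg = ProtocolConfig()                       # 5 min / 0.050 g / 3.0 kCal/g, 06:30-18:30
spec = GeneratorSpec(seed=1, n_animals=10, days=14)
streams, truth = simulate(spec, cfg)

summaries = [summarize(segment_meals(s, cfg), s.animal, s.window, cfg)
             for s in streams.values()]
df = summary_table(summaries)
print(df.groupby("stratum")[["meal_count_per_day", "mean_meal_size_kcal",
                             "mean_imi_min", "intake_kcal_per_day",
                             "intake_kcal_per_gbw_per_day"]].mean().round(3))
```

prints

```
           meal_count_per_day  mean_meal_size_kcal  mean_imi_min  intake_kcal_per_day  intake_kcal_per_gbw_per_day
stratum
daily                   11.60                0.794       111.566                9.582                        0.323
diurnal                  3.55                0.793       205.513                2.999                        0.101
nocturnal                8.05                0.795        69.154                6.583                        0.222
```

i.e. the cohort eats ~11.6 meals/day of ~0.8 kCal, mostly at night, and
the pipeline recovers the generator's injected nocturnal IMI scale
(69.2 vs 70 min) and meal size (0.794 vs 0.8 kCal). The daily mean IMI
(112 min) is the mix of nocturnal (69 min) and diurnal (206 min)
intervals.

Refeeding after a scripted 16-h fast, pooling ten animals as cohort
figures do:

```python
from mealpattern import (RefeedScenario, simulate_refeed, analyze_refeeding,
                         average_profiles, classify_kinetics)

profiles = []
for k in range(10):
    spec = GeneratorSpec(seed=7 + k, days=14, refeed=RefeedScenario())
    stream, rt = simulate_refeed(spec, cfg)
    base_end = rt.extras["fast_begin"]
    base = summarize(segment_meals(stream.subset(stream.window[0], base_end), cfg),
                     stream.animal, (stream.window[0], base_end), cfg)
    profiles.append(analyze_refeeding(stream, base, stream.animal, cfg))
kin = classify_kinetics(average_profiles(profiles))
```

gives `initial_suppression = 0.67`, `recovery_time_h = 6.0`,
`overshoot = True (magnitude 0.31)`: relative IMIs start at ~1/3 of
baseline (strong hyperphagia), return to baseline in the 6–8 h bin, and
exceed it at the end of the dark phase — recovering the injected
(0.7, 7 h, 1.25×) three-component curve within one 2-h bin.

## Command line

```sh
mealpattern simulate  --seed 1 --out-dir sim            # bout log + ground truth
mealpattern segment   --bouts sim/bouts.csv --out-dir seg
mealpattern summarize --bouts sim/bouts.csv --bw sim/body_weights.csv \
                      --animals sim/animals.csv --out-dir sum
mealpattern refeed    --bouts refeed_log.csv --bw bw.csv --out-dir rf
mealpattern stats     --summary sum/summary.csv --response mean_meal_size_kcal \
                      --factors genotype --out-dir st
mealpattern run-all   --seed 1 --out-dir out            # the whole chain
```

Thresholds are overridable (`--imi-threshold-s`, `--min-meal-g`,
`--kcal-per-g`, `--duration-mode`); identical seed + config give
byte-identical outputs, and every table embeds the config snapshot id.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch: it simulates a two-arm cohort
(10 control + 10 knockout animals, 14 days), segments every stream,
builds the summary tables, runs the pooled fasting–refeeding analysis
for each arm, and applies the ANOVA/Tukey-Kramer battery, writing the
intermediate tables beside the output JSON.
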