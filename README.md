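# feosim

Simulation and analysis of **food-anticipatory activity (FAA)** — the burst of
foraging behaviour that rats and other species show in the hours before a
predictable mealtime.  Food-restricted animals can anticipate several daily
meals, and even two "daily" meals recurring at different circadian periods
(e.g. one every 24 h and one every 26 h); when food is withheld, the
anticipation bouts keep recurring for days with a period matching the prior
feeding schedule.  `feosim` is for chronobiologists and modellers who want to
(i) simulate this behaviour with a population model of food-entrainable
oscillators (FEOs) and (ii) quantify activity records — simulated or
recorded — with a single analysis pipeline.

## The model

A population of N coupled phase oscillators with heterogeneous intrinsic
periods, driven by food availability:

    dθᵢ/dt = 2π/Tᵢ + (K/N) Σⱼ sin(θⱼ − θᵢ) − K_F · F(t) · M(θᵢ)

* Tᵢ — intrinsic periods, drawn once from 𝒩(μ = 24 h, σ = 1 h);
* F(t) — binary food stimulus: 1 while a meal is available, 0 otherwise;
* M(θ) = Σⱼ₌₁⁸ aⱼ sin(jθ) — a local, restoring phase-modulation: food pulls
  oscillator phases toward θ = 0 (the mealtime phase) but only within a ~6 h
  phase neighbourhood, so separate oscillator clusters can entrain to
  separate meals;
* K — weak mutual coupling (evaluated via the Kuramoto order parameter,
  K·R·sin(ψ − θᵢ), so the right-hand side costs O(N)).

The behavioural output is χ(t), the fraction of oscillators in the narrow
phase window [−θ*, 0] just before the mealtime phase, passed through a
saturating sigmoid α(χ) = (1/(1−c))·(e^{k₁χ}/(e^{k₁χ}+k₂) − c), c = 1/(1+k₂).
Anticipation is emergent: oscillators with short periods run ahead of the
entraining meal, so the window fills up before mealtime.  With two concurrent
schedules the population *sorts by period* — intrinsically slow oscillators
(τ > 24 h) entrain to the 26-h meal, fast ones to the 24-h meal — and during
extended food deprivation each cluster free-runs near its schedule's period.

Because F(t) is piecewise constant, the ODEs are integrated segment-by-segment
between meal boundaries (adaptive Runge–Kutta, abs/rel tolerance 1e-10), and
the run is bit-reproducible given a seed.

## Worked example

```python
from feosim import (ModelParams, build_preset, bin_activity, faa_ratio,
                    chi_square_periodogram, simulate)

params = ModelParams()                 # default parameter set
protocol = build_preset("three_meal", days=6, deprivation_h=60.0)
series = simulate(params, protocol, seed=1)      # χ(t) and α(χ) at 10-min steps
record = bin_activity(series, bin_width=10.0)    # analysis-ready 10-min bins

for r in faa_ratio(record, protocol, window=2.0, denominator_mode="intermeal"):
    if 120 <= r.meal_start < 144:      # last scheduled day
        print(f"meal at ZT{r.meal_start % 24:g}: intermeal FAA ratio = {r.ratio:.3f}")
print("periodogram peak:", chi_square_periodogram(record).peak_period, "h")
```

prints

```
meal at ZT2: intermeal FAA ratio = 0.615
meal at ZT10: intermeal FAA ratio = 0.637
meal at ZT18: intermeal FAA ratio = 0.595
periodogram peak: 24.0 h
```

i.e. after six days on the 3-meal schedule, ~60 % of the activity in each
inter-meal interval is packed into the 2 h before the next meal (anticipation
at all three mealtimes), and the record is dominated by a 24-h rhythm.
During the 60-h deprivation tail the simulated bouts recur at the expected
mealtimes with damping day over day (peak activity 0.82 on deprivation day 1,
0.62 on day 2).

The same pipeline runs from the shell:

```sh
feosim simulate --preset three_meal --seed 1 --out out/
feosim analyze --record out/activity_series.csv --protocol out/protocol.yaml \
       --faa-window 2 --periodogram chi2 --out out/
feosim fixture --seed 9 --out fixture.csv   # synthetic operant record
```

`feosim simulate` writes the activity series (CSV), a quintile raster
actogram (PNG/CSV) and a provenance log (version, seed, config hash, solver
tolerances, wall time).

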