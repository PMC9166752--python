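# Methods

## Model

The package simulates food-anticipatory activity as the collective output of
N food-entrainable oscillators (FEOs), each a phase oscillator

    dθᵢ/dt = 2π/Tᵢ + (K/N) Σⱼ sin(θⱼ − θᵢ) − K_F · F(t) · M(θᵢ),

with intrinsic periods Tᵢ ~ 𝒩(μ, σ²) sampled once per run.  The model
embodies three assumptions: (1) anticipation reflects entrained circadian
oscillators, not interval timers — bouts persist through food deprivation
because each oscillator keeps cycling at its own Tᵢ; (2) food acts only
through a *local, restoring* phase modulation M(θ) (a truncated 8-term
Fourier sine series), so the stimulus is invisible to oscillators more than
~6 h of phase away from the mealtime phase θ = 0, which is what lets separate
clusters entrain to separate meals; (3) behaviour is a threshold read-out —
the fraction χ(t) of oscillators inside the narrow pre-mealtime window
[−θ*, 0], filtered by the sigmoid α(χ) — rather than a prescribed activity
pattern.  Anticipation and period sorting are emergent consequences of
period heterogeneity.

The model deliberately omits SCN/light input, homeostatic hunger drive, meal
size/palatability and phase noise; the system is deterministic once the
periods and initial phases are drawn.

## Parameters

| name (code) | symbol | default | units | role |
|---|---|---|---|---|
| `coupling` | K | 0.001 | rad/h | mutual FEO coupling; weak, so clusters barely interact |
| `food_gain` | K_F | 0.6433 | rad/h | strength of food phase-modulation; sets the entrainment range of a daily meal (≈ ±2 h phase correction per 1-h meal) |
| `n` | N | 1000 | – | population size; χ resolution is 1/N |
| `period_mean` | μ | 24 | h | center of the period distribution |
| `period_sd` | σ | 1 | h | period heterogeneity; drives both anticipation build-up and deprivation damping |
| `indication_width` | θ* | 0.2 | rad | pre-mealtime window; ≈ 45.8 min at μ = 24 h |
| `sigmoid_rate` | k₁ | 40 | – | steepness of the activity read-out |
| `sigmoid_location` | k₂ | 5 | – | half-saturation location; the derived shift c = 1/(1+k₂) makes α(0)=0, and 1/(1−c) makes α(1)=1 |
| `fourier_coeffs` | a₁..a₈ | (0.2142 … 0.0041) | – | shape of M(θ) |

The defaults ship in `feosim/data/default_params.yaml`; every preset's day
counts, meal durations and deprivation lengths are likewise defaults that can
be overridden (tests use shortened entrainment phases at the same parameter
values).

## Protocol conventions

* Meal intervals are half-open [start, start+duration), so F(t) is
  single-valued at boundaries and daily food availability integrates exactly.
* Zeitgeber time maps to protocol hours as 24·day + ZT; in constant-dark
  segments the ZT labels are retained purely as notation.  For the
  SCN-ablated arm (dim light, meals at local clock times) the anchor is an
  explicit option rather than a guess.
* Meals from different concurrent schedules may overlap as they cross; F(t)
  is their logical OR (food is either present or absent).  Exact duplicate
  events (same start, duration and tag) are rejected.
* The concurrent two-schedule preset chains the single-meal phases by meal
  count (15 meals at 24-h spacing, then 7 at 25 h, 9 at 26 h), starts the
  fixed second meal at the first ZT17 after the ramp ends, continues the 26-h
  train through the 27-day concurrent window, and appends the deprivation
  segment at the end of the last scheduled day.

## Numerics

* F(t) is piecewise constant, so the ODE system is integrated on each
  interval of continuity separately (solver restarted at every meal start and
  end), with state carried across boundaries.  Solver: `scipy.solve_ivp`
  with DOP853 at rtol = atol = 1e-10 (an order-8 adaptive explicit
  Runge–Kutta; at this tolerance it takes far larger steps than RK45 on this
  smooth vector field, and the free-run test pins the accuracy).
* Phases are integrated unwrapped — every RHS term is 2π-periodic — and
  reduced mod 2π only at output, avoiding event handling at wrap points.
* The coupling sum is evaluated through the order parameter
  (K·R·sin(ψ−θᵢ), O(N) per RHS call); agreement with the literal double sum
  to 1e-12 is a tested invariant.
* Seeded draws use one `numpy` Generator per run: periods first, then
  uniform initial phases on [0, 2π).  The draw order is a package convention
  fixed for reproducibility.
* χ window membership is closed at both −θ* and 0 after mod-2π reduction — a
  measure-zero choice fixed for bit-reproducibility.
* α is evaluated as 1/(1 + k₂·e^{−k₁χ}) to avoid overflow.  Note that in
  double precision α saturates to exactly 1 for k₁χ ≳ 37; it is strictly
  increasing wherever it is resolvable.
* Default output sampling is 10 min, matching the analysis binning so
  simulated series feed the pipeline without resampling.

## Analysis pipeline

* **Binning**: event times are summed, continuous model output averaged, per
  bin (10-min default).
* **Smoothing**: 40-min centered running mean; edges use shrinking centered
  windows so record length and bout phases are preserved.  With an even
  window of w bins the window covers [i−w/2, i+w/2−1].
* **Actograms**: nonzero bins are ranked into quintiles of the whole record's
  nonzero-count distribution (per-day scaling is an option); rows of
  `day_length` hours, optionally double-plotted.
* **FAA ratios**: activity in the pre-meal window as a proportion of either
  the day's non-meal activity (whole-day) or the activity since the previous
  meal's end (intermeal).  Zero denominators return ratio 0 with an explicit
  degenerate flag, so downstream averages never propagate NaN.
* **Bout detection**: the original analyses used proprietary software
  (ClockLab) whose onset/offset rule is unpublished; here a transparent
  replacement is used — on the smoothed record within a search window, the
  onset is the first bin above `onset_frac` × window peak sustained for ≥3
  bins, the end the last bin above `offset_frac` × peak, and the bout center
  the onset–end midpoint (activity-weighted centroid available).  Parameters
  are exposed and validated by parameter recovery on synthetic records.
* **Free-running periods after concurrent schedules**: search windows are
  centered on mealtimes extrapolated from each schedule's last meal at its
  cycle length (cycle 0 = the last scheduled meal), half-width 3 h — wide
  enough for the 2–3 h anticipatory build-up, narrow enough to separate the
  two schedules' windows until they nearly cross.  Because a 24-h and a 26-h
  train drift 2 h/cycle relative to each other, windows that would overlap a
  window of the other schedule are discarded *on both sides*: a merged bout
  cannot be attributed to either schedule.  The period is the OLS slope of
  bout center against cycle index.
* **Periodograms**: Sokolove–Bushell Qp with a per-period chi-square 0.05
  line (the field's conventional display; note that scanning ~50 periods at
  0.05 each implies frequent single-point excursions under the null — use a
  Bonferroni-corrected alpha for family-wise control), and the normalized
  Lomb–Scargle spectrum for unevenly sampled records.

## Synthetic records

`generate_fixture` emulates time-binned operant activity as Poisson counts
with rate = background + amplitude·Gaussian bump recurring at the bout
period (circular distance in the cycle).  It reproduces the count statistics,
periodicity and bout shape that the pipeline consumes — not meal-driven
suppression of activity, day-to-day amplitude drift, or the asymmetric rise
of real FAA.  Pipeline tests passing on these fixtures therefore validate
the detection/regression machinery, not the behaviour of real animals.

## Problem sizes

The full two-schedule protocol (~62 days, N = 1000) integrates in a few
seconds per seed; the reproduction script averages 5 seeds.  Unit and
property tests use shortened entrainment phases (e.g. 6 days of the 3-meal
schedule) and smaller populations where the property under test does not
depend on scale; all model parameters stay at their defaults.

## Known limitations

* The deprivation-tail period regression rests on 3–4 bouts per schedule
  (90 h of deprivation), so single-bin center shifts move the slope by
  ~0.05–0.1 h; estimates are reported with r² and bout count.
* As the two schedules' expected times converge, bouts merge before the
  windows formally overlap; the overlap-discard rule removes the fully
  merged cycles but late nearly-merged bouts can still bias centers slightly
  toward each other.
* The bout-detection rule is a stated replacement for an unpublished
  proprietary algorithm, not a reconstruction of it.
* Quintile actogram ranks depend on the whole-record distribution, so
  appending data can change earlier rows' bar heights (use per-day scaling
  for incremental displays).
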