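# circashift

Occupational-health modelling of how **circadian rhythm types** and
**objective shift-work demands** jointly shape **sleep quality** and
**depressive symptoms** in rotating-shift nurses.

Shift nurses differ in how well their circadian system tolerates rotating
schedules. The Circadian Type Inventory captures this on two axes:
**FR** (flexible–rigid, 5–25; higher = more flexible sleep–wake timing,
protective) and **LV** (languid–vigorous, 6–30; higher = more drowsiness
vulnerability after sleep loss, a risk trait). `circashift` provides a
tested, reusable implementation of an analysis pipeline that relates these
traits and a nurse's measured four-week workload to PSQI sleep quality
(0–21, > 7 screens positive for insomnia) and PHQ-9 depression (0–27, ≥ 10
screens positive for probable depression) — and then simulates how symptom
trajectories evolve day by day under different schedules.

Because the underlying hospital data are not publicly deposited, the package
ships a calibrated **synthetic cohort generator**, so every stage runs and
is testable end-to-end with no external data.

## What it computes

1. **Workload metrics** (`circashift.workload`) — classifies shift events
   (evening = ≥ 4 consecutive worked hours in 18:00–24:00; night = ≥ 4 in
   00:00–08:00, with night precedence for the long 18:00–08:00 shift and its
   3-h nap netted out) and aggregates four-week work quantity. Work
   intensity uses the staffing curve

   `expected NPR = a · exp(b · severity)`, with (a, b) fit by
   original-scale least squares to the anchors severity 0 → 1:8, 1 → 1:3,
   2 → 1:1 (giving a ≈ 0.1154, b ≈ 1.0791); severity is unit CMI min–max
   normalised to [0, 2]. Workload = expected NPR / actual NPR, and
   workload exposure = workload × corresponding hours.

2. **Univariate statistics** (`circashift.preprocess`) — 3×IQR outlier
   fences, median/mode imputation, Yeo–Johnson (+ z-score) transform
   recipes, tie-corrected Spearman matrices, Mann–Whitney U /
   Kruskal–Wallis H group contrasts.

3. **Moderated GLMs** (`circashift.glm`) — for each outcome, three
   candidate log-link models differing in which demand variable (night
   count, shift hours, shift workload exposure) moderates the interactions;
   ranked by AIC/BIC/pseudo-R², with VIF and residual diagnostics.
   Coefficients are on the standardized (Yeo–Johnson + z) predictor scale.

4. **Nonlinear screen and breakpoint** (`circashift.nonlinear`) — a
   penalized-spline GAM (GCV-chosen smoothing; a term is flagged nonlinear
   when EDoF > 1.2 with p < 0.05) followed by continuous two-segment
   ("broken-stick") regression with an exhaustive candidate-grid breakpoint
   search and a Wald slope-contrast test.

5. **Trajectory simulation** (`circashift.simulate`) — coupled 100-day
   Monte-Carlo iteration: each day the predicted PSQI uses yesterday's
   smoothed PHQ-9 (and vice versa), followed by exponentially weighted
   smoothing `s_t = α·pred + (1−α)·s_{t−1}` with α = 0.2. Includes
   bootstrap population runs (1,000 virtual nurses), adaptability-profile
   scenario grids (M/H/L percentile rules on FR/LV) over demand multipliers,
   and threshold-crossing summaries.

6. **Synthetic cohorts** (`circashift.synthetic`) — Gaussian-copula
   generation with scaled-beta marginals calibrated to the published
   medians/IQRs/prevalences, plus planted-truth modes (known GLM
   coefficients, known dose-response kink) for parameter-recovery testing.

## Worked example

```python
from circashift import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, n=288, outdir="results",
                     simulate_n_individuals=1000,
                     stages=("cohort", "univariate", "glm", "simulate"))
bundle = run_pipeline(cfg)

rho = bundle.correlation.rho.loc["psqi", "phq9"]
print(f"Spearman rho(PSQI, PHQ-9) = {rho:.3f}")
sel = bundle.selected["psqi"]
print(f"selected sleep-quality moderator: {sel.spec.moderator} "
      f"(AIC {sel.aic:.2f}, pseudo R^2 {sel.pseudo_r2:.3f})")
pop = bundle.population
print(f"population insomnia crossing day: {pop.crossing['insomnia']}")
for g in ("H", "M", "L"):
    ts = bundle.scenarios[(g, 1.0)]
    print(f"group {g} @ baseline demand: final mean PSQI "
          f"{ts.mean_psqi[-1]:.2f}, insomnia day {ts.crossing['insomnia']}")
```

Output:

```
Spearman rho(PSQI, PHQ-9) = 0.545
selected sleep-quality moderator: night_count (AIC 1314.28, pseudo R^2 0.371)
population insomnia crossing day: 21
group H @ baseline demand: final mean PSQI 6.73, insomnia day None
group M @ baseline demand: final mean PSQI 7.64, insomnia day 22
group L @ baseline demand: final mean PSQI 8.86, insomnia day 14
```

Reading it: the synthetic cohort reproduces the strong sleep–depression
rank correlation it was calibrated to (0.545 here vs the 0.560 target);
on a cohort with *no planted demand effect* the moderator selection is
essentially noise (the three candidates differ only in interaction terms),
so the `night_count` pick carries no substantive meaning; and under the
baseline four-week demand condition (4 night shifts, 44 shift hours,
exposure 147) the simulated high-adaptability group stays below the
insomnia screen while the low-adaptability group crosses it within two
weeks — the qualitative dose–response pattern of interest.

The same run is available from the shell:

```bash
circashift all --seed 1 --n 288 --outdir results
```

## Acceptance script

`scripts/acceptance.py` recomputes the pipeline's headline quantities from
scratch — the expected-NPR curve coefficients refit from their three
anchor points, the mean recovered dose-response breakpoint over 200
planted synthetic cohorts, and the mean insomnia screening proportion over
100 calibrated cohorts — and writes them to a JSON file:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/circashift/
  workload.py    shift classification, demand summaries, NPR curve
  preprocess.py  fencing, imputation, Yeo-Johnson/z recipes, rank statistics
  glm.py         moderated GLM candidates, comparison, diagnostics
  nonlinear.py   GAM screen, broken-stick breakpoint regression
  simulate.py    coupled EWS trajectory engine, scenarios, crossings
  synthetic.py   copula cohorts, planted modes, shift logs, census tables
  pipeline.py    config, CSV I/O, end-to-end orchestration
  cli.py         `circashift` command-line entry point
docs/methods.md  modelling assumptions, defaults, and limitations
```
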