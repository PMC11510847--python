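# sevensload

Workload modelling for women's rugby sevens from 10 Hz GNSS speed traces,
contact counts and athlete mass.

In rugby sevens, the standard workload measure is session RPE
(sRPE = self-reported 0–10 effort × playing time in minutes). It is easy to
collect but hides *which* objective demands drive the load. This package
implements, as a fully tested pipeline, an analysis that decomposes the
external demands of match play into twelve kinematic zones and asks how
they — together with physical contacts and body mass — predict sRPE:

1. **Zone kinematics** — per-sample acceleration as the first difference of
   10 Hz GNSS speed; distance binned into three speed zones (walking
   < 1.5 m/s, running, sprinting above an individualized sprint-entry
   threshold) × four acceleration types (mild/hard acceleration and
   deceleration, split at ±2 m/s²).
2. **Workload model** — a linear mixed model

   `sRPE_ij = β₀ + β_m·mass_j + β_c·contacts_ij + β_d·distance_ij
   + Σ_a β_a·D(a)_ij + Σ_{a,s} β_{as}·D(a,s)_ij + u_j + ε_ij`

   with a random intercept `u_j` per athlete, fitted by REML; `D(a)` are
   acceleration-type distance sums and `D(a,s)` their low/high-speed cells
   (mild acceleration and moderate speed are reference levels).
3. **Evaluation** — actual vs. model-predicted sRPE across tournament game
   numbers: a two-factor ANOVA (game × sRPE type) with an athlete blocking
   stratum, Tukey HSD on game number, and Holm-adjusted paired comparisons
   per game.

The athlete data behind such analyses are not public, so the package ships
a calibrated **synthetic study generator**: a five-state semi-Markov
movement model producing 10 Hz speed traces, negative-binomial contact
counts, and RPE reports generated from a known ground-truth workload model.
Its defaults are calibrated so a default study reproduces the published
descriptive profile of international women's sevens match play (≈4
contacts, ≈12 min played, RPE ≈ 7, sRPE in the 90s, 1002 complete records,
mild-deceleration distances of ≈259/704/82 m across the speed zones, and a
model explaining ≈49% of sRPE variance). Because the generating
coefficients are known, the estimator is validated by parameter recovery
and confidence-interval coverage — see `docs/methods.md`.

Intended users: sports scientists and analysts reproducing or extending
zone-based workload models, and anyone needing a seeded, realistic GNSS
match-play simulator with known ground truth.

## Worked example

```python
from sevensload import StudyConfig, simulate_study, drop_incomplete, fit_lmm
from sevensload.model import adjusted_r2

study = simulate_study(StudyConfig(), seed=1)   # 99 matches, 19 athletes
complete = drop_incomplete(study)               # listwise deletion on RPE
fit = fit_lmm(complete)
print(len(complete), round(adjusted_r2(fit, complete), 3))
print(fit.coefficients.loc[["mass_kg", "contacts", "total_m", "LD_total"],
                           ["estimate", "t", "p"]].round(3))
```

prints

```
1004 0.493
          estimate      t    p
mass_kg     -0.744 -3.766  0.0
contacts     1.086  3.949  0.0
total_m      0.287  5.036  0.0
LD_total    -0.228 -3.954  0.0
```

Read: of 1188 simulated player-matches, 1004 had an RPE report; the model
explains 49% of sRPE variance (adjusted, including athlete intercepts).
Heavier athletes report lower session loads (−0.74 au/kg), each contact
adds ≈1.1 au, total distance drives load up, and mild-deceleration
distance carries a negative main effect with positive low- and high-speed
interactions — the same significance structure reported for the real
cohort, with every acceleration term non-significant.

The numbered drivers under `analysis/` run the same pipeline as a
narrative: `01_simulate_study.py` (records + descriptives),
`02_zone_profile.py` (12-zone table vs. the reference profile),
`03_fit_workload_model.py` (coefficient table), and
`04_evaluate_predictions.py` (game-number ANOVA + post hocs, e.g.
`game_number: F(5, 1978) = 25.9`, `srpe_type: F(1, 1978) = 0.0, p = 1`,
Tukey flagging exactly games 1–2 vs. 3–6). Each writes its tables under
`results/`. The same stages are available on the command line via
`sevensload simulate|extract|fit|evaluate|reproduce`.

## Layout

```
src/sevensload/     config, synthetic, kinematics, features, model,
                    evaluation, pipeline, cli
analysis/           numbered narrative drivers over the pipeline
scripts/            acceptance.py (headline quantities, from scratch)
tests/              pytest suites incl. the five-part validation suite
docs/methods.md     model, generator, calibration choices, limitations
```
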