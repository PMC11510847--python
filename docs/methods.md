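# Methods

`sevensload` is a tested reimplementation of a workload-analysis pipeline
for women's rugby sevens: 10 Hz GNSS speed traces are reduced to distances
in twelve speed × acceleration zones, fused with contact counts and athlete
mass, and regressed on session RPE with a linear mixed model; the model's
predictions are then evaluated against observed session RPE across
tournament game numbers. Because the original athlete data are not public,
a calibrated synthetic-data generator stands in for them; its generating
parameters are known, so the estimation machinery can be validated by
parameter recovery — something no real dataset allows.

## 1. Zone kinematics

A trace is a 10 Hz speed series `v_t` (m/s) with per-sample on-field flags
and period labels (`H1`, `HT`, `H2`). Acceleration is the backward first
difference, `a_t = (v_t − v_{t−1}) · f` with `f = 10` Hz and `a_0 = 0`;
no smoothing is applied by default (an odd centred moving-average window is
available for sensitivity work).

Per-sample distance `v_t/f` accrues to one of twelve cells:

* speed zones, half-open and lower-inclusive — walking `[0, 1.5)` m/s,
  running `[1.5, v_sprint)`, sprinting `[v_sprint, ∞)`, where `v_sprint`
  is each athlete's mean velocity over the first 10 m of a maximal 40 m
  sprint (one value per athlete for the study window);
* acceleration types at ±2 m/s² — hard acceleration `a > 2`, mild
  acceleration `0 < a ≤ 2`, mild deceleration `−2 ≤ a ≤ 0`, hard
  deceleration `a < −2`.

Two conventions deserve emphasis. First, `a = 0` counts as mild
deceleration, so distance covered at constant speed accrues to the LD
column; this is what makes LD dominate every speed zone by an order of
magnitude, as the reference descriptive profile requires, and it is the only
assignment of the zero sample consistent with that profile. Second, halftime
is excluded from both zone distances and playing time even though players
remain on the field; the flag `include_halftime` reverses this. Playing time
is the count of contributing samples divided by the sample rate.

Three comparator summaries used elsewhere in the acceleration-processing
literature are computed over the same samples: the absolute-value total
(distance at `|a| > 2`), the acceleration/deceleration distance ratio
(reported as undefined, never infinite, when no supra-threshold
deceleration exists), and the four speed-agnostic bins, which equal the
speed-marginalized rows of the 12-cell grid exactly.

## 2. Synthetic study generator

The generator emulates one international squad's tournament season:
19 athletes (mass ~ N(69.7, 6.24²) kg; sprint-entry threshold
~ N(5.2, 0.3²) m/s truncated above 1.5), 99 matches in alternating six- and
five-game tournaments, 12 players fielded per match, two 7-minute halves
with a 2-minute halftime at exactly 10 Hz.

**Movement model.** Each on-field span is a semi-Markov chain over five
locomotor states (stand, walk, jog, sprint, contact-brake) with exponential
dwell times and state-specific target speeds; sprint targets are drawn
relative to the athlete's own threshold. Between states the speed ramps
linearly at a magnitude drawn from a two-component mixture of mild
(< 2 m/s²) and hard (> 2 m/s²) ramps, with hard-biased overrides for sprint
entries/exits and contact brakes and a mild-biased override for gentle
pick-ups into walking. Chains start and end each span at zero speed, so
substitutions never produce speed discontinuities, and no consecutive
samples differ by more than the hardest ramp times the sample interval.
During halftime the chain is restricted to standing and walking.

Two per-trace heterogeneity factors make player-matches differ the way real
performances do, and they are statistically load-bearing: a log-normal
*tempo* factor scales all dwell means (same occupancy shares, different
transition frequency), and a Beta-distributed *hard-ramp share* varies the
mild/hard mix. Without them, total distance and the LD distance sum are
almost exactly collinear across records — mild-deceleration distance is
~93% of every total — and the workload model could not separate a distance
effect from a deceleration effect. Their variances were calibrated so the
separation succeeds at study scale while the zone-distance means stay on
the reference profile.

**Exposure.** On-field time is a three-part mixture: full match, one full
half plus part of the other, or a short cameo. The mixture was calibrated
to a mean of ≈ 12.6 min (see §5 on why this sits above the 11.8 min
reference) with an SD of ≈ 2.2 min.

**Contacts.** Counts are negative binomial with mean `rate × playing time`
(rate 0.318 min⁻¹) and dispersion 7.11, chosen so that SD/mean matches
2.5/4 at the mean playing time; a Poisson count cannot carry that
overdispersion.

**RPE reports.** The latent session load is

    sRPE* = Xβ + game_effect(g) + u_j + ε,

where `X` holds the same thirteen terms the analysis model uses (see §3),
`u_j ~ N(0, σ_u)` is the athlete intercept (σ_u = 4 au), and ε is a
standardized skew-normal residual (SD σ_e = 18.5 au, shape −3). The athlete
reports `RPE = clamp(round(sRPE*/T), 0, 10)` for playing time `T` minutes,
and the report goes missing completely at random with probability 0.1565
(yielding ≈ 1002 complete records out of 1188). The analysed sRPE is the
reported RPE times `T`, which keeps the generated reports and the analysed
response internally consistent.

Two aspects of the reporting layer are deliberate. The *negative skew*
thins the residual's upper tail: with a mean report near 7.3 and a residual
SD of ~1.5 RPE units, a symmetric residual pushes an appreciable share of
latent reports past the top of the 0–10 scale, and the resulting censoring
both attenuates coefficient recovery and destabilizes the explained
variance share across seeds. Bounded effort scales compress at the top in
practice, so the skew is also the more realistic choice. Second,
`discretize_rpe=False` switches the response to the raw latent ratio
`sRPE*/T` — no rounding *and no clamping* — making it an exact linear
function of the generating model. Parameter-recovery and interval-coverage
studies use this diagnostic scale so they measure the estimator rather than
the reporting scale; all descriptive calibration and the headline
variance-explained figure use the realistic discretized scale.

**Game effect.** Additive shifts of (−21, −21, +10.5, +10.5, +10.5, +13) au
for games 1–6: early tournament games carry lower load. The magnitude is
calibrated so the downstream evaluation detects the pattern reliably;
game 6 is slightly higher than games 3–5 because only six-game tournaments
contribute game-6 records (half the sample), and the post hoc must
distinguish games 1–2 from game 6 with that reduced sample while *not*
distinguishing games 3–5 from game 6.

The generating coefficients (au per raw predictor unit) are: intercept
48.5; mass −0.9 per kg; contacts +1.7 per contact; total distance +0.28 per
m; LD distance sum −0.218 per m; LD×LS +0.035 and LD×HS +0.09 per m; all
acceleration (HA) and hard-deceleration (HD) terms zero. The signs encode
the substantive structure under study: heavier athletes report lower loads,
contacts and distance drive load up, and mild-deceleration distance
modulates it with positive low- and high-speed interactions.

Everything is seeded through a `SeedSequence` tree: identical configuration
and seed give a bit-identical dataset.

## 3. Workload model

The analysis model regresses sRPE on thirteen fixed terms — intercept,
mass, contact count, total distance, the three non-reference
acceleration-type distance sums (HA, LD, HD), and the low/high-speed cells
of each non-reference type — plus a random intercept per athlete, fitted by
REML via `statsmodels.MixedLM`. Because total distance is the sum of all
twelve cells, including all four acceleration-type sums would be exactly
collinear; LA is absorbed as the reference type (its effect lives in total
distance) and MS is the reference speed zone within each type. Mass and
contact count are fixed effects; the random structure is confined to
athlete intercepts.

Numerical choices:

* predictors are z-scored by default (zone distances span two orders of
  magnitude); estimates and standard errors are reported on both scales,
  and per-term t statistics are invariant to the choice;
* Wald t tests use residual degrees of freedom `n − 13` (the toolchain
  provides no Satterthwaite approximation; the metadata records this);
* the optimizer tries BFGS, then Powell, CG and Nelder–Mead, and raises
  only if none converges;
* a boundary (zero) athlete variance is returned as the ordinary
  least-squares solution with `σ̂_u = 0` and a warning note — that *is* the
  REML solution on the boundary;
* a response that is an exact linear function of the design (zero-noise
  simulations) short-circuits to the least-squares solution with zero
  variance components, flagged in the fit notes.

Adjusted R² is `1 − (1 − R²)(n − 1)/(n − p − 1)` with `p = 12` slopes and
R² the squared correlation between observed sRPE and fitted values. The
*conditional* variant (fixed effects + athlete BLUPs) is the headline
number; the marginal (fixed-only) variant is reported alongside since
either definition is defensible.

## 4. Evaluation across game numbers

Predicted sRPE (fixed effects + BLUP) and observed sRPE form a long table
with two rows per player-match. A two-factor ANOVA (game number × sRPE
type) is fitted by OLS with the athlete as a fixed blocking factor and
type-II sums of squares, so game and type effects are tested against
within-athlete residual error. Published repeated-measures layouts for
data of this shape are rarely reconstructible exactly — the denominator
degrees of freedom depend on unstated error-stratum choices — so
conclusions rest on the significance *pattern*, not on matching specific F
values. Post hoc: Tukey HSD over all 15 game pairs at α = 0.01, and
Holm-adjusted paired t tests of actual vs. predicted within each game.
Degenerate inputs (zero residual variance, identical pairs) report F = 0 or
p = 1 with a note rather than dividing by zero.

Because the model contains no game term, predictions are flat across games
while observations carry the game effect; the evaluation therefore finds a
strong game effect, no type effect, and a significant interaction — the
qualitative triad the pipeline is designed to reproduce.

## 5. Calibration: what the defaults mean

The generator's defaults were tuned, by iterative simulation against the
published descriptive profile, until a default seeded study reproduces:
per-record means of contacts (4), RPE (≈7), sRPE (≈99), the twelve
zone-distance means (LD rows 259.39 / 703.58 / 82.49 m), ≈1002 complete
records, and a conditional adjusted R² ≈ 0.487. Over twelve verification
seeds the defaults give R²adj 0.494 ± 0.022, sRPE 90–97, RPE 7.1–7.6,
playing time 12.5–12.8 min, and LD-row means within ±10%; ten of the twelve
non-LD zone cells also sit within ±10% of their references (the worst,
MS_HD, reaches ≈ +15% on some seeds).

One compromise is structural and worth understanding. The reference
descriptives are mutually inconsistent with `sRPE = RPE × time`: means of
7 au, 11.8 min and 99.2 au would require corr(RPE, time) ≈ 2. The generator
therefore targets playing time ≈ 12.6 min (+7%) and RPE ≈ 7.35 (+5%) so
that mean sRPE lands within 10% of 99.2 — the three means cannot all be hit
exactly by any generator with a consistent sRPE definition. Similarly, the
reference playing-time SD (4.53 min) is not reproduced: duration-driven
distance variance is *explained* variance for the model, and an SD that
large forces the explained share far above 0.537 unless residual RPE noise
is inflated past the point where the 0–10 ceiling censors reports heavily.
The generator uses SD ≈ 2.2 min; only means are calibration targets.

Scales of the validation studies (chosen to keep the default suite within a
desktop run): interval coverage uses 200 replicates of a 20-match study on
the continuous diagnostic scale; the evaluation-pattern study uses 100
replicates of an 85-match study; permutation nullity uses 50 permutations
of a 12-match study.

## 6. What passing tests do and do not show

The generator produces clean piecewise-linear speed ramps with no
measurement noise, no positional (x, y) information, no satellite error
model, and contact counts drawn independently of the kinematic
contact-brake events. Real GNSS speed series carry vendor filtering and
Doppler noise that spread distance across the acceleration columns
differently (in particular, high-frequency noise would leak mild
acceleration into the LA cells); the a = 0 → LD convention reproduces the
reference profile's LD dominance but the true preprocessing behind that
profile is unknowable from published summaries. Missingness is completely
at random on RPE only; real self-report missingness is plausibly informative.
Passing tests therefore demonstrate that the pipeline's accounting is
exact, that the estimator recovers known generating structure at realistic
noise levels, and that the published descriptive and inferential *patterns*
re-emerge under the calibrated generator — not that the generator is a
faithful model of real match play.

Known limitations: degrees of freedom are residual-based rather than
Satterthwaite; the bounded reporting scale attenuates coefficients on the
discretized response by several percent (quantified by comparing fits on
the diagnostic scale); and the evaluation ANOVA's F denominators follow the
athlete-blocking layout described above, not any specific published
repeated-measures convention.
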