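# Methods

This note documents the models implemented in `sensrec`, the choices made
where the design was genuinely open, and what the bundled simulator does and
does not establish about real data.

## Data model

A session is an ordered run of 1 Hz `SensorRecord`s on a 0-based integer
grid (wall-clock start time is metadata only). Channels — temperature (°C),
humidity (%), noise (dB), brightness (lx), air pressure (kPa), GSR
(dimensionless, ≥ 0), heart rate (bpm), and a 3-axis accelerometer — may be
individually missing and are never silently zero-filled; an optional
last-observation-carried-forward imputation works within a session only,
because 1 Hz physiological signals are locally smooth while cross-session
carry-forward has no physical meaning. Gaps in the grid are preserved and
reported, not repaired.

The 14 detector predictors follow a fixed canonical order (environment,
profile quadrants, physiology, personal). Gender is encoded male = 0,
female = 1; the accelerometer enters as the mean absolute value
(|ax|+|ay|+|az|)/3, which is invariant to axis permutation and sign.

## Sensory-profile scoring

Scoring is a sum of Likert item responses per Dunn quadrant, normalized by
the quadrant's attainable minimum and maximum to [0, 1]. The standardized
questionnaire's item bank is proprietary, so the item-to-quadrant map is a
JSON configuration; the bundled 20-item instrument (5 items per quadrant,
1–5 scale) is synthetic — it preserves the scoring mechanics, not the real
items, and carries no claim about the real instrument's polarity or item
counts.

## Labelling

Entropy is Shannon entropy in base 2; the split search evaluates midpoints
between consecutive distinct scores (a finite candidate set that contains an
information-gain maximizer) and breaks ties toward the smaller threshold so
the output is deterministic. Attention is "normal" strictly above the
threshold (default 0.6) and "low" at or below it. The stress rules cover
exactly three context cells — (relaxing, moderate) → low, (task, moderate) →
moderate, (task, extreme) → high; the (relaxing, extreme) combination is
refused rather than guessed, since the acquisition protocol never produced
it.

## Detection

scikit-learn provides the model families: `LogisticRegression`,
`KNeighborsClassifier`, `RandomForestClassifier`, `MLPClassifier` (one
hidden layer, L2 penalty λ = 1e−3, no grid search), and
`GradientBoostingClassifier`, each behind a `StandardScaler` pipeline. The
default grids are small and standard (LR C ∈ {0.01, 0.1, 1, 10}; KNN
k ∈ {3, 5, 7, 11}; RF 100/300 trees × depth {None, 5, 10}; GBDT 100/300
trees × rate {0.05, 0.1} × depth {2, 3}) and fully configurable per call.
The 80:20 split is stratified by label; grouped-by-child splitting is not
the default because the per-session feature rows are aggregates, but the
dataset retains `child_id` so callers can group if per-child leakage is a
concern. Inference time is averaged over many repeated scoring passes
because a single pass at small n is timer-noise dominated; no test or
acceptance check depends on absolute timings. Model selection is argmax
accuracy, ties broken by speed and then by a fixed family order.

Caregiver corrections are append-only: each correction adds a new training
row flagged `source="caregiver"` and increments the session's
wrong-prediction tally, so retraining after corrections can only grow the
training set.

## Fuzzy risk engine

Each controller is a Mamdani system: min for conjunction, min-clipping for
implication, pointwise max for aggregation on a 1001-point output grid over
[0, 10], then LOM defuzzification (largest x attaining the aggregated
maximum). The centroid defuzzifier is retained for comparison. The risk
category is the output term with maximal membership at the crisp value,
ties broken toward higher risk — detecting High Risk accurately is the
design priority.

Membership parameters live in `src/sensrec/data/controllers.json`. The
published exemplars fix the anchors (100/400/750 lx are low/moderate/high
brightness; 15/26/32 °C low/moderate/high temperature; 60/70/80 dB
moderate/moderate-high/high noise); the remaining breakpoints were chosen so
adjacent terms cross at membership 0.5, which guarantees the coverage
invariant (max membership ≥ 0.5 everywhere on each numeric universe) that
the engine validates at construction time. Noise uses Gaussians, the other
stimuli and duration use trapezoids; attention and stress enter as crisp
categorical terms. The reported stimulus level is the argmax term, except
that an adjacent runner-up reaching at least half the argmax membership
yields a hybrid label such as "moderate-high" (the reading adopted for
70 dB noise). These parameters are reconstructions: drop replacement values
into the JSON to re-parameterize without code changes.

The 21-rule base per controller is likewise a documented reconstruction:
five rules pin every moderate-stimulus situation at Low Risk, and for each
extreme stimulus term (Low, High) eight rules escalate risk with duration
and stress — short exposure is Low Risk unless stress is high (Medium);
medium exposure is Low rising to Medium with moderate/high stress or low
attention; long exposure is High Risk; and low attention combined with high
stress is High Risk at any duration. The base includes verbatim the two
canonical example rules ("IF temperature is High AND duration is Short THEN
Low Risk"; "… AND duration is Long THEN High Risk") and is monotone: moving
duration toward Long or stress toward high never lowers the risk category.

The two-rule LOM-vs-centroid illustration uses a dedicated demo controller
whose Short and Long duration terms overlap (production terms are disjoint,
so the two rules could never co-fire there). With a high temperature and a
duration approaching Long, both rules activate; the centroid averages the
Low- and High-Risk consequents into the Medium band while LOM returns High
Risk. On the shipped 21-combination suite LOM matches all expected
outcomes and the centroid 19/21 — the centroid misses exactly the
combinations where a High-Risk consequent competes with lower ones. The
exact centroid fraction depends on the reconstructed rule base and is not a
claim about the original system.

Duration of the atypical response is tracked as the run length of seconds in
which (attention is low OR stress is high) while the stimulus level is not
plainly moderate, resetting to zero the moment the condition clears; this
rule is a documented choice, as the stream-level computation is otherwise
unspecified. Alerts are emitted only for High-Risk assessments with an
active phone subscription; transport is out of scope and only the payload is
produced.

## Evaluation statistics

SUS: odd (positively worded) items contribute score − 1, even items
5 − score, and the contribution sum is multiplied by 2.5; by linearity the
SUS of per-item means equals the mean per-respondent SUS, so published item
means reproduce published overall scores (70.5 ASD, 68.3 TD). Cohen's d
uses the pooled SD sqrt((s₁² + s₂²)/2); this reading reproduces the
published effect-size column from the published session summaries to three
decimals in seven of eight cells — the eighth (TD attention, caregiver)
gives 0.06448 from the rounded summaries 1.6 (1.6) vs 1.5 (1.5), one unit
in the last printed digit away, an artifact of input rounding. Sample SDs
use n − 1 throughout. The paired t-test operates on per-participant
differences with a two-tailed Student p on n − 1 degrees of freedom;
reproducing published t values from group summaries alone is not possible
(the difference-score SDs are not published) and is not attempted.

## The simulator

The generator emulates the acquisition protocol: a cohort of children
(default 35 × 15 sessions of 900 s at 1 Hz, ≈ 42.6 % of sessions carrying
assessor labels), each session in one of three conditions — relaxing in a
moderate environment, tasks in a moderate environment, tasks with one
modality pushed to an extreme setting (temperature 15/32 °C, brightness
100/750 lx, noise 80 dB; moderate centers 26 °C, 400 lx, 60 dB). Latent
stress follows the labelling scheme exactly before assessor label noise
(default 5 % corruption). Task accuracy is Beta(2, 2) scaled onto the side
of the attention threshold selected by the latent attention state, so the
split search can recover the planted threshold; the probability of low
attention rises with the extremity of the regime and the child's sensory
sensitivity. Physiology is baseline (GSR 200, HR 90 bpm, accelerometer MAV
0.1 — plausible sensor units, not calibrated to any cohort) plus additive
offsets per latent stress level and for low attention, with Gaussian
per-second measurement noise; humidity and air pressure get a per-session
baseline drift (SD 4 % and 0.4 kPa) emulating day-to-day weather, which
`controlled_weather` suppresses to mimic a controlled testing room. One RNG
stream is derived per (seed, child, session), so inserting or removing
sessions perturbs nothing else and generation is byte-identical across
runs.

`SimulationConfig.strong_effects()` is the benchmark condition used by the
detector sanity checks: channel-decoupled gains (stress → GSR +100/level and
HR +20/level; low attention → movement +0.5 MAV), strengthened
regime/profile links to latent attention so both classes are well
represented, zero label noise, controlled weather. It was calibrated so
that the session means of the two targets are cleanly separable for every
model family including nearest neighbours, whose Euclidean distance is
otherwise diluted by the six child-identity feature dimensions. Under the
defaults (moderate gains, label noise on) accuracies are deliberately lower
and family-dependent.

What passing tests on simulated data do show: the pipeline's arithmetic and
contracts — label rules, split recovery, metric identities, monotone
responses, end-to-end determinism. What they do not show: that real
physiological responses are additively separable, that real attention is a
threshold function of task accuracy, or that the detectors would reach any
particular accuracy on recorded children; the original recordings are not
available and no such claim is tested.

## Numerical choices and degenerate inputs

Output grid 1001 points on [0, 10] (LOM quantization ≤ 0.01); membership
evaluation clamps inputs to the universe bounds so out-of-range sensor
readings degrade gracefully; an input activating no rule (possible only
with a user-supplied rule base) yields Low Risk with an explicit flag
rather than an error; empty aggregated sets cannot be defuzzified; entropy
of an empty label set, splits with fewer than two distinct scores, a
zero-variance paired test with nonzero mean, and an effect size with two
zero SDs all raise validation errors. Floating-point ties in LOM use a
1e−12 tolerance on the aggregated maximum.

## Known limitations

The membership parameters and rule base are reconstructions isolated in
configuration, not the original calibration; the simulator's physiology is
a monotone-effects abstraction, not a biophysical model of electrodermal or
cardiac dynamics; session invalidity (the protocol discarded a handful of
recordings) is not modelled; and the CLI covers the computational flow
only — no hardware acquisition, mobile UI, or SMS transport.
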