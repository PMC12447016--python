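# Methods

## Data model

A study is a long-format table of ratings, one row per (patient, chest
position, rater). Positions are integer codes 1–6 for the six standard
auscultation sites; their anatomic meaning is out of scope. A label is
first an interpretability judgement (does the recording contain at
least one audible breath cycle?); interpretable recordings are normal
or abnormal, and abnormal ones may carry a wheeze / crackle / both
subtype. Missing recordings are represented by absent rows — never by a
sentinel label — so "4 of 570 recordings missing" is visible only as
row counts. Subtypes are retained through I/O even though all
downstream statistics are binary, so subtype-level analyses need no
format change.

## Panel adjudication

Two primary panelists rate every recording. Agreement finalises the
label; disagreement goes to a first arbitrator, whose label is final if
it matches either primary; otherwise a second arbitrator decides
unconditionally. Agreement is judged at *trilevel* granularity by
default (uninterpretable / normal / abnormal): a wheeze-vs-crackle
split between two abnormal calls does not trigger arbitration, because
every downstream statistic is binary normal-vs-abnormal among
interpretable recordings. This is a documented design choice, not an
observed protocol detail; *full* granularity (subtype included) is
available for sensitivity analyses. When a final abnormal label draws
on two raters whose subtypes differ, the consensus subtype is the
conservative union "both"; this affects no binary statistic.

Adjudication is symmetric in the two primaries, idempotent under
unanimity, and reaches the second-arbitrator branch exactly when the
three earlier raters are pairwise distinct at the configured
granularity — all three properties are enforced by property tests.

## Patient-level classification and ensembling

A patient with no interpretable positions is uninterpretable; a patient
with at least one interpretable abnormal position is abnormal;
otherwise normal. The mixed case (some uninterpretable, rest normal) is
resolved as normal by the at-least-one-interpretable reading — the only
reading under which a cohort with uninterpretable positions scattered
across patients retains all its patients in the analysis set.

AI iterations are combined per recording by strict majority (> k/2).
An exact tie, possible only for even k, is a hard error by default; an
explicit tie policy (`abnormal` or `normal`) can be configured, never
silently applied. k is a parameter (default 5).

Paired comparisons gate on the *reference* stream's interpretability
only: the classifier is not trained on uninterpretable recordings and
contributes status alone. At position level, pairs are the
panel-interpretable recordings present in both streams; at patient
level, the patients whose panel classification is not uninterpretable.

## Agreement statistics

From the 2×2 table (a = both abnormal, b = index-only abnormal, c =
reference-only abnormal, d = both normal; n = a+b+c+d):

- raw agreement p_o = (a+d)/n;
- Cohen's kappa κ = (p_o − p_e)/(1 − p_e) with
  p_e = [(a+b)(a+c) + (c+d)(b+d)]/n²;
- Brennan–Prediger B = (p_o − 1/q)/(1 − 1/q) with q = 2 categories,
  hence B = 2·p_o − 1; B replaces the margin-based chance model with a
  fixed 1/q and is therefore robust to skewed margins.

Standard errors use the simple large-sample form √(p_o(1−p_o)/n)
scaled by 1/(1−p_e) for κ and by 1/(1−1/q) for B; intervals are
point ± z·SE with z = Φ⁻¹(0.975) = 1.959964, clamped to [−1, 1]. The
simple SE (rather than the fuller Fleiss form) is a deliberate
compatibility choice: it is the form consistent with published interval
bounds for this design at position level. Positions are correlated
within patients; the agreement SEs deliberately do **not** adjust for
this clustering (matching common practice in reports of this design) —
clustering enters only the sample-size module. Strength categories use
half-open bins with cuts at 0, 0.195, 0.395, 0.595, 0.795 — midpoints
of the conventional rounded bounds (0.19/0.20, …), so every value in
[−1, 1] falls in exactly one bin without changing any categorisation of
a value rounded to two decimals.

Marginal counts (n, reference-positive, index-positive, agreements)
determine the table uniquely: a = (ref+ + idx+ + agree − n)/2, then b,
c, d by subtraction. `reconstruct_table` rejects parity violations and
negative cells.

## Diagnostic accuracy

sens = a/(a+c), spec = d/(b+d), PPV = a/(a+b), NPV = d/(c+d),
LR+ = sens/(1−spec), LR− = (1−sens)/spec, DOR = ad/(bc) (= LR+/LR−).
Proportions get exact Clopper–Pearson intervals (beta quantiles) — the
exact interval, not Wald, is what matches published bounds for these
cell counts. Ratios get normal intervals on the log scale with
SE(ln LR+) = √(1/a − 1/(a+c) + 1/b − 1/(b+d)), the analogous form for
LR−, and SE(ln DOR) = √(1/a + 1/b + 1/c + 1/d). A ratio whose defining
cells include a zero is reported as explicitly undefined; the optional
Haldane–Anscombe 0.5 correction (applied to ratio metrics only, and
only when some cell is zero) produces finite values behind a flag,
never by default.

Display rounding is half-away-from-zero (96.25% prints 96.3): one
decimal for percentages and the DOR, two for likelihood ratios, three
for agreement statistics.

## Sample size under clustering

For an agreement proportion estimated from m recordings per participant
with intra-class correlation ρ, the design effect is
DEFF = 1 + (m−1)ρ and the participant count for half-width d at
confidence level 1−α is ceil(DEFF · z² · p(1−p) / d²), ceiling applied
once at the end. The design effect multiplies the *participant* count
(the reading under which the canonical worked example — p = 0.7,
d = 0.2, m = 6, ρ = 0.7 — yields 4.5 × 20.17 → 91 participants; the
alternative reading, inflating recordings and dividing by m, yields 15
and is documented here only to be rejected). "Precision" is an absolute
half-width; relative precision is not implemented.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes:

- **Truth.** Patient random effect u ~ N(0, σ) with σ = 1.5 by
  default; position abnormal with probability logistic(α + u). α =
  0.5256 is calibrated by Gauss quadrature so the marginal abnormality
  is 0.592 at the default σ, matching the prevalence the pipeline is
  expected to see. σ = 1.5 produces strong within-patient clustering of
  abnormality, consistent with the ICC ≈ 0.7 regime assumed in the
  design calculation.
- **Interpretability and missingness** are independent of true status
  (a documented assumption — nothing in the target study design
  constrains this) with defaults 0.12 and 4/570.
- **Raters.** Each of three primaries, two arbitrators, the clinician,
  and each AI iteration emits the truth with its sensitivity/specificity,
  conditionally independently given the truth. Correlated rater errors
  are out of scope — there is no information to calibrate them.
  Defaults: primaries 0.90/0.90, arbitrators 0.93 and 0.97 (arbitrators
  are selected for experience), clinician 0.85/0.85, AI 0.80/0.87 per
  iteration over 5 iterations.
- **Uncooperative patients** (default fraction 0.20) have the AI's
  per-iteration error odds divided by an agreement odds ratio (default
  0.51, i.e. roughly halved odds of agreeing); the mechanism is exposed
  as a parameter rather than asserted as an estimate.
- **Streams.** One global seed expands into per-stream substreams
  (truth, panelist assignment, panel, AI, clinician) via
  `numpy.random.SeedSequence.spawn`, so adding a stream never perturbs
  earlier draws, and identical configs give byte-identical output
  files.

Because iteration errors are conditionally independent, the 5-iteration
majority vote is *more* accurate than a single iteration (~0.94
sensitivity at 0.80 per iteration); a real classifier's iterations are
correlated, so a default simulation is optimistic about the ensemble
relative to the per-iteration operating point. This is the main respect
in which passing tests on synthetic data say less about real data;
others: no correlated rater errors, no dependence of interpretability
on severity, and a single cooperation covariate.

The closed-form oracle `expected_table(θ, se_r, sp_r, se_i, sp_i)`
gives the cell probabilities for two conditionally independent raters
(e.g. p_a = θ·se_r·se_i + (1−θ)(1−sp_r)(1−sp_i)) and, via
`implied_kappa`, the kappa they converge to; simulated kappa is tested
against it to within 0.01 at 50 000 positions.

## Numerical and testing choices

- Brute-force verification: every 2×2 table with n ≤ 12 (1 819 tables)
  is checked against from-definition recomputations of κ, B and the
  diagnostic metrics to 1e−12; Cohen's kappa is additionally
  cross-checked against scikit-learn's independent implementation on
  expanded label vectors.
- Degenerate inputs: p_e = 1 (both raters constant) raises a
  degenerate-statistics error for kappa; B remains defined. Diagnostic
  metrics require both reference statuses present.
- Monte-Carlo problem sizes in the test suite (200 seeds for
  calibration, 5 000 patients for parameter recovery, ~50 000 positions
  for oracle convergence) were chosen as the smallest sizes at which
  the stated tolerances (3 MC SEs; 0.01 kappa) are comfortably
  discriminating.
- Known limitations: no weighted or multi-category (> 2) kappa, no
  cluster-adjusted agreement variances, no ROC analysis, no
  correlated-error simulation.
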