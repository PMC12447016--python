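# lungpanel

Evaluation toolkit for studies that compare an automated lung-sound
classifier against a physician listening panel. It was built around a
common study design in paediatric pneumonia research: a clinician
records lung sounds at six chest positions per patient with a digital
stethoscope, a trained panel of physicians classifies each recording
(uninterpretable, normal, or abnormal — abnormal optionally subtyped
wheeze / crackle / both) through a staged arbitration process, and an
AI classifier labels the interpretable recordings. The package covers
everything downstream of the audio:

- **Annotation I/O** — long-format ratings CSV (one row per patient ×
  position × rater) with strict invariant checking.
- **Panel adjudication** — two primary panelists per recording;
  disagreement goes to a first arbitrator, persistent disagreement to a
  second arbitrator whose call is final.
- **Aggregation** — patient-level roll-up (any abnormal position makes
  the patient abnormal; all-uninterpretable makes the patient
  uninterpretable) and majority-vote ensembling of k AI iterations.
- **Agreement statistics** — raw agreement p_o, Cohen's kappa
  κ = (p_o − p_e)/(1 − p_e) with margin-based chance agreement p_e, and
  the Brennan–Prediger statistic (p_o − 1/q)/(1 − 1/q), which for q = 2
  binary categories is 2·p_o − 1; both with large-sample CIs and
  Landis–Koch-style strength categories.
- **Diagnostic accuracy** — sensitivity, specificity, PPV, NPV, LR±,
  and the diagnostic odds ratio, with Clopper–Pearson intervals for
  proportions and log-scale intervals for ratios.
- **Study design** — participant counts for estimating an agreement
  proportion with recordings clustered within patients, via the design
  effect DEFF = 1 + (m − 1)·ICC.
- **Synthetic studies** — a seeded generator with latent true status,
  patient random effects, imperfect raters, and AI iteration noise, so
  every pipeline stage can be exercised and validated without audio.

A 2×2 table can also be reconstructed from published marginal counts
(N, reference-abnormal, index-abnormal, agreements) — the four numbers
determine the cells uniquely — which makes headline statistics of a
published comparison exactly recomputable.

## Worked example

```sh
$ lungpanel reproduce-paper
=== position level (n = 497) ===
  table a/b/c/d: 236/26/58/177  agreements 413 (83.1%)
  Cohen's kappa: 0.659 (0.592, 0.725) [substantial]
  Brennan-Prediger: 0.662 (0.596, 0.728) [substantial]
  abnormal by index: 262/497 (52.7%)
  sensitivity %: 80.3 (75.3, 84.7)
  specificity %: 87.2 (81.8, 91.5)
  PPV %: 90.1 (85.8, 93.4)
  NPV %: 75.3 (69.3, 80.7)
  LR+: 6.27 (4.36, 9.01)
  LR-: 0.23 (0.18, 0.29)
  diagnostic OR: 27.7 (16.8, 45.8)
=== patient level (n = 95) ===
  table a/b/c/d: 77/5/3/10  agreements 87 (91.6%)
  Cohen's kappa: 0.665 (0.443, 0.887) [substantial]
  Brennan-Prediger: 0.832 (0.720, 0.943) [almost perfect]
  ...
=== sample size ===
  participants: 91 (p=0.7, halfwidth=0.2, m=6, icc=0.7)
```

Reading the position block: of 497 interpretable chest-position
recordings the panel called 294 abnormal and the classifier 262; they
agreed on 413 (83.1%). Kappa 0.659 means agreement is substantially
above the level the two raters' margins would produce by chance; the
near-identical Brennan–Prediger value shows the margins are balanced
enough that the choice of chance model barely matters here (at patient
level, where 84% of patients are abnormal, the two statistics diverge —
0.665 vs 0.832 — exactly because kappa penalises skewed margins). A
diagnostic odds ratio of 27.7 means the odds of an abnormal classifier
call are about 28 times higher for recordings the panel heard as
abnormal than for ones it heard as normal.

The same pipeline runs end-to-end on data, simulated or real:

```sh
lungpanel simulate --seed 7 --out study/
lungpanel run-all --ratings study/ratings.csv --out report.json
lungpanel samplesize --p 0.7 --halfwidth 0.2 --cluster-size 6 --icc 0.7
```

All subcommands are thin wrappers over the `lungpanel` Python API
(`simulate_study`, `adjudicate_study`, `ensemble_ai`,
`build_comparison`, `agreement_statistics`, `diagnostic_metrics`,
`sample_size`, `run_pipeline`).

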