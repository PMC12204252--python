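# ofc-biosig

An analysis pipeline for deriving, and transferring across pain
conditions, an EEG time-frequency biosignature of **widespread
hyperalgesia** — pain hypersensitivity at body sites anatomically
unrelated to the disease site, a marker of centrally amplified pain. It is
aimed at researchers analyzing stimulus-evoked, source-localized EEG
time-frequency responses (medial orbitofrontal cortex in particular)
together with quantitative sensory testing in chronic-pain cohorts such as
chronic low back pain (cLBP) and chronic pancreatitis (CP).

The package covers the full chain:

1. **TFR processing** — multitaper power of ROI-level trial epochs
   (1–45 Hz), per-trial dB baseline correction against the −0.3–0 s
   pre-stimulus window, trial averaging and decimation onto a T=27 × F=45
   analysis grid over 0–0.7 s post-stimulus.
2. **Phenotyping** — rule-based labels: patients rating low-force stimuli
   at an unaffected site above the control mean + 2 SD are *widespread
   hyperalgesia*, otherwise *localized pain*; treatment *responders* show a
   ≥ 30% relative reduction in pain severity.
3. **Bayesian functional mixed model** — per ROI, the T × F outcomes are
   modeled as

   `Y_ic = (x_ic' γ) · (B_t u)(B_f v)' + Z b_i + Z b_ic + ε`,

   a rank-1 (optionally rank-R) fixed-effect surface through a 5 × 10
   tensor-product cubic B-spline basis with unit-norm direction vectors
   `u, v`, group-by-condition and covariate amplitudes `γ` under
   conjugate local–global shrinkage, subject and subject-by-condition
   random surfaces, and a Jeffreys prior on the error variance — fitted by
   a fully conjugate Gibbs sampler (1500 burn-in + 500 kept draws by
   default) with automatic rank selection.
4. **Biosignature scoring** — a fixed ±1 mask (+1 on delta/theta 1–7 Hz,
   −1 on alpha 8–12 Hz, inside 0.4–0.7 s) turns each subject's mOFC
   responses into a scalar projection score.
5. **Transfer evaluation** — one-way ANOVA + Tukey–Kramer HSD on scores
   across phenotype groups of a *new* cohort, and treatment-response
   prediction from score × phenotype interaction models with leave-one-out
   cross-validated AUC/accuracy/sensitivity/specificity.

A first-class synthetic-data generator (`ofc_biosig.synthetic_data`)
reproduces the generative structure of such a study — including ground
truth for every latent quantity — so the whole pipeline is testable
without any recordings. See `docs/methods.md` for the model, priors,
generator defaults and limitations.

## Worked example

```python
from ofc_biosig import (clbp_default_config, cp_default_config,
                        generate_cohort, generate_outcomes, fit_mcmc,
                        ModelSpec, summarize_contrast, build_signature_mask,
                        score_cohort, transfer_apply, compare_models)

# 1. simulate a cLBP-style cohort (25 controls / 30 localized / 12 widespread)
clbp, truth = generate_cohort(clbp_default_config(seed=1))

# 2. fit the Bayesian functional mixed model in the left mOFC
draws = fit_mcmc(clbp, ModelSpec(roi="mOFC-left", seed=2))
cs = summarize_contrast(draws, "widespread_hyperalgesia:affected_high")
print(f"Widespread - Localized at affected-site high intensity: "
      f"{cs.mean:.2f} (90% CI [{cs.lower:.2f}, {cs.upper:.2f}])")

# 3. score everyone on the fixed +/-1 delta-theta/alpha mask
mask = build_signature_mask(clbp.grid)
scores = score_cohort(clbp, mask)
print(scores.groupby("phenotype")["score_mean"].mean().round(1))

# 4. transfer the mask to a CP-style cohort (6 / 4 / 8) and test groups
cp, _ = generate_cohort(cp_default_config(seed=3))
cp_scores, test = transfer_apply(mask, cp)
print(f"CP ANOVA: F = {test.f_stat:.2f}, p = {test.p_value:.4f}")

# 5. predict 3-month treatment response from score x phenotype
cfg = cp_default_config(seed=3)
outcomes = generate_outcomes(cfg, cp_scores.set_index("subject")["score_mean"],
                             cp_scores.set_index("subject")["phenotype"])
report = compare_models(outcomes)
print(f"interaction model:  R2 = {report.r2:.0%}, LOOCV AUC = {report.loocv_auc:.0%}")
for c in report.comparisons:
    print(f"{c.model:>18s}:  R2 = {c.r2:.0%}, LOOCV AUC = {c.loocv_auc:.0%}")
```

Output:

```
Widespread - Localized at affected-site high intensity: 9.31 (90% CI [8.42, 10.22])
phenotype
localized_pain             41.2
no_pain                    29.9
widespread_hyperalgesia    80.3
Name: score_mean, dtype: float64
CP ANOVA: F = 29.57, p = 0.0000
interaction model:  R2 = 82%, LOOCV AUC = 90%
   widespread_only:  R2 = 12%, LOOCV AUC = 62%
       three_level:  R2 = 13%, LOOCV AUC = 62%
```

Reading the numbers: the model recovers the generative
widespread-vs-localized amplitude difference of 9 (on the unit-norm
surface scale) with a tight credible interval; projection scores separate
the widespread group by ~40 dB-units from localized patients; the mask
transfers to the independent CP-style cohort (significant ANOVA), and the
regression combining the EEG score with the sensory-testing phenotype
clearly outperforms the phenotype-only models in explained variance and
cross-validated discrimination — the qualitative pattern the biosignature
is designed to exhibit.

The same workflow is scriptable from the shell:

```bash
ofc-biosig simulate --seed 1 --out runs/clbp
ofc-biosig fit --data runs/clbp --roi mOFC-left --seed 2 --out runs/draws.h5
ofc-biosig score --data runs/clbp --out runs/scores.csv
ofc-biosig run --seed 1 --out runs/full        # full pipeline + manifest
```

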