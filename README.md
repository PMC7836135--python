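# ssvepmod

Analysis pipeline for steady-state visual evoked potential (SSVEP)
experiments that probe multisensory hypersensitivity: does visceral pain
sensitivity moderate the link between visual cortical excitation and
perceived visual unpleasantness?

The package is written for researchers studying brain–behavior relationships
in at-risk pain cohorts. It covers the full path from continuous 32-channel
EEG recorded during 25 Hz pattern-reversal stimulation at five brightness
intensities, through surface-Laplacian current source density (CSD) and
Hamming-tapered 25 Hz power spectral density (PSD) estimation, to a
two-stage multilevel moderation analysis — plus a synthetic-data generator
that produces cohorts, EEG sessions and ratings with plantable effect sizes,
so every stage is testable without access to clinical data.

## The model

Within each participant *i* (level 1, one observation per brightness block
*j*, brightness codes mean-centered to −2…2):

```
PSD_ij            = b0i + b1i * brightness_ij                      (stimulation response)
Unpleasantness_ij = b0i + b1i * brightness_ij + b2i * PSD_ij       (moderation analysis)
```

Across participants (level 2), each level-1 coefficient is regressed on the
grand-mean-centered moderators — menstrual pain (VAS 0–100), somatic
symptoms (symptom-inventory sum) and bladder pain (VAS) — e.g. for the
intercepts:

```
b0i = γ00 + γ01 * menstrual_i + γ02 * somatic_i + γ03 * bladder_i
```

and analogously `γ10..γ13` for brightness slopes and `γ20..γ23` for PSD
slopes. Per-term inference uses a model-comparison sum of squares
(full vs. single-term-deleted, 1 numerator df), the full-model MSE,
`F = SS/MSE`, partial eta-squared `ηp² = SS/(SS + df_den·MSE)` and t-based
95% CIs. Exploratory electrodes are corrected per (model, term) family with
Benjamini–Hochberg FDR; the a-priori occipital channel Oz is reported
unadjusted.

## Worked example

```python
from ssvepmod import TwoStageMLM, simulate_ratings_study
from ssvepmod.synth import COVARIATES

participants, long = simulate_ratings_study(seed=1)   # 147 simulated women
model = TwoStageMLM(long, response="unpleasantness",
                    include_psd="psd_db", moderators=COVARIATES)
print(model.fit().summary("Oz"))
```

```
Two-stage multilevel model results
Electrode: Oz   participants (level-2 N): 147
Response: unpleasantness   moderators: menstrual_pain, somatic_symptoms, bladder_pain

     model             term         b     ci_lo     ci_hi        se       ss     mse       f          p      p_fdr    eta_p2
 Intercept        Intercept     7.692     7.059     8.326    0.3204     8699   15.09   576.6  4.971e-52  4.971e-52    0.8013
 Intercept   menstrual_pain  -0.01032  -0.03865   0.01802   0.01433    7.816   15.09  0.5181     0.4728     0.4728   0.00361
 Intercept somatic_symptoms   -0.4362   -0.7576   -0.1148    0.1626    108.6   15.09   7.197   0.008162   0.008162   0.04792
 Intercept     bladder_pain   0.07937   0.02557    0.1332   0.02722    128.3   15.09   8.504   0.004117   0.004117   0.05613
Brightness        Intercept     0.351    0.2207    0.4812   0.06589    18.11  0.6383   28.37  3.807e-07  3.807e-07    0.1655
...
       PSD        Intercept   0.07143  0.005494    0.1374   0.03336   0.7501  0.1636   4.585    0.03394    0.03394   0.03107
       PSD     bladder_pain  0.009473   0.00387   0.01508  0.002834    1.827  0.1636   11.17   0.001061   0.001061   0.07245
```

The level-2 intercept of the Intercept model (7.7 GBS points) is the mean
unpleasantness rating across brightness intensities; the bladder-pain row of
the PSD model (`b ≈ 0.009` GBS per dB per VAS point) is the moderation
effect of interest: participants with higher bladder pain show a steeper
unpleasantness–cortical-excitation slope.

The full EEG pipeline is driven from the command line:

```
ssvepmod all --out run1 --seed 42 --n-participants 20
```

which simulates BrainVision sessions, preprocesses them (mastoid
re-reference, 1 Hz FIR high-pass, 256 Hz downsample, 60 Hz notch, 2 s
epochs with 1 s overlap, ±100 µV rejection), applies the spherical-spline
Laplacian, extracts 25 Hz power and writes the level-1/level-2 tables,
bootstrap moderator correlations, topographic value CSVs and a run log.

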