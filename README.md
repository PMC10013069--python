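# physiofluct

Sleep-stage-resolved scaling analysis of physiological fluctuations.

During sleep, the autonomic nervous system reorganises: heartbeat,
pulse-wave, respiratory and cortical dynamics all change their
correlation structure between wakefulness, light (N2), deep (N3) and REM
sleep. `physiofluct` implements the full per-subject analysis chain that
quantifies this with detrended fluctuation analysis (DFA):

* **Preprocessing** — pulse arrivals from a photoplethysmogram by the
  intersecting-tangents method, breath maxima from nasal airflow, a
  simple R-peak picker (or externally detected R times taken verbatim),
  and 1 Hz EEG alpha-band (7–12 Hz) amplitudes via Fourier filtering and
  the Hilbert transform.
* **Interval series** — RRI, PPI and BBI series with the standard
  normality filters (RRI/PPI ∈ (330, 2000) ms, BBI ∈ (2, 8) s, each
  within 0.7–1.6× its predecessor), pulse transit times (PTT) matched in
  the (0.1, 0.8) s window after each R peak, stitching of accepted
  segments, and SDNN/RMSSD-style variability statistics.
* **Sleep staging** — cropping to the lights-off/lights-on window,
  stage episodes from a 30 s-epoch hypnogram (N1 disregarded but still
  terminating episodes), and stage-wise slicing of every series.
* **DFA2** — second-order detrended fluctuation functions per stage,
  episode-duration-weighted averaging of F², and two-regime fits: the
  short-term exponent α₁ over scales 6–16 (intervals or seconds) and the
  long-term exponent α₂ over 50–200 (12–50 breaths for respiration),
  each gated by r² > 0.9. For stationary scaling noise, α relates to the
  spectral exponent by β = 2α − 1 and to the autocorrelation decay by
  γ = 2(1 − α).
* **Cohort pipeline** — per-subject tidy result tables and group means
  with standard errors by 10-year age bin, sex, BMI class, smoking,
  alcohol, or apnea–hypopnea index class.
* **Synthetic data** — generators for noise with prescribed scaling
  exponents (Fourier spectral synthesis), two-regime noise with a
  controlled crossover, and complete synthetic subjects (event times,
  transit times, EEG envelopes, hypnograms) whose ground truth is known
  exactly, so every stage of the chain is testable without recordings.

## Worked example

```python
import numpy as np
from physiofluct import dfa
from physiofluct.synth import SubjectConfig, StageTargets, gen_subject
from physiofluct.pipeline import analyze_subject, bundle_from_synthetic

cfg = SubjectConfig(
    stage_plan=[("N2", 60), ("R", 30)],
    rri_targets={"N2": StageTargets(1.0, 0.55),
                 "R":  StageTargets(1.0, 0.95)},
)
subj = gen_subject(cfg, seed=0)
df = analyze_subject(bundle_from_synthetic(subj))
print(df[df.signal == "RRI"][["stage", "n_values",
                              "alpha1", "alpha2", "r2_2"]].to_string(index=False))
```

prints

```
stage  n_values   alpha1   alpha2     r2_2
   N2      4005 1.051923 0.614033 0.997692
    R      2007 1.073869 1.008186 0.984212
```

The heartbeat-interval series was generated with short-term exponent 1.0
in both stages and long-term targets 0.55 (N2) versus 0.95 (REM); the
recovered α₂ values (0.61 and 1.01, both with r² well above the 0.9
acceptance gate) reproduce the non-REM versus REM contrast: long-term
heartbeat correlations are strongly persistent in REM and much weaker in
light sleep.

The same chain runs from the command line:

```bash
physiofluct synth --seed 1 --n-subjects 5 --out subjects/
physiofluct analyze --config run.yaml --out results/
physiofluct aggregate --results results/subject_results.csv --by age
```

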