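# milsurv

Weakly-supervised survival analysis for whole-slide images (WSIs), built
around attention-based multiple-instance learning (MIL) and discrete-time
hazards. The package is aimed at computational-pathology researchers who
want to predict patient-level prognosis (e.g., overall survival in ovarian
cancer) from H&E slides when only slide-level outcomes — never pixel
labels — are available.

## The model

A slide is reduced to a *bag* of patch feature vectors
`X = {x_1, …, x_M}`, `x_m ∈ R^d`: tissue is segmented from the glass
background (HSV-saturation thresholding), tiled into non-overlapping
256×256 patches at the highest resolution level, and each patch is encoded
by a pluggable encoder (a pretrained CNN in production; a deterministic
statistics-projection encoder for testing, `d = 32`).

The network embeds patches (`h_m = ReLU(W x_m)`), pools them with gated
attention,

    s_m = w^T ( tanh(V h_m) ⊙ σ(U h_m) ),    a = softmax(s),
    pooled = Σ_m a_m h_m,

and a two-layer head emits one conditional hazard per survival interval:

    f_hazard(r | x) = P(T = r | T ≥ r, x) = σ(logit_r),    r = 0..3.

Overall survival is discretized into four right-open intervals at the
quartiles of the uncensored event times. The survival function is
`f_surv(r | x) = Π_{u≤r} (1 − f_hazard(u | x))` and the patient risk score
is the sum of the four hazards. With censoring indicator `c` (1 =
right-censored) the training loss is

    L = −c·log f_surv(Y | x) − (1−c)·log[ f_surv(Y−1 | x) · f_hazard(Y | x) ]
    L_surv = (1−α)·L + α·L_uncensored,       α = 0.31,

optimized with Adam (lr 2e-4, cosine annealing, one bag per step, 40
epochs) under 5-fold cross-validation stratified on censoring. Patients
are stratified into high/low risk groups at the median risk score and the
groups are compared with Kaplan–Meier curves, the log-rank test, Harrell's
concordance index and IPCW time-dependent AUC. An HRD
(homologous-recombination-deficiency) utility scores TAI + LST + LOH with
positivity strictly above 42.

Everything is implemented in NumPy with hand-derived, finite-difference-
verified gradients; no deep-learning framework is required.

Because real WSIs are gigabytes, the package ships a synthetic-cohort
generator that plants a known low-dimensional prognostic signal inside
patch bags (a per-patient subset of patches shifted along a hidden
direction; per-interval hazards driven by the planted risk; calibrated
independent right-censoring), so the entire pipeline is testable and its
recovery behavior measurable on a laptop.

## Worked example

```python
import numpy as np
from milsurv import (SyntheticConfig, TrainConfig, generate_cohort,
                     cross_validate, median_split, logrank_test)

cohort = generate_cohort(SyntheticConfig(n_patients=100, seed=3))
cv = cross_validate(cohort.bags, cohort.clinical, TrainConfig(epochs=20, seed=0))
print(np.round(cv.cindexes, 3), round(cv.mean_cindex, 4))

times = np.array([r.os_months for r in cohort.clinical])
cens  = np.array([r.censored  for r in cohort.clinical])
high  = median_split(cv.oof_risks) == "high"
res = logrank_test(times[high], cens[high], times[~high], cens[~high])
print(f"log-rank chi2 = {res.statistic:.2f}, p = {res.p_value:.2e}")
```

prints

```
[0.685 0.791 0.832 0.719 0.772] 0.7598
log-rank chi2 = 41.40, p = 1.24e-10
```

i.e., out-of-fold risk scores concordant with observed survival in ~76% of
comparable patient pairs, and a median split whose two Kaplan–Meier curves
are separated far beyond chance. The `examples/` directory holds one short
script per capability (cohort synthesis, segmentation/tiling/encoding,
hazard arithmetic, training + stratification, the orchestrated pipeline,
HRD scoring).

A thin CLI mirrors the stages: `milsurv synth | preprocess | train |
evaluate | run` (see `milsurv --help`).

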