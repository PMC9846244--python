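# Methods

## Problem and model

The package estimates patient-level prognosis from a whole-slide image
represented as a bag of M patch feature vectors with a single slide-level
outcome (overall survival with right censoring). Survival time is
discretized into `n_intervals = 4` right-open intervals whose cut points
are the 25/50/75th percentiles (linear-interpolation definition) of the
*uncensored* event times in the training split, so events spread evenly
across intervals; the per-interval counts of uncensored training cases
differ by at most one. Censored times beyond the last cut point receive
the final interval label and contribute only the survival term of the
loss. The boundary convention is right-open: a time exactly equal to a cut
point belongs to the later interval, and if all uncensored times are
identical (all three cuts equal) only earlier times get interval 0 while
the common value lands in the last interval.

The network is: linear projection d→d_h with ReLU; gated attention
(`tanh ⊙ sigmoid`, with a plain-`tanh` variant behind a config switch)
producing softmax weights that form a convex combination of patch
embeddings; and a two-layer head d_h→d_p→4 whose logits pass through
*per-interval sigmoids*. Sigmoid rather than softmax because the four
outputs are conditional probabilities `P(T = r | T ≥ r, x)`, not
competing classes. The risk score is the sum of the four hazards, so it
lies in (0, 4); higher risk means earlier expected death by construction
of the hazard model. The survival product starts at interval 0 with the
empty-product convention `S(-1) = 1`, which makes the uncensored
likelihood term `S(Y-1)·h(Y)` well defined at `Y = 0`.

The loss mixes the full negative log-likelihood with the uncensored term,
`L_surv = (1-α)L + α·L_uncensored`, `α = 0.31` by default. For an
uncensored case `L = L_uncensored`, so the mix is the identity — the α
weight only down-weights censored cases. Probabilities are clamped at
`ε = 1e-7` inside logarithms.

## Optimization

All forward and backward passes are NumPy; gradients are derived by hand
and verified against central finite differences (loss-level to 1e-5
relative, full network to ~1e-4). Adam uses β1 = 0.9 ("momentum"),
β2 = 0.999, with an initial learning rate of 2e-4 decayed by cosine
annealing over the epochs; one bag per optimizer step; 40 epochs; He/
Glorot-style initialization from a fixed seed, so runs are bit
reproducible. The garbled-looking hyperparameter triple in common MIL
survival configurations is resolved here as batch = 1, epochs = 40,
α = 0.31, each overridable.

Head widths default to `d_h = max(64, d/4)`, `d_a = d_p = d_h/2`
(256/128/128 at d = 1024). The floor of 64 at small test dimensions is
deliberate: with one-bag batches at this learning-rate budget, very narrow
heads (e.g. 16 units) optimize noticeably less reliably while the
parameter count is negligible either way.

Cross-validation is 5-fold, stratified on the censoring indicator
(scikit-learn `StratifiedKFold`), so each test fold matches the cohort's
censored fraction to within one case; on a 90-case cohort with 30 censored
this yields 72/18 train/test splits with exactly 6 censored cases per test
fold. The interval scheme is recomputed from each training split only —
the test fold never influences the cut points. Each patient receives
exactly one out-of-fold risk score.

## Evaluation conventions

* **Concordance index** (Harrell): a pair is comparable iff the shorter
  observed time belongs to an uncensored case; time ties between two
  events are excluded, a tie between an event and a censored case counts
  the event as earlier; risk ties earn 0.5. The orientation is explicit:
  the default scores "higher risk ⇒ earlier event" (natural for a
  hazard-sum risk), and the flipped orientation is available because on
  some real cohorts the learned score has been reported with the opposite
  association; results record which orientation was used.
* **Kaplan–Meier**: product-limit estimator; at tied times events are
  counted before censored exits leave the risk set.
* **Log-rank**: two-group observed-minus-expected with the hypergeometric
  variance; identical groups give statistic exactly 0 and p = 1.
* **Median split**: scores strictly above the linear-interpolation median
  are "high"; ties at the median go low (a documented convention, not a
  claim about any external implementation). All-identical scores emit a
  warning and label everyone low.
* **Time-dependent AUC**: cumulative/dynamic definition with inverse
  probability of censoring weights from the Kaplan–Meier estimate of the
  censoring distribution evaluated just before the event time; without
  censoring it reduces exactly to the Mann–Whitney AUC. Cases censored at
  or before the horizon carry no weight.
* **HRD**: score = TAI + LST + LOH, positive strictly above 42.
* Two-sample comparisons (t, Wilcoxon rank-sum, chi-square, Spearman)
  delegate to scipy; the t-test also accepts summary form (mean, sd, n)
  with pooled variance for table-style inputs.

These implementations are cross-checked in the test suite against
lifelines and scikit-survival (agreement to ≤1e-9) and against exhaustive
brute-force pair enumeration for the C-index.

## Synthetic cohorts: what they emulate, and what they do not

Each patient j gets a bag of `M_j ~ U{16..64}` feature vectors in
d = 32 dimensions (the production dimension is 1024; nothing in the code
depends on which). Background patches are iid standard normal. A
per-patient subset of *informative* patches is additionally shifted by
`signal_strength = 3` along one cohort-level unit direction u, giving the
attention a consistent target. The informative fraction is drawn per
patient as `informative_fraction × Beta(0.3, 0.3)` — a U-shaped law
emulating the wide slide-to-slide spread of tumor content; the latent risk
is `z_j = signal_strength × (realized fraction)`. Per-interval hazards are
`logistic(logit(baseline) + β z_j)` with `β = 1.5` and baseline hazards
(0.03, 0.06, 0.10, 0.15); the event interval is sampled sequentially with
survivors absorbed into the last interval.

The fraction law and baselines were fixed once, from a direct large-n
simulation of the generator itself: they put the Bayes-attainable
(true-risk) concordance on the continuous-month scale at ≈ 0.78, which is
the ceiling any estimator can reach under this planting. With a constant
or uniform fraction the planted contrast is weaker and no method can
exceed ≈ 0.72, which would make "recover the signal" an unreachable bar
rather than a test of the network.

Censoring is entry-independent: the censoring interval follows a geometric
law whose per-interval hazard is calibrated by bisection so the expected
censored fraction equals `censoring_rate` (default 1/3, matching a
60/30 uncensored/censored reference split at n = 90). A patient whose
event and censoring land in the same interval counts as uncensored.
Continuous months are synthesized uniformly inside the labeled 12-month
interval so Kaplan–Meier/log-rank operate on a time axis; the model itself
consumes interval labels. Within-interval ordering is therefore pure
noise — this is what caps the months-scale concordance below the
label-scale one.

Synthetic slides are white images with elliptical "tissue" blobs in an
H&E-like pink/purple band plus exact ground-truth masks; they exercise
segmentation and tiling geometry only. No stain texture, nuclei,
pen marks, or pyramid levels are simulated, so passing tests demonstrate
the geometry and the learning mechanics, not robustness to real staining
variation.

## Known limitations

* **Attention localization is not identified under fraction-coded risk.**
  When the bag-level signal is the *fraction* of informative patches, mean
  pooling already suffices, and attention that tilts toward or away from
  informative patches encodes the fraction equally well. Trained models
  end up on either side depending on the initialization seed (measured:
  positive tilt in roughly a fifth to a third of seeds, mean slightly
  negative). The attention-contrast diagnostic is therefore reported but
  should not be expected to exceed chance under this planting; attention
  localization claims require a planting where bag outcome depends on
  patch *presence*, not abundance.
* The test encoder summarizes color statistics only; it is a contract
  stand-in, not a perceptual feature extractor. A pretrained CNN backend
  can be plugged in behind the same patch→vector contract.
* Real-WSI pyramid reading is an adapter concern; the preprocessing here
  operates on single-level raster images.
* Problem sizes in the shipped protocols (cohorts of 200–300, 20 seeds,
  five folds) were chosen so the full suite runs on one CPU core in
  minutes; they are large enough that the reported fractions and means are
  stable to the tolerances asserted.
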