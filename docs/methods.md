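# Methods

`felacc` re-implements, as a tested Python pipeline, a complete
accelerometer-to-behaviour workflow for domestic cats wearing two
triaxial accelerometers (collar and harness). This note records the
models, the parameters that matter, the synthetic-data assumptions, and
the numerical choices made where the design was genuinely open.

## Study design emulated

Twelve cats wear two 30 Hz, ±8 g triaxial accelerometers (one on a
collar, one on a harness) for seven consecutive days. Behaviour is
video-scored at 1 s resolution for one five-hour window (09:00–14:00)
on day 1, against a 24-behaviour ethogram organised into four
categories: *active* (climbing, jumping horizontal/vertical, fighting,
playing, rolling, rubbing, running, trotting, walking), *inactive*
(lying, sitting, standing), *maintenance* (digging, drinking, eating,
grooming, littering, scratching, shaking) and *other* (other, out of
sight, allogrooming, human contact).

## Identifier variables

Each 1 s epoch (30 samples) yields 32 features: per axis the mean, sum,
min, max, sd, skewness and kurtosis (21); pairwise Pearson correlations
r_XY, r_XZ, r_YZ (3); the same seven moment statistics of the
per-sample vector magnitude VM = √(X²+Y²+Z²) (7); and ODBA (1). ODBA
smooths each axis with a centred 1 s moving average (edge-truncated;
offsets −14…+15 for the even 30-sample window), takes per-sample
residuals, and sums |res_X|+|res_Y|+|res_Z| over the epoch.

Conventions where the construction is ambiguous:

* **DBA.** "Sum_axis − moving average" is dimensionally ambiguous; the
  default implements the standard ODBA construction (absolute
  per-sample residuals summed over the epoch). A literal mode
  (`dba_mode="as_printed"`: signed epoch residual sums added across
  axes) is available.
* **sd** is the sample standard deviation (ddof = 1, configurable);
  **skewness/kurtosis** are population moment estimators (biased,
  kurtosis non-excess: a normal window → 3).
* Zero-variance windows make skewness, kurtosis and correlations
  undefined; these are encoded 0.0 with a degenerate-epoch flag so
  classifiers never see missing values.
* Trailing partial epochs are dropped. Epoch *k* covers samples
  [30k, 30(k+1)); annotation second *s* joins the epoch at the same
  wall-clock second, with an optional device/video clock offset
  (default 0).

## Preprocessing

Study-pooled rules, each removed second attributed to exactly one
reason: unobserved behaviours drop out; behaviours with fewer than 11 s
observed (i.e. n ≤ 10) are too rare to model; the two scoring
bookkeeping labels "out of sight" and "other" are removed (allogrooming,
although catalogued under *other*, is a real behaviour and is kept);
"jumping horizontal" and "jumping vertical" merge into "jumping".
Applied to the original study's printed counts these rules leave exactly
15 classes for the first modelling round.

Classes above 7000 datapoints are down-sampled to 7000 (5000 in the
final round) by seeded uniform sampling without replacement, guarding
against over-fitting to abundant behaviours (lying alone is ~half the
data). The 70/30 train/test split is stratified by class — the source
procedure states only the proportions; stratification prevents rare
classes from vanishing from the test set — and single-row classes go to
train with a warning.

## Classifiers

**Random forest** (scikit-learn): 500 trees, ⌊√32⌋ = 5 candidate
features per split (a literal mtry = 32 is configurable), majority
vote, features used raw (trees are scale-invariant), `n_jobs=1` and a
fixed seed for determinism.

**Supervised self-organizing map** (implemented here, numba-compiled
training loop): an 8×6 hexagonal Kohonen map whose units carry two
fused codebooks — a 32-vector feature layer and a one-hot class layer.
Features are z-scored on training statistics only. The winner minimises
`(1−w)·d_feat/s_feat + w·d_class/s_class` with w = 0.5 and per-layer
scales s maintained as running means (EMA, rate 1e-3) of the mean
unit distance — this keeps a 32-dimensional squared distance
commensurable with a one-hot distance. Winner and neighbours update
toward the sample in both layers with a Gaussian grid kernel; learning
rate decays linearly 0.05 → 0.01 and radius from ⅔ of the map diagonal
to 1 over the whole run; each of rlen = 100 passes presents all
training samples in seeded random order. Prediction uses the feature
layer only; the label is the argmax of the winning unit's class
codebook. Only rlen = 100 is inherited from the original workflow; the
grid size, topology, learning rates and neighbourhood mirror the
documented defaults of the R `kohonen` toolkit and are recorded here as
assumptions.

## Modelling rounds

Each round maps labels (merge/remove), caps classes, splits 70/30,
trains, and evaluates on the held-out split with per-class one-vs-rest
metrics, micro overall accuracy (trace/N) and Cohen's kappa

κ̂ = (N·Σxᵢᵢ − Σxᵢ₊x₊ᵢ) / (N² − Σxᵢ₊x₊ᵢ),

interpreted on Fleiss bands (>0.75 excellent, 0.40–0.75 fair-to-good,
<0.40 poor). Per-class specificity defaults to the as-printed
TN/(TN+FN); the textbook TN/(TN+FP) is one flag away, and the mode is
part of every report. Undefined ratios (zero denominators, e.g.
precision of a never-predicted class) propagate as flags, never as 0 —
except sensitivity with TP = 0, FN > 0, which is a true 0.

The fixed four-round plan reproduces the original selection: round 1 is
the identity over the 15 classes; round 2 removes climbing, jumping,
rubbing, digging, shaking and allogrooming (small samples) and merges
trotting + walking into "active" (8 classes); round 3 merges scratching
into grooming and drops littering (6 classes); round 4 collapses to the
three categories with the 5000 cap. In auto mode the next plan is
derived from the confusion matrix: a class with TP = 0 or sensitivity
< 0.20 (the source never quantifies "low"; 0.20 is configurable) merges
into its largest off-diagonal row target if the ethogram categories
match, otherwise it is removed; ties break toward the more frequent
target; merge chains/cycles are resolved deterministically. The loop
stops when neither overall accuracy nor κ improves (ε = 0) or at three
classes.

Open choices made here: every round re-applies its composed mapping to
the *full* preprocessed dataset and caps afresh (so a merged class is
re-limited, and removed behaviours never return); labels outside a
fixed plan's domain are dropped with a log line rather than raising, so
the protocol is executable on any seeded study regardless of which rare
behaviours crossed the 11 s threshold.

## Activity budgets and Dirichlet regression

Final models classify every epoch of whole unannotated days; class
frequencies normalised per cat-day give activity budgets. Budgets are
compared with a Dirichlet regression in the common parametrisation with
log link, α_k(x) = exp(xᵀβ_k), covariates mount, technique and day
(categorical, first level reference, treatment coding). Zeros —
classifiers routinely predict a behaviour 0% of a day — are handled
with the standard compositional adjustment y* = (y(n−1) + 1/K)/n before
fitting. The likelihood is maximised by BFGS with the analytic gradient
from a method-of-moments start; standard errors come from the inverse
observed information (numerical Hessian at the optimum); Wald z = β̂/se
gives two-sided p-values, reported raw (no multiplicity correction).
Non-convergence flags the result instead of raising.

## Synthetic data: what it emulates and what it does not

The generator produces the study design above with known ground truth.
Behaviour sequences follow a semi-Markov chain: gamma bout durations
(mean `mean_dwell`, shape 2 by default, rounded up to whole seconds —
note the ceiling adds ≈0.5 s to realised means) and successor draws
proportional to per-behaviour entry weights (zero diagonal), so time
occupancy ≈ weight × dwell. Default weights and dwells make lying
(~48%) and sitting (~26%) dominate, with standing and grooming near 8%,
eating ~4%, walking ~3% and the rest rare — a realistic colony-cat
budget. Fighting and playing are set rare enough to fall under the 11 s
removal threshold, mirroring their fate in the original data.

Each behaviour has a body-frame signature: 1 g of gravity along a
posture-specific unit vector, a sinusoid of amplitude `dyn_amp` at
`gait_freq` on the craniocaudal axis, and isotropic Gaussian noise.
Device axes follow the mounting conventions (collar X/Y/Z =
lateral/dorsoventral/craniocaudal; harness X/Y/Z reversed order).
Collar traces additionally get an Ornstein–Uhlenbeck rotational drift
about the neck axis (stationary sd 0.25 rad, τ = 30 s) and a damped
0.3 g, 3 Hz ring for ~2.5 s after every active→inactive transition —
the loose-attachment artefacts that motivate comparing mounts. 25% of
annotated seconds are relabelled "out of sight"/"other" (9:1) to
exercise filtering, approximating the original exclusion share.

Because no per-behaviour acceleration statistics were ever published
for the real animals, signatures are statistical stand-ins chosen for
separability with realistic structure (scratching deliberately
resembles grooming; trotting resembles walking), not a biomechanical
cat model. Passing tests therefore demonstrate that the *pipeline*
(features → models → rounds → budgets) is correct and that the
protocol behaves as described under controlled signal-to-noise; they do
not certify classification accuracy on real cats.

## Problem sizes and determinism

The default study yields 216,000 annotated epochs per mount (12 cats ×
5 h), ~41,000 datapoints per mount after filtering and the 7000 cap —
the same order as the original 124,230-point dataset after capping.
The full 16-model protocol runs in a few minutes on one CPU; tests use
2-cat, 15-minute studies except where the full-scale protocol itself is
under test. Every stage derives its randomness from a single seed
through named `SeedSequence` streams (per cat, mount, day, round), so
any artefact is independently reproducible; model archives embed their
parameters, class sets and feature-schema hash and refuse mismatched
schemas or archive versions.

## Known limitations

* The SOM map geometry and neighbourhood are assumptions (see above).
* Eq-style specificity (TN/(TN+FN)) is reported by default for
  comparability, although TN/(TN+FP) is the conventional definition.
* The Dirichlet mean/precision ("alternative") parametrisation is not
  implemented; only the common parametrisation with log link.
* No significance test accompanies κ (the upstream p-value's test is
  unstated); no bootstrap CIs for per-class metrics.
* The generator has no inter-cat variability in signatures and no
  diurnal structure; days are statistically exchangeable.
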