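# Methods

`spiketau` implements a complete analysis chain for intrinsic neural
timescales in trial-structured spiking data, together with a synthetic
spike-train generator with known ground truth that stands in for recorded
data.  This note documents the models, the tunable parameters that matter,
the numerical choices, and what the synthetic world does and does not
establish.

## Intrinsic timescale estimation

Baseline-epoch spikes (default: the 300 ms before stimulus onset, i.e. the
half-open window [200, 500) ms of each trial) are binned at 10 ms.  The
across-trial mean of each bin is subtracted, removing stimulus-locked and
slow-rate structure, and the lag-k autocorrelation is

    ac(k) = mean over trials of [ sum_i r_i r_{i+k} / (n_bins - k) ],

scaled by ac(0) so the profile starts at 1.  Dividing by the pair count
(n_bins − k) makes each lag's estimate unbiased in pair number; because all
trials share the bin count, it cancels after the zero-lag scaling and is a
pure normalization convention.

The profile from its peak lag onward (excluding lag 0; refractoriness
often depresses the first lag) is fit with

    f(lag) = A * (exp(-lag / tau) + B)

by bounded least squares (Trust Region Reflective; bounds tau ∈ [1, 500] ms,
A ∈ [0, 10], B ∈ [−1, 1]).  Initialization is deterministic and
scale-aware: tau0 is the lag where the profile first falls below 1/e of its
peak, A0 the peak value, B0 the mean of the last three lags.  Ties at the
peak break toward the smaller lag.  Goodness of fit is the pseudo-R² over
the fitted lags; precision is CV = SE(tau)/tau with SE from the
least-squares covariance (local curvature).  Fits with R² < 0.3 or
non-convergence are excluded; profiles whose maximum sits at (or within
three lags of) the final lag are unfittable and excluded as "no-decay".

Known behaviour: with 300 ms windows the likelihood surface for long
timescales has a tau–B ridge, so individual long-tau estimates are
right-skewed (occasionally hitting the 500 ms bound) even when the median
is accurate.  Split-half stability (first vs second half of a session's
trials, Spearman correlation over neurons passing QC in both halves) is the
intended diagnostic for this noise.

Baseline descriptives: firing rate = total spikes / (trials × window);
temporal variability = population SD across bins of the across-trial mean
count divided by its mean (scale-invariant); trial-to-trial variability =
Fano factor of per-trial totals.

## Bimodality testing and classification

The excess-mass statistic for one vs two modes equals twice Hartigan's dip
(the sup-distance from the empirical CDF to the nearest unimodal CDF).  The
dip is computed from its tube characterization: F_n is within t of a
unimodal CDF exactly when a nondecreasing convex-then-concave path passes
through every gate [F_n−t, F_n+t] evaluated at both corners of every CDF
step.  For fixed t, feasibility is decided in O(n²) by propagating extremal
tangent-line bounds (smallest convex-prefix arrival height, largest
concave-suffix departure height) and scanning mode positions; the dip is
the critical t found by bisection to ~1e-15.  The implementation is
validated in the test suite against an independent linear-programming
transcription of the same definition (agreement to 1e-14 on random
samples).  Ties are supported (atoms collapse to single steps).

The p-value uses a smoothed bootstrap from the nearest unimodal density:
a Gaussian KDE of the data at its critical bandwidth (the smallest
bandwidth at which the density is unimodal, found by bisection), rescaled
to preserve the sample variance; p = (1 + #{stat* ≥ stat})/(1 + B), default
B = 500.  Calibration on unimodal normal samples is checked in the suite
(rejection rate within the exact binomial band around α = 0.05).

Classification uses a Gaussian KDE of the pooled timescales on the linear
axis with a robust Silverman bandwidth (0.9·min(SD, IQR/1.349)·n^(−1/5) —
robust so that a handful of boundary-valued estimates cannot oversmooth
the density).  Local maxima below 2% of the peak density are ignored when counting
modes (tail ripples from isolated extreme values are not modes).  The
threshold is the density minimum between the two tallest remaining modes;
tau < threshold → "short", tau ≥ threshold → "long".  A single-mode
density returns a unimodal signal instead of a threshold.

## Visual indices and onsets

The receptive field (RF) is the set of locations whose mean single-stimulus
rate in the 50–500 ms response window strictly exceeds 95% of the maximum;
the four far-right-column grid locations are the fixed Out-RF controls and
are removed from any overlapping RF.  The visual index per stimulus type
(single/popout) and period (transient [50, 200) ms, sustained [200, 500) ms
after onset) is (In − Out)/(In + Out) of the trial-mean rates; it is NaN
when both means are zero.  RFs are estimated from control trials and reused
under inactivation so the In/Out definition is fixed across the contrast
(a re-estimation flag exists).

Onset latency: threshold = mean + 2·SD (population SD across baseline bins
of the trial-averaged counts — one stable threshold per neuron); onset is
the leading bin of the first run of ≥ 2 consecutive post-stimulus bins
strictly above threshold, searched over the full 500 ms stimulus period.
A silent baseline gives threshold 0, so any active bin pair triggers
(documented degenerate case).

## Regression and contrasts

The linkage model regresses per-neuron timescale on the four indices plus
baseline rate by Huber M-estimation (tuning constant 1.345, MAD scale,
IRLS to coefficient convergence 1e-10; statsmodels RLM supplies the
solver).  Because residuals are heavy-tailed, coefficient inference is by
permutation: the response is shuffled (default 10,000 times), the robust
model refit, and p = (1 + #{|β*| ≥ |β̂|})/(1 + n_perm) — the +1 correction
keeps p-values valid (the plain proportion could reach 0).  A permutation
refit that fails counts as an exceedance (conservative).  Multicollinearity
is screened with VIF = 1/(1 − R²_j) from OLS of each predictor on the rest.
Listwise deletion handles missing indices; the Q–Q inspection of residuals
is replaced by a reported normality statistic in the result object.

Rank tests use exact nulls below n = 26 per group (no ties) and the
continuity-corrected normal approximation otherwise.  Effect sizes:
rank-sum r = 1 − 2U/(n₁n₂) (positive when the first sample ranks lower),
signed-rank r = (W⁺ − W⁻)/(W⁺ + W⁻).  The two-sample Cramér–von Mises test
takes its statistic from scipy and its p-value from label permutation
(default 9,999), switching to exhaustive enumeration when the number of
label assignments is small.  Multiple comparisons use Benjamini–Hochberg.

## Neuron-dropping decoding

Pseudo-populations combine separately recorded (or simulated) neurons by
matching trial labels.  Features are per-trial rates in the transient or
sustained window; detectability labels trials In-RF vs Out-RF,
discriminability labels all 24 grid locations.  Neurons with fewer than 20
trials in any class are excluded and every class is subsampled to the
global minimum count, so each neuron contributes the same balanced block.

Each decode: sample n neurons without replacement, shuffle each neuron's
class-matched trials independently, concatenate into pseudo-trials, split
stratified 70/30 on the labels as given (critically: after any label
permutation — stratifying on pre-permutation structure induces the classic
below-chance bias of null decoding), standardize with training statistics,
project onto the top three principal components fit on the training split
only, and score a linear SVM (C = 1).  Curves run sizes 3–120 (step 1 for
detectability, 2 for discriminability) with 500 iterations per size.

The chance band per size is the 2.5th/97.5th percentile of binomial
accuracy draws at the chance probability (0.5 or 1/24) with the test-trial
count from simulating the sampling/splitting procedure (default 1000
draws).  Normalized AUC clips the accuracy curve below at the band's upper
bound, integrates the excess by the trapezoid rule, and divides by the
area between perfect accuracy and the bound; the AUC sampling distribution
partitions the 500 iterations into 100 non-overlapping groups of 5.
Degenerate splits retry up to 10 times, then error.

## The synthetic world

Baseline activity is a doubly stochastic Poisson process: a stationary
AR(1) log-rate on a 1 ms grid, exponentiated with a variance-correcting
mean adjustment so the rate is positive with exact mean and CV, thinned by
per-step Bernoulli draws (rate·dt ≪ 1).  The exponential link distorts the
rate autocorrelation — (e^{σ²ρ}−1)/(e^{σ²}−1) for log-rate correlation ρ —
enough at the default fluctuation CV to bias recovered timescales by
roughly −20%, so the AR constant is calibrated in closed form so the rate
autocorrelation crosses 1/e at exactly the requested tau; the residual
shape misfit is a few percent, which is why recovery checks use tolerances.

Default parameters and their anchors:

- class sizes 168/212 and class centers 27.34/102.64 ms: the reported
  population.  The class SDs default to 15/8 ms — deliberately below the
  reported 16.5/23.3 ms, because those describe *estimated* timescales and
  therefore already contain estimation noise that the analysis re-adds; a
  reported median CV of ~0.22 implies noise of ~6 ms at tau ≈ 27 and
  ~23 ms at tau ≈ 103, i.e. essentially the whole long-class spread.
- tau floor 5 ms (draws below are redrawn): the 1 ms simulation step needs
  dt ≤ tau/5 for a faithful AR(1) discretization.
- latent-rate fluctuation CV 1.0 and baseline rate 25 spikes/s (mild
  log-normal heterogeneity, CV 0.3): chosen so the *estimated* timescale
  distribution reproduces the reported shape — a bimodal density with a
  valley near 60 ms, group spreads of roughly 16/50 ms, ~6% of units
  excluded at R² < 0.3, and split-half stability rho ≈ 0.7.  At these
  settings fit-precision statistics come out somewhat better (R² ≈ 0.9,
  CV ≈ 0.14) than the reported 0.78/0.22; under this noise model the
  reported precision and the reported distribution shape cannot both be
  matched, and the distribution shape is the anchor the classification
  and class-contrast stages actually depend on.
- evoked responses: multiplicative gains on the latent rate in the
  transient/sustained windows, spatially weighted (1 at the RF peak, 0.5
  for grid neighbours, 0 elsewhere and always 0 in the far-right Out-RF
  column; peaks are drawn away from that column).  Short-class neurons get
  the strongest transient single-stimulus gain (4.0); long-class neurons
  the strongest sustained popout gain (2.5 vs 1.6) — the short-class
  sustained popout gain is set high enough that its decoder is clearly
  above chance, since relative AUC changes are meaningless at chance.
- inactivation: tau ×2.0 (short) / ×1.05 (long), sustained-popout gain
  modulation ×0.85 (short) / ×0.5 (long), baseline +0.93 spikes/s — the
  reported direction and rough magnitude of the manipulation effects.
- depths: overlapping normals at 900/1350 µm (short shallower), matching
  the reported medians.

RNG streams are split per (neuron, condition) from the master seed, so
enlarging a population never perturbs existing neurons' draws, and every
run is byte-reproducible.

What the generator does **not** emulate: refractory dips in the
autocorrelation (the fit-start rule is exercised by constructed profiles in
the tests instead), multi-timescale or oscillatory baseline structure,
spike-sorting artifacts, session-level correlations between simultaneously
recorded neurons (pseudo-trials are exchangeable by construction), and eye
movements.  A green end-to-end test therefore establishes that the
pipeline recovers the statistical structure it assumes — not that the
assumed structure exhausts real recordings.

## Numerical details worth knowing

- All windows are half-open [start, end); a spike at exactly a boundary
  belongs to the later bin/window.  Binning is floor-based, not
  `np.histogram` (whose final bin is closed).
- "Exceeds 95% of maximum" and "exceeding the onset threshold" are strict
  inequalities; R² ≥ 0.3 keeps the boundary; tau = threshold classifies as
  "long".
- The dip bisection brackets t from the heaviest tie group's half-mass to
  0.26 and runs 52 halvings; the excess-mass statistic is affine-invariant
  by construction.
- Permutation p-values are +1-corrected everywhere; their minimum is
  1/(n_perm + 1).
- The pipeline driver records package version, config hash and master seed
  in `run_meta.json`, and every stage can be re-run bit-identically from
  saved upstream artifacts.
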