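# Methods

`erfield` estimates spatiotemporal *electrical receptive fields* (ERFs) of
retinal ganglion cells (RGCs) from multi-electrode pulse stimulation.  The
recorded quantity is a spike count per inter-pulse bin; the stimulus is a
vector of signed current amplitudes (one per electrode and pulse, positive =
anodic-first).  This note documents the model, the estimation procedure, the
numerical choices, and what the synthetic ground-truth cells do and do not
emulate.

## Model

The stimulus history over the T = 300 ms window preceding a response bin is
flattened into S ∈ R^D with D = L·n_electrodes and L = round(T·f/1000) lags
at stimulation frequency f.  The expected spike count is a Generalized
Quadratic Model (GQM):

    g(S) = v0·S + Σ_i w_i (v_i·S)²,     w_i ∈ {+1 (excitatory), −1 (suppressive)}
    E(S) = a / (1 + exp(−b (g(S) − c)))

and spike counts are Poisson with mean E(S).  Parameters maximize the
Poisson log-likelihood L = Σ_t R(t) log E(S_t) − E(S_t) (the log R! term is
constant in the parameters and omitted).  The sigmoid output nonlinearity is
used because saturating responses are poorly captured by log-exponential
nonlinearities; a binned log-exponential fit is retained as a diagnostic.

### Identifiability and canonicalization

Two redundancies are resolved explicitly:

* **Scale.** (g, b, c) → (g/s, b·s, c/s) leaves E unchanged, so filters can
  trade norm against the sigmoid gain.  Fits are kept on the scale
  std(g) = 1, and the gain is bounded (b ≤ 20 on that scale).  Without the
  bound, maximum likelihood on weak or null data drives the sigmoid toward a
  step function with unbounded filters that memorize individual response
  bins.  A small L2 penalty on the filter coefficients (default `ridge = 1`
  on the standardized stimulus scale, orders of magnitude below the
  likelihood curvature of genuine components at ~30k spikes) removes the
  same degeneracy from the filter block.  This matters for the *calibration*
  of significance tests, not for parameter recovery.
* **Rotation.** The generator depends on the components only through the
  kernel M = Σ w_i v_i v_iᵀ, so components within a degenerate eigen-subspace
  of M are rotations of each other.  After fitting, components are
  canonicalized to the eigenvectors of M scaled to √|λ| with w = sign(λ)
  (excitatory first).  Recovery of planted components is therefore judged by
  subspace principal-angle cosines per class, never by per-component
  cosines.

### Optimization

Quasi-Newton (L-BFGS) ascent with analytic gradients over the filter block
(v0 and all v_i, sigmoid fixed), alternating with an L-BFGS refit of
(a, b, c) (filters fixed, generator values cached), until the relative
penalized log-likelihood change is below 1e-6 or 200 outer iterations.  The
(penalized) objective is non-decreasing across blocks and the trace is
stored in `fit_meta["ll_trace"]`.  Internally the stimulus is divided by its
global SD (the white-noise stimulus has equal variance on every electrode);
returned filters are on the raw μA scale.  Initialization: v0 from the STA
direction, components from the top/bottom STC eigenvectors scaled by the
square root of their eigenvalue excess.

## Subspace identification and significance

The STA is the spike-count-weighted mean stimulus; the STC is the weighted
covariance of the spike-triggered ensemble about the STA.  Because the
stimulus is white with equal per-electrode variance, no whitening is
applied; significance is judged against a shuffle null: responses are
circularly time-shifted by a random offset ≥ L rows (preserving the
response autocorrelation while destroying stimulus alignment) and the STC
spectrum recomputed.

Eigenvalue significance uses a *sequential (nested)* test: the extreme
eigenvalues are compared with the extreme-rank quantiles of the shuffle
spectra; each significant eigenvector is projected out and the test repeats
in the reduced space with freshly recomputed nulls.  Plain per-rank band
comparison is also available (`sequential=False`) but is fragile: one
genuine outlier displaces every bulk eigenvalue by a rank, so the bulk
drifts outside a rank-wise band whenever strong components or a large STA
are present.  Each deflation round retests at level alpha, so the expected
number of spurious components grows by roughly alpha per genuine component
found; where exact component counts matter a stricter per-round alpha can
be passed.

### Electrode-level bootstrap

Which electrodes and lags matter is decided per coefficient: the estimation
procedure is repeated against `n_boot` circularly time-shifted response
vectors, *including the STA/STC initialization step* (each replicate
initializes from its own shifted ensemble's moments — omitting this
selection step shrinks the null and inflates false positives severely), and
the filter block is refit with the sigmoid fixed.  Coefficients with
|value| > 2 × null SD are significant.  Two equivalent backends exist: a
per-replicate L-BFGS loop (`method="scipy"`, best for small designs) and a
vectorized full-batch Adam ascent over all replicates simultaneously
(`method="batched"`, two matrix products per iteration, for large designs);
they agree on the null SD to within sampling error.  Whether the original
study refit all parameters or filters only during its 1000 repeats is not
determinable; filters-only is used here, with the sigmoid at its fitted
values.

## Model order and validation

The number of components expands from (0, 0) by total count; each candidate
order is scored by held-out R² (contiguous-fold cross-validation, 2 folds
for selection) and expansion stops once two consecutive levels fail to
improve the running best by ΔR² = 0.01 — the one-level lookahead prevents
stopping on a plateau step just before a genuine component.  The *argmax
over everything evaluated* is returned: superfluous components overfit and measurably lower held-out R²
(≈0.01–0.02 here), so noise cells fall back to (0, 0), while a genuine
component whose marginal contribution is below the stopping tolerance
(typical for weak suppression) is still selected when it wins.  Exact ties
prefer fewer components.

Validation binning sorts held-out rows by predicted rate into 200-stimulus
bins (stable sort; partial final bin dropped) and compares observed bin
means with predicted means by R² = 1 − SS_res/SS_tot.  The *best-case* R²
simulates Poisson counts at the predicted rates and re-scores — the ceiling
an exact model could reach under Poisson variability.  The variance-vs-mean
check regresses normalized per-bin count variance on normalized mean
through the origin; Poisson data gives slope 1.  Reported metrics are means
over 5 contiguous folds (contiguous, not interleaved, because overlapping
stimulus windows make adjacent rows dependent and random splits would leak).

Baselines: **STC1** projects onto the first STC eigenvector and fits a
double-sided sigmoid — two independent saturating arms sharing the response
floor at zero, continuous there and monotone on each half-axis.  **STC2**
projects onto the two components departing most from the null and fits a
2-D lowess surface (tricube-weighted local linear regression, span 0.05,
50×50 grid, bilinear interpolation, extrapolation clamped).  The 2-D lowess
is implemented here because available lowess implementations are 1-D only.

## Synthetic ground-truth cells

The generator emulates the study's stimulation conditions: Gaussian
amplitudes with σ = 150 μA rejection-resampled at ±300 μA (per-entry SD
131.9 μA), 20-electrode hexagonal array at 1 mm pitch (≈3.5 × 3.5 mm),
10/20/30 Hz, 300 ms window, sigmoid (a, b, c) = (3, 2, 1) giving a ~3
spikes/bin ceiling.  Planted components have 2–4 strong electrodes in one
lag frame — excitatory at lag 0, suppressive at earlier lags — over a
Gaussian background at 5% of peak (the true-negative set for significance
testing), and are Gram–Schmidt orthogonalized.

Component scales are stated as the SD of the stimulus projection in
generator units: quadratic components 0.35, linear component 0.25.  With
the default sigmoid this yields ≈0.5 spikes/bin — ≈30,000 spikes over a
60,000-pulse run, the data volume of a well-sampled recording session.
**Direct mode** (synaptic blockade) reduces the cell to one dimension: a
single excitatory quadratic component whose direction the linear term
shares (g = αp + κ²p² in the projection p), emulating direct activation
that responds to both pulse polarities with a moderate polarity preference.

What the generator does *not* emulate: spike-history dependence and
refractoriness (real counts are mildly sub-Poisson at high rates),
electrode-to-electrode noise correlations, stimulation artefacts and
blanking dead time (a configurable dead-time hook exists but defaults off,
since blanking is a recording artefact rather than a model property),
non-orthogonal generative subunits (orthogonality can be disabled), and
slow nonstationarities.  Passing tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not robustness
to every artefact of real recordings.

## Degenerate inputs and edge conventions

* Zero-variance stimulus columns are retained but their coefficients are
  unidentifiable and always masked insignificant (logged).
* An empty significance class reports integration time 0 ms with a flag; no
  significant electrodes makes the ERF size NaN with a flag.
* R² with zero variance in the observed bin means is NaN (warned), as is
  the best-case R² for constant predictions.
* `poisson_log_likelihood` returns −inf when a zero rate meets a nonzero
  count.
* Polarity preference requires uniform-polarity significant electrodes;
  mixed-sign components raise.
* Ties in prediction sorting are broken by stable sort (time order).
* ERF sizes are reported in mm, the natural unit of the 1 mm-pitch array
  geometry.

## Problem sizes

Tests and the acceptance script run at desk scale on one CPU: the recovery
fixture uses 60,000 pulses × 20 electrodes at 20 Hz (~30k spikes);
calibration uses 50 null cells of 5,000 pulses × 6 electrodes with 200
bootstrap replicates; baseline comparisons use 40,000-pulse cells over 10
seeds.  These sizes were chosen so each statistical check retains the power
the corresponding full-scale analysis would have, while a complete run of
the suite and the acceptance script stays in the tens of minutes.
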