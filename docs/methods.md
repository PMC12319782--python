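# Methods

This note records the package's models, estimators, numerical choices and
their rationale, and what the synthetic validation does and does not show.

## Forward model

A homogeneous conducting sphere of radius R = 92 mm stands in for the head.
Each source is a current dipole with fixed radial orientation; for a dipole
at eccentricity f = b/R and a surface electrode at angular distance γ the
potential is the closed form of the Legendre series
Σₙ (2n+1) f^(n−1) Pₙ(cos γ):

    V ∝ 2 (cos γ − f) / g³ + (1/f) (1/g − 1),   g = √(1 − 2 f cos γ + f²).

The implementation is verified against the truncated series to 1e−10.
Rows are re-referenced to the common average, so gain columns sum to zero
across electrodes.  Tangential orientations, multi-shell conductivity and
realistic (MRI-derived) geometry are out of scope; externally computed gain
matrices can be wrapped with `normalize_leadfield` instead.

Electrodes are mirrored left/right pairs of a deterministic Fibonacci
spiral on the cap z > −0.45 R.  High-density nets extend well below the
equator, and the below-equator rows matter quantitatively: with electrodes
confined to z ≥ 0 the leakage kernel of ventral sources keeps only ~54% of
its mass in the ventral parcel and slope recovery degrades to ~60% of the
planted value.  Sources sit on a shell at 0.85 R restricted to the same
polar cap (the bottom of the head sphere holds no cortex), built as one
quasi-uniform hemisphere mirrored through x = 0 so that homotopic mapping
is exact by construction.  With 804 sources the grid step is ~8 mm.

## Contribution measures

For a recording x(t) with scalp covariance C_x, the matched-filter series
of source q is μ_q = ã_qᵀ x and the contribution measure

    β_q = max(Var(μ_q) − ã_qᵀ C_z ã_q, 0) / (ã_qᵀ Ã diag(s) Ãᵀ ã_q).

Estimator choices, in order of appearance:

* **Noise covariance C_z = σ̂² I**, with σ̂² the mean of the smallest
  ⌈noise_frac·n⌉ eigenvalues of C_x (noise_frac default 0.25).  Simple,
  scale-correct, and adequate for band-limited white sensor noise; a
  colored-noise model would need a dedicated noise recording.
* **Diagonal source covariance** s ≥ 0, fit by least squares of
  C_x − C_z against Σ_q s_q ã_q ã_qᵀ over the vectorized upper triangle of
  the selected-electrode submatrix.  The normal equations have the closed
  Gram form G_qr = ((ã_qᵀã_r)² + Σ_i ã²_qi ã²_ri)/2, solved with a small
  relative ridge (1e−6 of the mean diagonal) and negatives clipped at
  zero.  On orthogonal designs the fit recovers planted variances to <10%
  at T = 100·n (tested); on the real, heavily collinear leadfield it is a
  smoothed estimate — which is precisely what makes β informative, since β
  measures the local departure of the data from the smoothed global model.
* β is scale-invariant when covariances are re-estimated from the same
  recording, and condition ratios are floored (ε = 1e−12 of the mean
  denominator) rather than allowed to blow up.

**Which covariance model normalizes which condition matters.**  If each
condition's β uses a covariance model freely refit to that condition, the
model tracks the data and the condition effect cancels (β → 1 everywhere);
this was confirmed numerically, and it motivates two asymmetric choices:

* Slope estimation normalizes every scrambling condition with the
  *resting-state* fit, so the β ratio reduces to the noise-corrected
  matched-filter power ratio against rest — the estimand the slopes are
  defined on.
* Activation-mode localization likewise uses the baseline fit as the task
  model, evolving it only through the iterative ×2 up-weighting of the
  selected region.  A free task fit absorbs the activation (planted-region
  overlap drops from ~0.9 to ~0.3).

## Region selection (CSpeC) and the iterative localizer

The convex relaxation min βᵀs + λ sᵀLs s.t. 0 ≤ s ≤ 1, 1ᵀs = k is solved by
FISTA with an exact capped-simplex projection (bisection on the shift; 60
iterations bound the dual gap far below solver tolerance).  λ is scanned
over a log grid (1e−4…1e2, 13 values, scaled by max|β|) and the smallest λ
whose thresholded top-k is already connected is recorded as the chosen
smoothness weight.  Disconnected candidates are repaired (largest component
+ greedy growth by smallest β) and all candidates — including greedy
growths from the 10 lowest-β seeds — are polished by a steepest-descent
1-swap local search that preserves connectivity and size.  The lowest
total-β connected candidate wins; ties break by (β, index) so builds are
deterministic.  On all random graphs with ≤ 12 nodes and k ≤ 4 tried
(1000+ instances during development, 200 in the test suite) the result
equals exhaustive search over connected k-subsets.

The silence localizer iterates: free fit of the task covariance → β ratio
task/base → CSpeC selection → re-fit of the task covariance with the
selected region constrained to zero variance → repeat, stopping when
consecutive regions reach the Jaccard tolerance (default 0.95) or r_max
(default 4).  The hard zero constraint is *self-defeating* as a fixed-point
iteration: once a region is zeroed, the model under-predicts its power and
its β rises, so the selector can flip to the opposite extreme in a
period-2 oscillation.  The returned region is therefore the converged one
when the iteration stabilizes, and otherwise the *first* iterate — the
region selected on the unconstrained contrast — with a warning recorded in
the provenance.  Two alternatives were evaluated and rejected: trusting the
last iterate (oscillation makes it arbitrary; mean center-of-mass error
13–30 mm in pilot runs) and picking the iterate whose constrained fit has
the lowest Frobenius residual (the residual landscape is too flat at
realistic noise levels to discriminate nearby wrong regions; it chose a
poor iterate in 2 of 20 validation seeds).  With the convergence-or-first
rule the validation runs give mean Jaccard 0.75 and mean center-of-mass
error 8.3 mm, with every seed above Jaccard 0.59.

k defaults to 100 sources per hemisphere, chosen to yield a single
contiguous mask wide enough to cover the ventral and dorsal visual
pathways; silence-mode k is configurable.

## Synthetic scenario

Defaults are the emulated study conditions: 128 electrodes, 804 sources,
512 Hz, 120 s rest, 60 s per scrambling condition, 10 dB sensor SNR,
base source variance 100 µV².  Sources are independent Gaussian processes
band-limited by the package's own Butterworth filters (4th order,
forward–backward; the same filters analyze the data).  Under scrambling
level i (x_i ∈ 1..5 from S256 to S1) the variance is
base·(1 + α*(x_i−3)/2), floored at 0.05·base; the ground-truth record
stores the exact OLS slope of each source's planted relative-power line,
which is what recovery is scored against.  The shape-sensitivity plan
covers the full posterior visual territory (ventral + dorsal parcels in
both hemispheres, α* = 0.5 in every band) — matching the observation that
healthy visual cortex is broadly shape-sensitive — with per-subject
(sd 0.10) and per-band (sd 0.05) multiplicative jitter providing
between-subject variability.  The planted lesion silences the 100 sources
nearest a right-ventral centroid (1% residual variance in all conditions);
the diaschisis replaces α* with 0.05 inside a 30 mm homotopic region
mirrored from the lesion centroid, by default in Theta only.

What the generator does *not* emulate: non-Gaussian and nonstationary EEG
(eye blinks, muscle, line noise), correlated source dynamics, evoked
transients, realistic head geometry, inter-subject anatomical variability,
or channel dropout.  Passing recovery tests therefore demonstrates the
estimators' correctness and calibration under the stated statistical
model, not robustness to real-world artifacts — the preprocessing that
removes those artifacts is explicitly out of scope.

Leakage is physics, not a bug: the matched-filter kernel mixes neighboring
sources, so even noiseless parcel-mean slopes recover ~88–95% of the
planted value (computable exactly from the leadfield).  The recovery
tolerance (20%) covers this bias plus estimation noise.

## Single-case statistics

* Crawford-Howell t: exact transcription; empirical type-I error at
  α = 0.05 over 10⁵ null draws is within [0.045, 0.055] (tested).
* RSDT: the published closed form (quartic coefficients with the (3+r)
  term).  An exact-null parametric bootstrap — redraw n controls + 1 case
  from the estimated bivariate normal, recompute the full statistic with
  each replicate's own sample moments — ships in the package
  (`rsdt_bootstrap_oracle`) and guards the transcription.  At n ≥ 8 the
  closed form agrees with the oracle to <0.005; at n = 5 the published
  approximation deviates by up to ~0.015 in mid-p ranges (its α = 0.05
  rejection rate remains calibrated at 0.055), a known limitation reported
  here rather than hidden.
* Bayesian single-case: σ² ~ (n−1)s²/χ²ₙ₋₁, μ ~ N(x̄, σ²/n),
  p* = Φ((case−μ)/σ); the posterior mean reproduces the Crawford
  one-tailed p to <0.005 at 10⁵ draws.  BSDT: inverse-Wishart (df = n−1,
  scale (n−1)S) via Bartlett factors, conditional normal mean, per-draw
  standardized-discrepancy tail.  BSDT and RSDT approximate the same tail
  probability with config-dependent discrepancies up to ~0.02 at small n;
  the cross-check tolerance (0.025) reflects that measured bound.
* Leave-one-out deviation counting and percentile bootstrap are direct
  implementations; no multiple-comparison correction is applied, matching
  the design they calibrate.
* Null difference band: a per-source 2.5/97.5 percentile of the 10
  pairwise control maps undercovers badly (exact iid coverage ~72%,
  because the width is estimated from few correlated differences).
  `null_band` instead estimates the per-source null spread from the mean
  square of the pair differences (E[d²] = 2σ², n/(n−1) corrected) scaled
  by the t quantile with n−1 df; simulated coverage is 97–98%.

## Problem sizes used in the test suite

The suite runs the full study-sized geometry (128 electrodes, 804 sources)
throughout; recordings are scaled for turnaround as the package's own
validation sizes: localization tests keep the 120 s duration but decimate
to 128 Hz (for [1,50] Hz content the effective sample count depends on
duration, not rate), and band-resolved slope/statistics tests sample each band near
its own Nyquist need (Delta/Theta 32 Hz … Gamma 128 Hz) with 20–60 s per
condition.  `scripts/acceptance.py` runs the full 120 s / 512 Hz setup.

## Known limitations

* Radial-only dipoles and a single-shell sphere understate the leadfield
  complexity of real heads; the import path exists for realistic gains.
* One contiguous region per hemisphere, by design; multiple simultaneous
  regions are out of scope.
* The diagonal source-covariance model is the minimal identifiable choice;
  correlated source activity is absorbed into leakage bias.
* RSDT/BSDT p-values are approximations with ~0.01–0.02 config-dependent
  error at n ≤ 8 relative to exact null simulation (see above).
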