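# Methods

## Model and metrics

The decoder is a penalized linear regression on ±1 labels with sign
readout: Θ̂, b̂ = argmin Σᵢ(yᵢ − xᵢΘ − b)² + λ‖Θ‖₁, the intercept
unpenalized. The loss is the *unscaled* sum of squared errors: this fixes
the meaning of the λ grid {0.001, 0.01, 0.1, 1, 10, 50, 100, 250, 500,
1000} so that, at the trial counts of the validation studies, the grid
spans effectively-unregularized to fully-sparse fits (a mean-loss
convention would rescale every grid value by n). Fits are delegated to
scikit-learn's cyclic coordinate descent with α = λ/(2n), which minimizes
the identical objective up to a positive factor.

The multivariate brain map (MBM) of a fitted decoder is its weight vector
normalized to the unit sphere. When features are standardized before
fitting, the weights are first mapped back to the raw feature scale
(w_raw = w_std / sd): the map then lives in the original feature space,
and the zero pattern introduced by the ℓ1 penalty is preserved. A fit
whose coefficients are all exactly zero has no direction; it is excluded
from ensembles and counted (`degenerate_count`), and a λ whose ensemble is
entirely degenerate gets undefined metrics and ζ = 0.

For an ensemble of m MBMs and a reference map, η is the mean signed
cosine to the reference, ψ the mean signed cosine to the normalized
ensemble mean, and β the absolute cosine between the ensemble mean and the
reference. η and ψ follow the signed formulas; β takes the absolute
value. The identity η = ψβ is exact only when the main map's signed dot
product with the reference is non-negative; sign-flipped ensembles warn
rather than fail, since an anti-aligned ensemble is itself diagnostic.
ψ equals the Euclidean norm of the plain ensemble mean (resultant
length), which the tests exploit as an independent oracle. All algebraic
identities (unit norms, η = ψβ, the resultant identity) are held to 1e−9
— they are exact in double precision.

The cosine of two independent uniformly random unit vectors in dimension p
has mean 0 and variance exactly 1/p and is asymptotically normal;
`cosine_null_sd` / `cosine_significance` expose this N(0, 1/p) null so
observed alignments can be judged against the high-dimensional chance
scale.

## cERF heuristic and activation patterns

For evoked (time-locked) M/EEG, the contrast ERF — the unit-normalized
difference of the two condition means — stands in for the unknown true
map. The activation-pattern transformation multiplies the pooled
empirical feature covariance (mean-removed, n−1 denominator) by the
decoder weights, converting backward weights into their forward
(generative) equivalent. On balanced classes with centered features the
cERF direction coincides with the activation pattern of the least-squares
decoder; the test suite asserts this collinearity (> 0.999) only under
those preconditions, where it is exact up to rank effects. The heuristic
applies to binary, stimulus-locked designs only; multiclass input is
rejected with a hint to binarize.

## Out-of-bag evaluation and the ζ criterion

Each evaluation draws m = 50 bootstrap replicates (in-bag: n draws with
replacement; out-of-bag: the complement, redrawn if empty — at n ≥ 30 the
OOB fraction concentrates near e⁻¹ ≈ 0.368). Standardization is fit
per in-bag set and applied to the corresponding OOB trials, so no
validation information leaks into the fit.

EPE is the 0/1 loss pooled over all OOB prediction events. Its
decomposition follows the standard 0/1-loss construction: each trial's
*main prediction* is the majority vote of its OOB predictions (ties to
+1); bias is the 0/1 loss of the main prediction, variance the trial's
disagreement rate with its own main prediction, and the identity
EPE = Σᵢ wᵢ(biasᵢ + (1 − 2 biasᵢ) varᵢ) with event-count weights wᵢ holds
exactly (tested to 1e−12). Trials that never land out-of-bag (possible at
small m) contribute no events. δ = 1 − EPE.

ζ is the ω-weighted average of η̃ and δ when δ clears κ, else 0. Defaults
ω₁ = ω₂ = 1, κ = 0.6 (chance 0.5 plus a safety margin for binary
balanced designs). The grid search computes the cERF once on the full
provided training set, shares one seeded bootstrap plan across the grid
(which removes partition noise from the λ comparison and lets each
replicate warm-start coordinate descent along the descending λ path), and
selects argmax ζ with ties broken toward larger λ — the sparser model.
If every ζ is 0 the result is flagged "no admissible model" and carries
the δ-argmax as an advisory. A fixed seed makes the whole table
bit-reproducible.

## Data generators

**Toy.** Prototypes ±[1.5, 0] plus Gaussian noise with covariance
[[1.02, −0.3], [−0.3, 0.15]]; 1000 trials per class by default. The true
map is [1, 0]; the population least-squares direction is [1, 2]/√5 ≈
[0.447, 0.894] and the Bayes accuracy Φ(d/2) ≈ 0.9897 (Mahalanobis
separation d). The toy study runs on raw (unstandardized) features: the
λ-grid calibration of the reference behavior — the noise coordinate's
weight vanishing exactly on the 500–1000 plateau, with an analytic
subgradient threshold near λ ≈ 504 at n = 2000 — holds in the raw feature
scale, whereas standardizing the two comparably-scaled coordinates shifts
the zeroing threshold to ≈ 1000.

**Simulated evoked MEG.** One current dipole at (−4.7, −3.7, 5.3) cm RAS,
oriented [1, 1, 0], inside a homogeneous conducting sphere; the radial
field at 102 magnetometers on a deterministic Fibonacci hemisphere
(radius 12 cm) follows the closed-form spherical-conductor solution
(volume currents included; radial dipoles are silent). Epochs are 100
samples at 300 Hz (≈ 333 ms — the nominal 330 ms epoch at this rate).
The positive class carries on the dipole: a time-locked ERF (positive
3 Hz half-cycle peaking at 150 ms, negative 5 Hz half-cycle at 250 ms,
independent ±10 ms uniform per-trial jitter per peak) plus background
activity summing 50 sinusoids with frequencies uniform on 1–125 Hz,
phases uniform on 2π, amplitudes 1/f^γ with γ = 1 — the standard
emulation of the broadband 1/f power profile of human brain activity; the
ERF half-cycles follow the same spectral amplitude law (1/3 and 1/5).
The negative class carries the background only. White Gaussian noise is
added per sensor sample with sd equal to `white_noise_scale` (default 1)
times the RMS of that epoch's projected signal. It is added at the
sensor level because placing it on the dipole would leave the sensor
covariance exactly rank one — every channel a scalar multiple of one time
course — making the ℓ1 weight allocation among duplicated channels
solver-arbitrary and contaminating the reproducibility metric; dipole-
level noise remains available (`white_noise_at="dipole"`). The ground
truth map is the dipole topography ⊗ jitter-free ERF waveform, flattened
channel-major.

What the generators do *not* emulate: multi-dipole or realistic
volume-conductor head geometry, gradiometers, spatially correlated sensor
noise, non-stationary background, and the trial-to-trial amplitude
variability of real ERFs. Passing tests therefore certify the algebra and
the selection machinery under idealized single-source conditions, not
performance on recorded MEG.

## Numerical choices

- Unit-norm and identity tolerances: 1e−9 (exact algebra in doubles).
- Coordinate descent: deterministic cyclic order, no random
  initialization, max 10⁵ iterations; relative dual-gap tolerance 1e−6.
  Above ~2×10⁶ matrix entries the solve runs in single precision with
  tolerance 1e−5 — coefficients agree with the double-precision optimum
  to ~1e−5 relative (map cosines to 0.999999) at roughly half the cost.
  Non-convergence raises with the solver report attached.
- Standardization uses the unbiased (n−1) sd; constant features get a
  sd = 1 guard so they standardize to zero.
- sign(0) predicts +1; majority-vote ties resolve to +1.
- λ = 0 bypasses the penalized solver and uses minimum-norm least squares,
  as does the reference map Σ_X⁻¹XᵀY (pseudo-inverse when rank-deficient).

## Study sizes

The toy study runs at its full default conditions (2000 trials, m = 50,
10-point grid; seconds of CPU). The simulated-MEG selection study runs
with 5 repetitions over the reduced grid {10, 50, 100, 250, 500} with
m = 50, which keeps the 1250 lasso fits on 500 × 10200 matrices to a few
minutes on one CPU while leaving λ = 50 an interior grid point with
neighbors on both sides; unit tests use reduced sensor geometries
(16–24 channels) that preserve every structural property of the
full-size simulation.

## Known limitations

- The cERF heuristic degrades with small trial counts (the contrast mean
  itself becomes noisy) and is undefined for non-time-locked designs.
- η̃ systematically overestimates η; it is a ranking tool across
  hyper-parameters, not an unbiased estimate of interpretability.
- The ζ threshold κ = 0.6 presumes balanced binary classification;
  unbalanced designs need a recalibrated κ.
- Absolute λ values are tied to the unscaled-loss convention and to the
  generators' amplitude calibration; on other data the grid should be
  rescaled (e.g. by the λ that first produces a fully-sparse fit).
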