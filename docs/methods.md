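# Methods

## Problem and model

We observe a stream X₁, X₂, … ∈ ℝᵏ, i.i.d. from a known pre-change
density f₀ up to a deterministic but unknown change-point τ and from a
known post-change density f₁ afterwards. A detector is a stopping time
T; performance is measured by the average run length to false alarm
ARL = E∞[T] (expectation when no change ever occurs) and by the
worst-case average detection delay in Lorden's sense. For CUSUM-type
rules the worst case over τ and over pre-change histories is attained
at τ = 0 with the statistic at zero, so delay is estimated by running
the detector on pure-f₁ streams from S₀ = 0.

Both densities are assumed fully known (the composite/unknown
post-change problem, non-i.i.d. streams and change-point localization
are out of scope). The detectors never estimate τ; they only alarm.

## Privatization

The indicator mechanism releases Zₜ = 1{Xₜ ∈ A} + Lap(1/α) with
A = {x : f₁(x) > f₀(x)}. Membership uses the strict inequality; the
boundary (measure zero for all continuous families here) belongs to the
complement. Because the indicator has global sensitivity 1, the
mechanism is α-LDP for every data dimension; `verify_ldp` returns the
analytic worst-case density ratio e^α after a grid check.

The privatized marginal under fᵢ is the two-component Laplace mixture
mᵢ(z) = (α/2)[(1 − pᵢ)e^{−α|z|} + pᵢ e^{−α|z−1|}] with
pᵢ = P_{fᵢ}(X ∈ A). The CUSUM increment log m₁(z)/m₀(z) is evaluated as
a difference of two-term log-sum-exps with the larger exponent factored
out (`np.logaddexp`), which is stable for |z| up to 10⁶ and α up to 50.
Weights p ∈ {0, 1} are rejected rather than clamped: a separating
region makes the increment unbounded and the mixture degenerate.

The truncation baseline clips a scalar observation to [−K, K] (k = 1)
or projects onto the ℓ₁ ball of radius K (k > 1) and adds Lap(2K/α)
noise per coordinate (ℓ₁ sensitivity 2K). Its CUSUM uses the *raw*
densities as a surrogate increment, since the privatized marginal has
no closed form; the surrogate's pre-change mean can be positive (it
demonstrably is for the variance-shift model with heavy noise), which
is exactly the pathology the indicator mechanism avoids. K is exposed
as configuration with no automatic selection rule — in practice it is
chosen by simulation, and the experiments simply sweep a few values.

The ℓ₁ projection is the exact Euclidean projection by sort-based
soft-thresholding: find θ ≥ 0 with Σⱼ max(|xⱼ| − θ, 0) = K and shrink
every coordinate toward zero by θ, preserving signs. Tests compare it
against a brute-force KKT active-set enumeration at k ≤ 4.

## Regions and probabilities

For the named families the Neyman–Pearson region has closed form:
half-line (mean shifts; threshold at the midpoint of the means),
two-sided outer region (variance inflation; threshold
√(2 log(v₁/v₀) / (1/v₀ − 1/v₁)), stored at full precision), half-space
(multivariate mean shift), and a quadratic region in the scalar
projection u᙭x (spiked covariance). Half-space normals are scaled so
the largest component is ±1, which makes the canonical equal-shift case
read 1ᵀx > 0.25k. Descending univariate shifts are represented as a
flipped half-space rather than a second half-line form.

Region probabilities reduce to 1-d integrals: Normal/Laplace CDFs, a
Gaussian projection for half-spaces, and a χ²₁ law for the quadratic
region (s = u᙭x has variance ‖u‖² under f₀ and ‖u‖²(1 + r‖u‖²) under
f₁). Fitted and custom models use the generic sign-of-LLR region with a
seeded Monte Carlo fallback (default 2·10⁵ draws per law). Because A is
the most-powerful region, TV(f₀, f₁) = p₁ − p₀ exactly; the Gaussian
mean-shift families additionally use the closed form
2Φ(‖μ₁ − μ₀‖/(2σ)) − 1, and the two routes agree to 10⁻¹⁰ in tests.

## Information bounds

`kl_mixture_numeric` integrates m₁ log(m₁/m₀) by adaptive quadrature
split at the density kinks z ∈ {0, 1}, with tails truncated at
L = 30/α where the mixture mass is below 10⁻¹²; absolute tolerance
10⁻¹⁰, and a reported error above 10⁻⁶ raises. The privatized-TV
identity, the Pinsker lower bound 2 TV²(1 − e^{−α/2})², the contraction
upper bound min{4, e^{2α}}(e^α − 1)² TV² and the raw KL ceiling are all
closed-form. `delay_upper_bound` returns only the first-order
coefficient log γ / [2 TV²(1 − e^{−α/2})²]; the o(1) term is not
modeled, so the bound serves as a sanity envelope in simulation checks,
never as an equality.

## CUSUM engine

The recursion Sₜ = max(0, Sₜ₋₁ + ℓₜ) is initialized at 0. The
alternative write-up S′ = max(0, S) + ℓ started at −∞ is stopping-time
equivalent for every b > 0 (the two statistics satisfy
U_t = max(0, V_t) by induction); this is covered by a test on random
streams rather than a second code path.

Internally blocks of increments are processed with the exact unrolled
identity Sₜ = max(Cₜ + S₀, Cₜ − min_{0≤j≤t} Cⱼ), C the within-block
cumulative sum, so a run is a handful of vectorized operations per
block while remaining step-for-step identical to the scalar recursion
(asserted in tests). Streams are generated lazily in blocks of 2048,
giving O(1) memory per run regardless of the stopping time.
Trajectories are recorded only on request.

## Monte Carlo protocol

Every replication i of an evaluation derives its generator from the
seed sequence (seed, context, i), making each estimate a pure function
of configuration and seed. Three contexts separate calibration,
reporting and delay estimation. Because a replication re-uses identical
raw draws and noise across threshold values, the stopping time — and
hence the estimated ARL — is monotone in b path by path, which makes
bisection well behaved.

Calibration brackets b at log γ ± 3 and expands in steps of 3 when the
increments are too noisy for the first-order guess (heavily privatized
baselines need b far above log γ); bisection stops when the calibration
estimate is within 5% of γ (at most 40 iterations). The reported ARL is
then re-estimated at the final threshold under the independent
reporting context, avoiding optimization bias. Each run carries a hard
cap (default 50γ); censored ARL runs are counted at the cap — a
downward bias that is conservative for ARL ≥ γ claims — and the
censoring count is always reported. Delay estimation errors out if more
than 1% of runs censor.

Default study conditions follow the evaluation protocol the detectors
are built for: target ARL 1000, 1000 replications, privacy grid 0.5–2,
truncation levels K ∈ {0.8, 0.9, 1} for unit mean shifts. The tradeoff
ordering checks run at 300 replications with two-joint-standard-error
slack so the full suite stays fast; the acceptance script keeps the
full 1000 replications for the calibration target. The statistical
conclusions (monotone delay in α; exact ≤ LDP ≤ truncation at matched
ARL) are unchanged by the replication count, only the noise level is.

## Synthetic data and its limits

`generate_stream` plants a single hard change-point in an otherwise
i.i.d. stream — exactly the model the theory assumes. Real streams
(e.g. network-traffic features) have temporal dependence, drifting
baselines and gradual onsets that this generator deliberately does not
emulate; passing tests therefore validate the implementation and the
i.i.d. theory, not robustness to model misspecification. For empirical
streams the package fits full-covariance Gaussians to labeled pre/post
samples (`fit_gaussian_models`, ridge 10⁻⁶ of the mean diagonal for
conditioning; whether full or diagonal covariance is the better fit is
data-dependent, full is the declared choice) and runs the detectors
generically over CSV input. Dimension-reduction preprocessing is left
to the user.

## Known limitations

* Delay and ARL guarantees are first-order asymptotic in γ; at moderate
  γ the constants matter and only orderings/envelopes are asserted.
* The truncation baseline's surrogate statistic has no false-alarm
  theory; its calibrated thresholds can be an order of magnitude above
  log γ, and at strong privacy its pre-change drift can make
  calibration expensive.
* Only the sequentially non-interactive LDP setting is implemented;
  randomized-response channels, smooth bounded transformations and
  adaptive mechanisms are not.
* Analytic (integral-equation) ARL computation is not provided; all
  operating characteristics are Monte Carlo estimates with reported
  standard errors.
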