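# Methods

## Estimand and model

For a competing-risks cohort with event time T, censoring time C,
observed time U = min(T, C) and cause indicator ε ∈ {0, 1, 2}, the
estimand at follow-up length l is the restricted mean time lost to
cause 1,

    μ₁(l | Z) = ∫₀ˡ F₁(t | Z) dt = E[(l − T(l)) · I(ε(l) = 1) | Z],

modelled with an identity link as μ₁(l | Z) = Z*(l) β, where each
covariate effect is polynomial in l (default quadratic):
βₖ(l) = βₖ₀ + βₖ₁ l + βₖ₂ l². A negative βₖ(l) marks a protective
factor: group k has lost βₖ(l) fewer years to cause 1 by time l. The
derivative βₖ′(l) is the *real-time* effect, the instantaneous speed at
which the between-group difference accumulates.

### Restriction and stacking

At each horizon lⱼ of a grid l₁ < … < l_J ≤ τ, a subject failing before
lⱼ keeps its cause with known lost time ((lⱼ − U) for cause 1, zero for
cause 2); a subject with U ≥ lⱼ — whatever its eventual fate — is
*event-free at lⱼ* with known zero lost time and stays in the analysis;
only subjects censored strictly before lⱼ have unknown restricted
outcomes. This reading is essential for consistency: treating
event-free-at-lⱼ subjects as non-contributing would delete exactly the
observations that anchor the lower tail of the lost-time distribution.
Events at exactly lⱼ count as event-free at lⱼ (half-open [0, lⱼ)
windows).

The J restricted copies are stacked; each observable row carries the
IPCW weight 1/Ĝⱼ(T(lⱼ)⁻), where Ĝⱼ is the Kaplan–Meier estimator of
the censoring ("non-censoring") survival function computed *within* the
j-th restricted dataset (censorings before lⱼ are its events; everyone
else is censored at min(U, lⱼ)). Ĝ is evaluated at the left limit, with
failure-before-censoring tie handling — the standard IPCW convention.
If Ĝⱼ = 0 for an observable row (risk set exhausted), the row is
dropped with a warning rather than given an infinite weight.

### Estimation and inference

With the identity link the estimating equation is linear, so β̂ is the
weighted least-squares solution on the stacked rows, computed by a
rank-revealing solve; a rank-deficient expanded design raises an error
naming the collinear columns. No iteration is needed; the fitted
gradient norm is checked in the tests at 1e-10.

The covariance is the cluster-robust sandwich Â⁻¹B̂Â⁻¹ with
Â = Σ wᵢⱼ Z*ᵢ(lⱼ)⊗² and B̂ = Σᵢ (Σⱼ ψᵢⱼ)⊗², clustering each subject's J
score contributions. Two conventions were open:

* **Weight in the bread.** Differentiating the weighted estimating
  equation puts wᵢⱼ inside Â; since E[w] = 1 among observables the
  weighted and unweighted versions agree asymptotically. The weighted
  form is used: in the Monte Carlo study it gives relative SE ≈ 1.00
  and ≈95% coverage, while the unweighted-over-observable-rows variant
  overestimates SEs (relative SE ≈ 1.10).
* **Estimated weights.** Ĝ is treated as fixed; no correction for its
  sampling variability is applied. Monte Carlo coverage shows the
  approximation is adequate at the study's censoring levels.

Wald tests are per expanded term (z = β̂/SE against the standard
normal). Optional backward stepwise screening removes, one at a time,
the individually least significant expanded term with p > α (default
0.05), refitting after each removal. No hierarchy constraint links the
(1, l, l²) terms of one covariate — a covariate may legitimately retain
only its l² term — and a covariate leaves the model when all its terms
are gone. The intercept's constant term is never removed. On synthetic
cohorts (n = 2000, 200 replicates) this screens out a pure-noise
covariate 92% of the time while retaining both real effects always.

### Horizon grid

The default grid takes J = 30 equally spaced points between the 10th
and 95th percentiles (linear-interpolation convention) of the observed
event times. Percentiles are computed over subjects with *any* event by
default: restricting to cause-1 subjects ends the grid so early in
cause-1-heavy data that late-horizon summaries become long quadratic
extrapolations — in the simulation scenarios this inflates the bias of
β̂₀(1.5) by an order of magnitude and collapses its coverage, whereas
the any-event grid reproduces the expected estimator behaviour.
`select_time_grid(events="interest")` keeps the cause-1-only variant.
Evaluating curves or predictions outside [l₁, l_J] is permitted but
flagged with an `ExtrapolationWarning`. Predictions are not truncated
to [0, l] by default (so additivity holds exactly); `truncate=True`
clips them.

## Synthetic-data generator

Cohorts are drawn from a two-cause mechanism with two independent
Bernoulli exposures. Within each (Z₁, Z₂) stratum the cause-1
subdistribution hazard is Gompertz, λ₁(t) = γ e^{ρt} with ρ < 0, so
F₁(t) = 1 − exp(−γ(e^{ρt} − 1)/ρ) plateaus at 1 − e^{γ/ρ} and the rest
of the mass fails from cause 2 with a unit-exponential conditional
time. The cause is drawn first (Bernoulli), then the time by closed-form
inversion of the conditional CIF; the inverse is verified by round-trip
to 1e-10. Default stratum parameters

    γ = (2.88, 1.95; 2.29, 1.55),  ρ = (−1.7, −1.4; −2.9, −2.8)

(indexed by (z₁, z₂)) make both subdistribution hazard ratios
time-varying — sHR(Z₁, t) = 0.795 e^{−1.2t}, and sHR(Z₂, t) crosses 1
near t ≈ 1.30 — so proportional-subdistribution-hazards fitting would
be misspecified by design. Defaults: exposure probabilities 0.25,
censoring rate 10%, n = 1000.

Censoring is independent Uniform(0, θ); θ is calibrated by bisection on
the *analytic* censoring probability P(C < T) = (1/θ)∫₀^θ S_T(t) dt of
the scenario mixture, so calibration is deterministic and seed-free;
the realized rate is verified empirically to ±0.01 at n = 10⁴. True
RMTL values and coefficients come from adaptive quadrature of F₁
(absolute tolerance 1e-8), with β₀(l) the baseline-stratum RMTL and
β₁, β₂ the single-exposure contrasts against baseline.

Note one deliberate property: the true RMTL surface is *not* additive
in (Z₁, Z₂) — the Z₁ contrast differs slightly between Z₂ strata — and
it is not exactly quadratic in l. The fitted model is therefore a
(mild) projection even in simulation, exactly as in the published
design, and the Monte Carlo biases at the largest horizon partly
reflect that projection rather than estimator error.

What the generator does **not** emulate: covariate-dependent or
non-uniform censoring, more than two binary covariates (the seer-like
fixture adds a 12-covariate log-linear Gompertz mechanism but remains
synthetic), time-varying covariate values, left truncation, or the tied
and coarsened times of real registry data. Passing tests demonstrate
estimator correctness under the stated mechanism, not robustness to
those features.

## Monte Carlo harness

`run_simulation` draws replicate cohorts (replicate seeds spawned
sequentially from the master seed for bit-reproducibility), places the
percentile grid on each replicate's own event times, fits the full
quadratic model and evaluates β̂ₖ(l) with delta-method SEs at the
report horizons {0.75, 1, 1.5} — by design even when 1.5 lies at or
beyond the replicate's grid end. Aggregates are mean bias, relative
bias, RMSE, relative SE (mean estimated SE / Monte Carlo SD) and
empirical 95% coverage against quadrature truth; replicate-level fit
failures are counted, never silently dropped. The accuracy study run by
`scripts/acceptance.py` uses n = 250 and n = 1000 with 2000 replicates
and n = 500 with 1000 replicates — sizes chosen to keep Monte Carlo
error on a coverage estimate near ±0.005–0.008 while the full study
completes in minutes on one CPU.

## Validation metrics

The cause-specific concordance at horizon l compares every cause-1
failure before l with (a) subjects still under observation at that
failure time and (b) subjects with an earlier competing event (known to
accrue no cause-1 lost time). Pairs are weighted by inverse products of
the censoring survival function (1/G(tᵢ⁻)² for at-risk partners,
1/(G(tᵢ⁻)G(tⱼ⁻)) for competing partners); prediction ties count 1/2,
so constant predictions score exactly 0.5, and permuted predictions
score 0.5 within Monte Carlo noise. The relative prediction error at l
is the IPCW-weighted mean absolute difference between observed lost
time and predicted RMTL, divided by l; a squared-error variant is
available behind a flag.

## Known limitations

* Identity link only; the link-function plumbing exists but alternative
  links are not exposed.
* Polynomial time bases only (degree configurable); no splines.
* No correction for estimating Ĝ; SEs can be slightly optimistic under
  heavy censoring.
* Large-horizon IPCW weights are unstable when few subjects remain at
  risk; rows with Ĝ = 0 are dropped with a warning, and grids should
  stay inside the data's support.
* Two event causes; no left truncation or time-varying covariate
  values.
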