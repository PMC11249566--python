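# dynrmtl — dynamic-effect RMTL regression for competing risks

`dynrmtl` fits regression models for the **restricted mean time lost**
(RMTL) — the area under the cause-specific cumulative incidence function
F₁ on a follow-up window [0, l] — in right-censored competing-risks
cohorts (for example, death from breast cancer with death from other
causes as the competing event). Unlike hazard-ratio models, the RMTL
difference between groups is an absolute quantity on the time scale
("ER-negative patients lost an extra 0.25 years of life to breast cancer
within 4.5 years"), and unlike a single-τ RMTL regression, the *dynamic*
model lets every covariate effect vary with the follow-up length.

It is written for biostatisticians and epidemiologists analysing
registry-style cohorts: one row per subject with a follow-up time in
years, an event indicator coded 0 (censored) / 1 (event of interest) /
2 (competing event), and covariates.

## Model

For a pre-specified end of follow-up l, define the restricted outcome
ε(l) and restricted time T(l) = min(T, l). The model links the expected
lost time to covariates with an identity link:

    μ₁(l | Z) = E[(l − T(l)) · I(ε(l) = 1) | Z] = Z*(l) β,

where each covariate's coefficient is a quadratic in l,
βₖ(l) = βₖ₀ + βₖ₁ l + βₖ₂ l², so the expanded design Z*(l) carries
zₖ, zₖ·l, zₖ·l². Choosing J horizons l₁ < … < l_J and stacking the J
restricted copies of the cohort, β solves the IPCW estimating equation

    Φ(β) = Σⱼ Σᵢ [I(εᵢ(lⱼ) ≠ 0) / Ĝ(Tᵢ(lⱼ)⁻, lⱼ)] Z*ᵢ(lⱼ) {Yᵢⱼ − Z*ᵢ(lⱼ)β} = 0,

with Yᵢⱼ the observed lost time and Ĝ(·, lⱼ) the Kaplan–Meier estimate
of the censoring survival function in the j-th restricted dataset. With
the identity link this is one weighted least-squares solve. Standard
errors come from the sandwich Â⁻¹B̂Â⁻¹ with each subject's J score
contributions clustered. The fitted model yields

* **cumulative effects** βₖ(l) with pointwise delta-method CIs,
* **real-time effects** dβₖ(l)/dl — the speed at which a between-group
  difference in lost time accumulates,
* **individual RMTL trajectories** μ̂₁(l | z), and
* horizon-indexed validation metrics (cause-specific C-index and
  relative prediction error, both IPCW-weighted).

A Gompertz-subdistribution simulator (`dynrmtl.simulation`) generates
two-exposure competing-risks cohorts with analytically known CIFs, RMTL
and true β(l), and drives the Monte Carlo accuracy harness.

## Worked example

The package bundles the coefficient set of a published dynamic RMTL
analysis of older early-stage breast-cancer patients
(`dynrmtl.examples`). Predicting mean life lost to breast cancer for
three covariate patterns (all aged 75+, T2, ER−/PR−; A = N3/grade IV/
mastectomy/no chemo, B = A with breast-conserving surgery and
chemotherapy, C = B with N1/grade I):

```python
>>> import numpy as np
>>> from dynrmtl.examples import breast_cancer_model, example_patients
>>> m = breast_cancer_model()
>>> np.round(m.predict(example_patients(), [5.0, 10.0]), 1)
array([[1.5, 4.2],
       [1.2, 3.5],
       [0.5, 1.5]])
```

Patient A is predicted to lose 1.5 years to breast cancer within 5
years of follow-up and 4.2 years within 10; switching to
breast-conserving surgery plus chemotherapy (B) lowers these to 1.2 and
3.5. The ER-positivity effect at l = 4.5 and its accumulation speed:

```python
>>> round(m.coefficient_curve("er_pos", 4.5)[0], 3)
-0.242
>>> round(m.realtime_effect("er_pos", 4.5), 3)
-0.096
```

ER-positive patients have lost 0.24 fewer years by 4.5 years, and the
gap is still widening at ≈0.10 years of life per follow-up year.

Fitting on simulated data with known truth:

```python
>>> from dynrmtl import GompertzScenario, generate_cohort, fit_dynamic_rmtl, true_beta
>>> sc = GompertzScenario(n=5000, censoring_rate=0.1)
>>> time, status, Z = generate_cohort(sc, np.random.default_rng(42))
>>> fit = fit_dynamic_rmtl(time, status, Z)
>>> est, se, lo, hi = fit.coefficient_curve("z1", 1.0)
>>> print(f"beta1(1) = {est:.3f} (95% CI {lo:.3f} to {hi:.3f})")
beta1(1) = -0.147 (95% CI -0.173 to -0.121)
```

against the quadrature truth β₁(1) = −0.150.

The same operations are available from the shell:

```sh
dynrmtl fixture --kind paper-sim --n 1000 --seed 7 --out cohort.csv
dynrmtl fit-dynamic --cohort cohort.csv --grid-j 30 --out-coef coef.csv --out-model model.json
dynrmtl predict --model model.json --cohort cohort.csv --at 0.75,1,1.5
dynrmtl validate --model model.json --cohort cohort.csv --at 0.75,1 --out metrics.csv
dynrmtl simulate --n 500 --cens 0.1 --reps 500 --seed 1 --out report.csv
```

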