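# cocpd

Exposure–response modelling of combined oral contraceptive efficacy.

Hormonal contraceptives are dosed at the top of their exposure–response
curves, so the effect of anything that lowers exposure — CYP3A4-inducing
co-medication (rifampicin, carbamazepine), higher body weight — on the
clinical endpoint cannot be read off trial data, and deliberately
under-dosing women to measure it would be unethical. `cocpd` implements a
quantitative framework that links progestin dose, average steady-state
concentration (C<sub>avg</sub>) and two efficacy endpoints — the Pearl
Index (PI, contraceptive failures per 100 woman-years) and the ovulation
rate (OR, % of women ovulating per cycle) — across progestins
(levonorgestrel, LNG; drospirenone, DRSP), for pharmacometricians and
regulatory scientists evaluating contraceptive drug–drug interactions in
a PK/PD rather than PK-only context.

## The model

The core is the Black–Leff operational model of agonism, which separates
receptor affinity from intrinsic efficacy. With x = log₁₀(C<sub>avg</sub>
in pmol/L) and k<sub>D,i</sub> = log₁₀(K<sub>D,i</sub> in pmol/L) for
progestin *i*:

```
E_ij = BL · ( 1 − Imax · (τ_i·x_ij)^H / ( (k_D,i + x_ij)^H + (τ_i·x_ij)^H ) ) + ε_ij

ε_ij ~ N(0, σ_i²/n_ij)
```

- BL — endpoint level without contraception (85 for PI, 100 for OR; fixed)
- Imax — maximal fractional suppression (fixed at 1)
- τ_i — transducer constant, the drug's intrinsic efficacy (estimated)
- H — Hill factor, shared across drugs within an endpoint (estimated)
- σ_i — additive residual scale per drug; arm j with n_ij subjects has
  variance σ_i²/n_ij, so the pooled likelihood weights arms by size

Fitting is naïve-pooled weighted maximum likelihood: (τ_LNG, τ_DRSP, H)
are searched on the log scale from a deterministic multistart grid with
σ_i profiled in closed form; uncertainty is Wald (finite-difference
Hessian, delta method). On top of the fitted models the package simulates
bivariate log-normal (τ_PI, τ_OR) pairs to correlate the two endpoints,
and predicts PI/OR for DDI × BMI scenarios over virtual populations,
reporting incidence rate ratios (IRR = rate / no-induction reference
rate) and percent changes.

## Worked example

```python
import numpy as np
from cocpd import fit_model, generate_arms, operational_response
from cocpd.simulate import SynthDesign, published_pi_params

truth = published_pi_params()          # PI parameter set: tau, H, KD, sigma
design = SynthDesign(
    true_params=truth,
    exposure_grid={d: np.linspace(1.8, 5.2, 20) for d in truth.drugs},
    n_per_arm=5000,
    seed=1,
)
arms = generate_arms(design)           # 40 synthetic trial arms
fit = fit_model(arms, "PI", baseline=85.0, imax=1.0)
print(fit.estimates["tau_LNG"], fit.estimates["tau_DRSP"], fit.estimates["hill"])
print(operational_response(2.42, "LNG", fit.to_operational_params()))
```

prints

```
3.0459880299878797 2.601951073449874 9.653667091485229
0.9492166287207593
```

i.e. the fit recovers the generating transducer constants (3.046, 2.602)
and Hill factor (9.653) to four significant digits, and a woman on LNG
with C<sub>avg</sub> = 2.42 ng/mL (the marketed 100 µg dose) has a
predicted Pearl Index of ≈ 0.95 failures per 100 woman-years.

The numbered scripts under `analysis/` run the full study pipeline —
simulate trial arms (01), fit both endpoints (02), correlate τ_PI with
τ_OR (03: mean difference 0.79, Pearson r 0.76 under the packaged
configuration), predict DDI × BMI scenarios (04) and check parameter
recovery (05) — writing tables under `results/`. The same pipeline is
available as a CLI: `cocpd synth | fit | tau-sim | ddi-table | predict`.

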