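# Methods

## Model

Both efficacy endpoints are modelled on their natural reporting scales:
the Pearl Index (PI) in failures per 100 woman-years, the ovulation rate
(OR) in percent. Two forward models are provided.

**Inhibitory Emax** (`cocpd.model.emax_response`), the drug-specific
baseline historically used for levonorgestrel PI meta-analysis, operates
directly on C_avg in ng/mL:

    E = BL · (1 − Imax · C / (IC50 + C))

**Operational model of agonism** (`cocpd.model.operational_response`),
the drug-class model, separates receptor affinity (dissociation constant
K_D, fixed from receptor-binding literature) from intrinsic efficacy (the
transducer constant τ, estimated per drug), with a Hill factor H shared
across drugs within an endpoint. C_avg is converted to molar units with
the progestin's molecular weight (pmol/L = ng/mL · 10⁶ / MW), and the
model operates by default on x = log₁₀(C pmol/L), k_D = log₁₀(K_D
pmol/L):

    E = BL · (1 − Imax · (τx)^H / ((k_D + x)^H + (τx)^H))

A `concentration_scale: linear` switch evaluates the same algebra on the
linear molar scale instead; the published account of the transformation
is ambiguous, so both forms are kept and the log form is the default.
Neither form is claimed to reproduce absolute published scenario
predictions, which depended on external PBPK virtual-population exposures
that are not available (possibly unbound rather than total
concentrations).

Assumptions worth stating explicitly: effects are wholly attributed to
the progestin (ethinyl estradiol enters only as an exposure-stratum
label); Imax = 1 (every woman can become pregnant / ovulate); the
response is monotone non-increasing in exposure; and the model is only
defined for C > 1 pmol/L on the log scale — at or below that boundary the
baseline is returned with a `RuntimeWarning` rather than NaN, since a
sub-picomolar progestin concentration occupies essentially no receptor.

Default constants: BL = 85 (PI) / 100 (OR); log₁₀ K_D = 3.556 (LNG) /
2.949 (DRSP), read as pmol/L, i.e. K_D ≈ 3.6 and 0.9 nmol/L, physiological
for progestin–receptor binding; MW = 312.45 (LNG) / 366.49 (DRSP) g/mol,
standard chemistry references. All are overridable through
`PipelineConfig`.

## Estimation

Naïve-pooled weighted maximum likelihood: all arms share one parameter
set; arm j of drug i contributes a Gaussian term with variance σ_i²/n_ij,
so subject counts weight the fit. The free parameters (τ per drug, H) are
searched as natural logs with L-BFGS-B (gradient tolerance 1e-8, bounds
τ ∈ [1e-2, 1e3], H ∈ [0.1, 100]) from a deterministic 3×3 multistart grid
(τ₀ ∈ {0.3, 1.5, 5}, H₀ ∈ {1, 5, 20}); σ_i has the closed-form profile
MLE σ̂_i² = (1/J_i) Σ_j n_ij (y_ij − ŷ_ij)², floored at 1e-6 so noiseless
fixtures do not degenerate the likelihood. When several starts reach the
same optimum within 1e-6 NLL, a cleanly terminated run is preferred over
one whose final line search failed; a Nelder–Mead polish refines the
winner, and its termination status defines convergence in the σ-floored
regime where NLL differences are meaningless.

Uncertainty is Wald: a central finite-difference Hessian (relative step
1e-4) of the full NLL over (ln τ…, ln H, ln σ…) at the optimum, inverted,
delta-method transformed to the natural scale; CV% = 100·SE/estimate and
95% CI = estimate ± 1.96·SE. The published intervals are symmetric and
consistent with this construction, though their exact method is unstated.
No random effects, bootstrap or model averaging — the design is pooled by
construction.

## τ-pair correlation

Each drug contributes one (τ_PI, τ_OR) point. X = (ln τ_PI, ln τ_OR) is
modelled as bivariate normal with μ the per-component mean over drugs and
Σ the sample covariance (denominator n_drugs − 1); pairs are exp(X),
sampled by Cholesky factor (after symmetrisation; eigenvalues below
−1e-10 are rejected, small negatives clipped). With only two drugs Σ is
rank-1 and every simulated pair would be perfectly correlated, so
estimation uncertainty can be propagated: ln-scale Wald SEs
(≈ CV%/100) are squared, averaged over drugs per component, and added to
the diagonal. The pipeline enables this inflation by default; the plain
construction remains available (`se_inflation=None`). How the original
analysis obtained a non-degenerate covariance from two drugs is not
documented, so no published correlation value is asserted — the packaged
configuration yields r ≈ 0.76 and a mean τ_PI − τ_OR difference ≈ 0.79
as illustrative output.

Natural logs are used for X (the correlation analysis), even though the
concentration axis of the model uses base-10 logs. The paired t-test is
two-sided; zero-variance differences are flagged degenerate rather than
erroring. The Pearson CI is Fisher-z: tanh(atanh r ± 1.96/√(n−3)).

## Exposure fixture and DDI scenarios

Dose→C_avg resolution goes through a lookup table stratified by drug, EE
dose, BMI group (<25, 25–30, ≥30 kg/m²) and inducer (none, CBZ 400 mg,
RIF 600 mg). The packaged table emulates external PBPK model output and
is anchored to published steady-state ranges — LNG 0.54–3.63 ng/mL over
30–150 µg, DRSP 5.47–43.72 ng/mL over 500–4000 µg (near
dose-proportional) — with BMI effects (×1.00/0.88/0.82) and inducer
effects (CBZ ×0.50, RIF ×0.40) applied as multiplicative factors on the
mean. These multipliers are illustrative placeholders, not study-derived;
consequently absolute scenario predictions and percent changes from the
packaged table are demonstrations of the machinery, not reproductions of
published values. Dose queries between table rows are linearly
interpolated within a stratum; BMI and inducer strata are never
interpolated across, and out-of-range doses raise rather than
extrapolate.

Virtual subjects are log-normal around the stratum mean with a geometric
CV (default 30%, typical steroid PK; ln-scale SD = √ln(1+(GCV/100)²), so
the geometric mean equals the table value). Each scenario's endpoint is
the model response averaged over its population; the interval is the
2.5/97.5 percentile across subjects (the published interval construction
is unstated). IRR = scenario mean / reference mean, where the reference
is the no-induction scenario with the same drug, dose, EE and BMI group;
percent change = 100·(IRR − 1), rounded half-up to one decimal in printed
tables (the convention the published table follows — verified on all
printed cells, one of which, DRSP 3000/EE 20 with RIF at BMI < 25, prints
30.3% where its own rounded inputs give 30.4%).

## Synthetic data

`generate_arms` draws one observation per drug × grid point:
y = model mean + ε, ε ~ N(0, σ²/n). Grids are specified directly in
log₁₀ pmol/L, decoupling recovery experiments from the exposure table;
`dose_level_grid` provides the sparse grid at the actually-studied dose
levels as an alternative preset. Observations are deliberately not
truncated at zero — the additive-normal error model allows negative
arm-level values where the mean is near zero, and truncation would bias
the estimator the data are meant to test. File readers therefore accept
negative observed values with a logged warning (real endpoint data cannot
be negative) while hard-rejecting invalid subject counts and enum values.

What the generator emulates: the arm-level summary structure, 1/n
variance scaling, and per-drug residual scales of a pooled meta-analysis
(the driver scripts use 20 arms/drug × 450 subjects ≈ the 36,040 women of
the real dataset). What it does not: between-study heterogeneity,
differing ovulation-detection methodologies, varying study durations, and
pregnancies as a count process. Passing recovery tests therefore show
that the estimator is consistent under its own assumptions — not that
those assumptions hold in real trial data.

The standard recovery experiment (`generate_recovery_suite`, also run by
`scripts/acceptance.py` and `analysis/05`) uses 20 replicates of 20
arms/drug on x ∈ [1.8, 5.2] — a span covering both drugs' steep
transition regions, which the sparse real dose sets do not — with 5000
subjects/arm, and refits each; medians across replicates recover the
generating τ_LNG, τ_DRSP and H to well within 5%. These problem sizes
keep the whole suite and the acceptance script in the tens of seconds.

## Known limitations

- Absolute PI/OR scenario values depend on the placeholder exposure
  multipliers; only the relative machinery (IRR, percent change) is
  exact.
- The τ-covariance inflation is this package's design choice for making
  a two-drug covariance usable; with ≥3 drugs the plain construction
  becomes meaningful.
- Wald intervals can be poor for steep Hill factors at sparse designs;
  the coverage check in the test suite uses a well-identified small
  model.
- With two PI dose levels both near the response floor (the real DRSP
  design), τ_DRSP is weakly identified; the wide synthetic grid exists
  precisely because of this.
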