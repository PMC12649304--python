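"""Pooled weighted likelihood, profile sigma and model fitting."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cocpd.fitting import (
    FitResult,
    fit_emax,
    fit_model,
    neg_log_likelihood,
    profile_sigma,
)
from cocpd.model import Endpoint, OperationalParams, TrialArm, operational_response
from cocpd.simulate import SynthDesign, generate_arms


def one_drug_params(sigma=0.5, tau=3.0, hill=9.0, kd=3.556):
    return OperationalParams(
        endpoint=Endpoint.PI, baseline=85.0, imax=1.0, hill=hill,
        tau={"LNG": tau}, log10_kd={"LNG": kd}, sigma={"LNG": sigma},
    )


def arm(observed, n, cavg=2.0, arm_id="a"):
    return TrialArm(
        study_id="s", arm_id=arm_id, drug_id="LNG", dose_ug=0.0, ee_dose_ug=0.0,
        endpoint=Endpoint.PI, observed=observed, n_subjects=n, cavg=cavg,
    )


class TestNegLogLikelihood:
    def test_zero_residual_constant_term(self):
        # 0.5*ln(2*pi*sigma^2/n) with sigma = 0.5, n = 100
        p = one_drug_params(sigma=0.5)
        yhat = operational_response(2.0, "LNG", p)
        nll = neg_log_likelihood(p, [arm(yhat, 100)])
        assert nll == pytest.approx(-2.076793740349318, abs=1e-12)

    def test_half_unit_residual(self):
        p = one_drug_params(sigma=0.5)
        yhat = operational_response(2.0, "LNG", p)
        nll = neg_log_likelihood(p, [arm(yhat + 0.5, 100)])
        assert nll == pytest.approx(47.923206259650684, abs=1e-9)

    def test_doubling_n_shifts_by_half_log2(self):
        p = one_drug_params()
        yhat = operational_response(2.0, "LNG", p)
        delta = (neg_log_likelihood(p, [arm(yhat, 200)])
                 - neg_log_likelihood(p, [arm(yhat, 100)]))
        assert delta == pytest.approx(-0.5 * np.log(2.0), abs=1e-12)

    def test_permutation_invariance(self, pi_params, noisy_arms):
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(noisy_arms)))
        a = neg_log_likelihood(pi_params, noisy_arms)
        b = neg_log_likelihood(pi_params, [noisy_arms[i] for i in perm])
        assert abs(a - b) < 1e-10

    def test_unknown_drug_raises(self):
        p = one_drug_params()
        bad = arm(1.0, 10)
        bad.drug_id = "NET"
        with pytest.raises(KeyError):
            neg_log_likelihood(p, [bad])


class TestProfileSigma:
    def test_closed_form_two_arms(self):
        # residuals (+1, -1) with n = (4, 9): sigma^2 = (4 + 9)/2
        p = one_drug_params()
        y1 = operational_response(2.0, "LNG", p) + 1.0
        y2 = operational_response(3.0, "LNG", p) - 1.0
        arms = [arm(y1, 4, cavg=2.0, arm_id="a"), arm(y2, 9, cavg=3.0, arm_id="b")]
        sig = profile_sigma(p, arms)
        assert sig["LNG"] == pytest.approx(np.sqrt(6.5), rel=1e-12)

    def test_floor_on_zero_residuals(self):
        p = one_drug_params()
        y = operational_response(2.0, "LNG", p)
        assert profile_sigma(p, [arm(y, 10)])["LNG"] == 1e-6

    def test_matches_numeric_minimisation(self, pi_params, noisy_arms):
        sig_hat = profile_sigma(pi_params, noisy_arms)
        for drug in pi_params.drugs:
            def nll_of_sigma(s):
                q = OperationalParams(
                    endpoint=pi_params.endpoint, baseline=pi_params.baseline,
                    imax=pi_params.imax, hill=pi_params.hill,
                    tau=dict(pi_params.tau), log10_kd=dict(pi_params.log10_kd),
                    sigma={**sig_hat, drug: s},
                )
                return neg_log_likelihood(q, noisy_arms)
            res = minimize_scalar(nll_of_sigma, bounds=(1e-4, 50.0), method="bounded",
                                  options={"xatol": 1e-10})
            assert res.x == pytest.approx(sig_hat[drug], rel=1e-6)

    def test_optimality(self, pi_params, noisy_arms):
        sig_hat = profile_sigma(pi_params, noisy_arms)
        base = neg_log_likelihood(
            pi_params.__class__(**{**pi_params.__dict__, "sigma": sig_hat}), noisy_arms
        )
        for f in (0.99, 1.01):
            pert = {d: s * f for d, s in sig_hat.items()}
            alt = neg_log_likelihood(
                pi_params.__class__(**{**pi_params.__dict__, "sigma": pert}), noisy_arms
            )
            assert base <= alt


class TestFitModel:
    def test_noiseless_recovery(self, pi_params, noiseless_arms):
        res = fit_model(noiseless_arms, "PI", baseline=85.0, imax=1.0)
        assert res.converged
        assert res.estimates["tau_LNG"] == pytest.approx(3.046, rel=1e-3)
        assert res.estimates["tau_DRSP"] == pytest.approx(2.602, rel=1e-3)
        assert res.estimates["hill"] == pytest.approx(9.653, rel=1e-3)

    def test_nll_consistency_at_truth(self, pi_params, noisy_arms):
        # plugging truth + profiled sigma into the NLL reproduces the
        # objective the optimiser sees
        from cocpd.fitting import _ArmMatrix
        from cocpd.model import DEFAULT_DRUGS
        sig_hat = profile_sigma(pi_params, noisy_arms)
        p_hat = pi_params.__class__(**{**pi_params.__dict__, "sigma": sig_hat})
        direct = neg_log_likelihood(p_hat, noisy_arms)
        mat = _ArmMatrix(noisy_arms, DEFAULT_DRUGS, "log10")
        tau_vec = np.array([pi_params.tau[d] for d in mat.drugs])
        kd_vec = np.array([pi_params.log10_kd[d] for d in mat.drugs])
        yhat = mat.predict(tau_vec, pi_params.hill, kd_vec, 85.0, 1.0)
        assert mat.profiled_nll(yhat)[0] == pytest.approx(direct, rel=1e-12)

    def test_degenerate_design_raises(self, pi_params):
        p = one_drug_params()
        y = operational_response(2.0, "LNG", p)
        arms = [arm(y, 10, cavg=2.0, arm_id=f"a{i}") for i in range(3)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_model(arms, "PI", baseline=85.0)

    def test_json_round_trip(self, noiseless_arms, tmp_path):
        res = fit_model(noiseless_arms, "PI", baseline=85.0)
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = FitResult.from_json(path)
        # NaN-tolerant equality (SEs can be undefined on degenerate data)
        np.testing.assert_equal(back.estimates, res.estimates)
        np.testing.assert_equal(back.ci95, res.ci95)
        assert back.endpoint is res.endpoint

    def test_ci_brackets_estimate(self, noisy_arms):
        res = fit_model(noisy_arms, "PI", baseline=85.0)
        assert res.converged
        for name, est in res.estimates.items():
            lo, hi = res.ci95[name]
            assert lo <= est <= hi
            assert res.cv_percent[name] >= 0


class TestFitEmax:
    @staticmethod
    def emax_arms(ic50=2.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        arms = []
        for k, c in enumerate(np.linspace(0.2, 10.0, 10)):
            y = 85.0 * (1.0 - c / (ic50 + c)) + noise * rng.standard_normal()
            arms.append(arm(float(y), 150, cavg=float(c), arm_id=f"e{k}"))
        return arms

    def test_noiseless_recovery(self):
        res = fit_emax(self.emax_arms(ic50=2.0), baseline=85.0)
        assert res.converged
        assert res.estimates["ic50"] == pytest.approx(2.0, rel=1e-3)

    def test_cv_identity(self):
        res = fit_emax(self.emax_arms(ic50=2.0, noise=0.5, seed=3), baseline=85.0)
        for name in res.estimates:
            if np.isfinite(res.se[name]):
                assert res.cv_percent[name] == pytest.approx(
                    100.0 * res.se[name] / res.estimates[name], rel=1e-12
                )

    def test_wald_coverage(self):
        # nominal 95% interval should cover roughly 95% of the time
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            res = fit_emax(self.emax_arms(ic50=2.0, noise=0.8, seed=s),
                           baseline=85.0, starts=(1.0, 5.0))
            lo, hi = res.ci95["ic50"]
            hits += lo <= 2.0 <= hi
        assert 0.90 <= hits / n_rep <= 0.99
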