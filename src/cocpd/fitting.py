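"""Naive-pooled weighted maximum-likelihood estimation.

All study arms are fitted jointly with a single parameter set (no random
effects).  The residual model is additive and arm-level: the observed
endpoint of arm j for drug i is

    y_ij = yhat_ij + eps_ij,    eps_ij ~ N(0, sigma_i^2 / n_ij)

so larger arms carry proportionally more weight.  The per-drug residual
scale sigma_i has a closed-form profile MLE, which the optimiser exploits:
only the transducer constants (one per drug) and the shared Hill factor
are searched numerically, on the natural-log scale, from a deterministic
grid of starting points.  Standard errors are Wald, from the inverse of a
central-finite-difference Hessian of the full negative log-likelihood at
the optimum, delta-method transformed back to the natural scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from cocpd.model import (
    DEFAULT_DRUGS,
    DrugSpec,
    EmaxParams,
    Endpoint,
    OperationalParams,
    TrialArm,
    emax_response,
    operational_response,
)

__all__ = [
    "FitResult",
    "neg_log_likelihood",
    "profile_sigma",
    "fit_model",
    "fit_emax",
]

SIGMA_FLOOR = 1e-6
TAU_BOUNDS = (1e-2, 1e3)
HILL_BOUNDS = (0.1, 100.0)
GRAD_TOL = 1e-8
#: deterministic multistart grid: every (tau, H) combination is tried
TAU_STARTS = (0.3, 1.5, 5.0)
HILL_STARTS = (1.0, 5.0, 20.0)


@dataclass
class FitResult:
    """Estimates with Wald uncertainty for one endpoint's model fit.

    ``estimates`` holds free parameters and the profiled residual scales;
    ``fixed`` holds the parameters that were held at constants.  CV% is
    100*SE/estimate and the 95% CI is estimate +/- 1.96*SE on the natural
    scale.
    """

    endpoint: Endpoint
    model: str
    estimates: dict[str, float]
    fixed: dict[str, float]
    se: dict[str, float]
    cv_percent: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    loglik: float
    converged: bool
    n_arms: int
    n_subjects_total: int
    multistart: list[dict] = field(default_factory=list)
    message: str = ""

    def to_dict(self) -> dict:
        d = {
            "endpoint": self.endpoint.value,
            "model": self.model,
            "estimates": self.estimates,
            "fixed": self.fixed,
            "se": self.se,
            "cv_percent": self.cv_percent,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_arms": self.n_arms,
            "n_subjects_total": self.n_subjects_total,
            "multistart": self.multistart,
            "message": self.message,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            endpoint=Endpoint(d["endpoint"]),
            model=d["model"],
            estimates=dict(d["estimates"]),
            fixed=dict(d["fixed"]),
            se=dict(d["se"]),
            cv_percent=dict(d["cv_percent"]),
            ci95={k: (v[0], v[1]) for k, v in d["ci95"].items()},
            loglik=d["loglik"],
            converged=d["converged"],
            n_arms=d["n_arms"],
            n_subjects_total=d["n_subjects_total"],
            multistart=list(d.get("multistart", [])),
            message=d.get("message", ""),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_operational_params(self, concentration_scale: str = "log10") -> OperationalParams:
        """Rebuild the full parameter set from an operational-model fit."""
        if self.model != "operational":
            raise ValueError(f"not an operational-model fit: {self.model}")
        tau = self.tau_map()
        return OperationalParams(
            endpoint=self.endpoint,
            baseline=self.fixed["baseline"],
            imax=self.fixed["imax"],
            hill=self.estimates["hill"],
            tau=tau,
            log10_kd={d: self.fixed[f"log10_kd_{d}"] for d in tau},
            sigma=self.sigma_map(),
            fixed_flags={"baseline": True, "imax": True, "log10_kd": True},
            concentration_scale=concentration_scale,
        )

    def tau_map(self) -> dict[str, float]:
        """Per-drug transducer constants, for operational-model fits."""
        return {
            k.removeprefix("tau_"): v
            for k, v in self.estimates.items()
            if k.startswith("tau_")
        }

    def sigma_map(self) -> dict[str, float]:
        return {
            k.removeprefix("sigma_"): v
            for k, v in self.estimates.items()
            if k.startswith("sigma_")
        }


def _check_arms(arms: Sequence[TrialArm], endpoint: Endpoint | None = None) -> None:
    if not arms:
        raise ValueError("no trial arms given")
    for a in arms:
        if a.cavg is None:
            raise ValueError(
                f"arm {a.study_id}/{a.arm_id} has no resolved cavg; "
                "resolve exposure before fitting"
            )
        if endpoint is not None and a.endpoint is not endpoint:
            raise ValueError(
                f"arm {a.study_id}/{a.arm_id} endpoint {a.endpoint.value} "
                f"does not match {endpoint.value}"
            )


def neg_log_likelihood(
    params: OperationalParams,
    arms: Sequence[TrialArm],
    specs: Mapping[str, DrugSpec] | None = None,
) -> float:
    """Exact Gaussian negative log-likelihood of the pooled arm data.

    NLL = sum over arms of
    0.5*ln(2*pi*sigma_i^2/n_ij) + n_ij*(y_ij - yhat_ij)^2 / (2*sigma_i^2).
    """
    _check_arms(arms, params.endpoint)
    total = 0.0
    for a in arms:
        if a.drug_id not in params.tau:
            raise KeyError(f"arm {a.study_id}/{a.arm_id}: unknown drug {a.drug_id!r}")
        sig = params.sigma[a.drug_id]
        if sig <= 0:
            raise ValueError(f"sigma[{a.drug_id}] must be > 0, got {sig}")
        yhat = operational_response(a.cavg, a.drug_id, params, specs)
        var = sig**2 / a.n_subjects
        total += 0.5 * np.log(2.0 * np.pi * var) + (a.observed - yhat) ** 2 / (2.0 * var)
    return float(total)


def profile_sigma(
    params: OperationalParams,
    arms: Sequence[TrialArm],
    specs: Mapping[str, DrugSpec] | None = None,
) -> dict[str, float]:
    """Closed-form profile MLE of the per-drug residual scale.

    sigma_i^2 = (1/J_i) * sum_j n_ij * (y_ij - yhat_ij)^2 over the J_i
    arms of drug i.  Drugs with no arms are excluded; a floor of 1e-6
    guards against degenerate (zero-residual) data.
    """
    _check_arms(arms, params.endpoint)
    ss: dict[str, float] = {}
    counts: dict[str, int] = {}
    for a in arms:
        yhat = operational_response(a.cavg, a.drug_id, params, specs)
        ss[a.drug_id] = ss.get(a.drug_id, 0.0) + a.n_subjects * (a.observed - yhat) ** 2
        counts[a.drug_id] = counts.get(a.drug_id, 0) + 1
    return {
        d: max(float(np.sqrt(ss[d] / counts[d])), SIGMA_FLOOR) for d in ss
    }


# ---------------------------------------------------------------------------
# vectorised internals


class _ArmMatrix:
    """Arms flattened to arrays for fast likelihood evaluation."""

    def __init__(
        self,
        arms: Sequence[TrialArm],
        specs: Mapping[str, DrugSpec],
        concentration_scale: str,
    ):
        self.drugs = sorted({a.drug_id for a in arms})
        idx = {d: k for k, d in enumerate(self.drugs)}
        self.drug_idx = np.array([idx[a.drug_id] for a in arms])
        self.y = np.array([a.observed for a in arms], dtype=float)
        self.n = np.array([a.n_subjects for a in arms], dtype=float)
        cavg = np.array([a.cavg for a in arms], dtype=float)
        mw = np.array([specs[a.drug_id].molecular_weight for a in arms])
        c_molar = cavg * 1e6 / mw
        if concentration_scale == "log10":
            self.x = np.log10(c_molar)
            if np.any(self.x <= 0):
                raise ValueError(
                    "arm concentration <= 1 pmol/L lies outside the log-domain model"
                )
        else:
            self.x = c_molar
        self.n_arms_per_drug = np.bincount(self.drug_idx, minlength=len(self.drugs))
        for d, j in zip(self.drugs, self.n_arms_per_drug):
            if np.unique(self.x[self.drug_idx == idx[d]]).size < 2:
                raise ValueError(
                    f"degenerate design: drug {d!r} has fewer than 2 distinct "
                    "exposure levels"
                )

    def predict(self, tau_vec: np.ndarray, hill: float, kd_vec: np.ndarray,
                baseline: float, imax: float) -> np.ndarray:
        tau = tau_vec[self.drug_idx]
        kd = kd_vec[self.drug_idx]
        log_num = hill * np.log(tau * self.x)
        log_den = hill * np.log(kd + self.x)
        m = np.maximum(log_num, log_den)
        frac = np.exp(log_num - m) / (np.exp(log_den - m) + np.exp(log_num - m))
        return baseline * (1.0 - imax * frac)

    def profiled_nll(self, yhat: np.ndarray) -> tuple[float, np.ndarray]:
        """Profile out sigma; return (NLL at sigma-hat, sigma-hat per drug)."""
        wsq = self.n * (self.y - yhat) ** 2
        ss = np.bincount(self.drug_idx, weights=wsq, minlength=len(self.drugs))
        sig2 = np.maximum(ss / self.n_arms_per_drug, SIGMA_FLOOR**2)
        sig2_arm = sig2[self.drug_idx]
        nll = np.sum(0.5 * np.log(2.0 * np.pi * sig2_arm / self.n) + wsq / (2.0 * sig2_arm))
        return float(nll), np.sqrt(sig2)

    def full_nll(self, yhat: np.ndarray, sigma_vec: np.ndarray) -> float:
        sig2_arm = sigma_vec[self.drug_idx] ** 2
        wsq = self.n * (self.y - yhat) ** 2
        return float(
            np.sum(0.5 * np.log(2.0 * np.pi * sig2_arm / self.n) + wsq / (2.0 * sig2_arm))
        )


def _select_best(runs):
    """Lowest-NLL run, preferring clean terminations within tolerance.

    Several starts typically reach the same optimum; a run whose line
    search failed in the last step can undercut the successful ones by a
    numerically meaningless margin, so any successful run within 1e-6 of
    the minimum wins over an unsuccessful one.
    """
    best_fun = min(r.fun for r in runs)
    tol = max(1e-6, 1e-8 * abs(best_fun))
    near = [r for r in runs if r.fun <= best_fun + tol]
    ok = [r for r in near if r.success]
    pool = ok if ok else near
    return min(pool, key=lambda r: r.fun)


def _fd_hessian(f, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2.0 * f(theta) + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def _wald_tables(
    names: list[str], values: np.ndarray, hess: np.ndarray
) -> tuple[dict, dict, dict]:
    """SE/CV/CI maps from a working-scale (log) Hessian via the delta method."""
    se_work = np.full(len(names), np.nan)
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        with np.errstate(invalid="ignore"):
            se_work = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
    except np.linalg.LinAlgError:
        pass
    se = {}
    cv = {}
    ci = {}
    for name, val, sw in zip(names, values, se_work):
        s = val * sw  # d exp(u)/du = exp(u)
        se[name] = float(s)
        cv[name] = float(100.0 * s / val) if val != 0 else float("nan")
        ci[name] = (float(val - 1.96 * s), float(val + 1.96 * s))
    return se, cv, ci


def fit_model(
    arms: Sequence[TrialArm],
    endpoint: Endpoint | str,
    baseline: float,
    imax: float = 1.0,
    log10_kd: Mapping[str, float] | None = None,
    specs: Mapping[str, DrugSpec] | None = None,
    concentration_scale: str = "log10",
    starts: Iterable[tuple[float, float]] | None = None,
    grad_tol: float = GRAD_TOL,
) -> FitResult:
    """Fit the operational model: free (tau per drug, shared H), sigma profiled.

    Baseline, Imax and the per-drug log10 KD are fixed.  The search runs
    on (ln tau_1, ..., ln tau_D, ln H) from every start in a deterministic
    grid; the best optimum is kept.

    Parameters
    ----------
    arms
        Trial arms with resolved ``cavg``; all must share ``endpoint``.
    baseline, imax
        Fixed system parameters (85 and 1 for PI; 100 and 1 for OR).
    log10_kd
        Per-drug fixed log10 dissociation constants (pmol/L scale);
        defaults to the registry values.
    starts
        Optional explicit (tau, H) start list replacing the default grid.
    """
    endpoint = Endpoint(endpoint)
    specs = DEFAULT_DRUGS if specs is None else specs
    _check_arms(arms, endpoint)
    mat = _ArmMatrix(arms, specs, concentration_scale)
    drugs = mat.drugs
    if log10_kd is None:
        log10_kd = {d: specs[d].log10_kd for d in drugs}
    kd_vec = np.array([log10_kd[d] for d in drugs])
    D = len(drugs)

    lb = np.concatenate([np.full(D, np.log(TAU_BOUNDS[0])), [np.log(HILL_BOUNDS[0])]])
    ub = np.concatenate([np.full(D, np.log(TAU_BOUNDS[1])), [np.log(HILL_BOUNDS[1])]])

    def objective(theta: np.ndarray) -> float:
        tau_vec = np.exp(theta[:D])
        hill = np.exp(theta[D])
        yhat = mat.predict(tau_vec, hill, kd_vec, baseline, imax)
        return mat.profiled_nll(yhat)[0]

    if starts is None:
        starts = [(t0, h0) for t0 in TAU_STARTS for h0 in HILL_STARTS]
    multistart_log = []
    runs = []
    for t0, h0 in starts:
        theta0 = np.concatenate([np.full(D, np.log(t0)), [np.log(h0)]])
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={"gtol": grad_tol, "ftol": 1e-12, "maxiter": 1000},
        )
        multistart_log.append(
            {"start_tau": t0, "start_hill": h0, "nll": float(res.fun),
             "success": bool(res.success)}
        )
        runs.append(res)
    best = _select_best(runs)

    # derivative-free polish; on degenerate (noiseless, sigma-floored) data
    # L-BFGS-B can stop with a failed line search at the optimum, so
    # convergence is judged by whether the polish can still improve
    polish = minimize(objective, best.x, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    theta_hat = np.clip(polish.x, lb, ub) if polish.fun <= best.fun else best.x
    converged = bool(best.success) or bool(polish.success)
    tau_hat = np.exp(theta_hat[:D])
    hill_hat = float(np.exp(theta_hat[D]))
    yhat = mat.predict(tau_hat, hill_hat, kd_vec, baseline, imax)
    nll_min, sigma_hat = mat.profiled_nll(yhat)

    # full-parameter Hessian (tau, H, sigma all on the ln scale) for Wald SEs
    def full_obj(theta_full: np.ndarray) -> float:
        tv = np.exp(theta_full[:D])
        hh = np.exp(theta_full[D])
        sv = np.exp(theta_full[D + 1:])
        return mat.full_nll(mat.predict(tv, hh, kd_vec, baseline, imax), sv)

    theta_full = np.concatenate([theta_hat, np.log(sigma_hat)])
    hess = _fd_hessian(full_obj, theta_full)
    names = [f"tau_{d}" for d in drugs] + ["hill"] + [f"sigma_{d}" for d in drugs]
    values = np.concatenate([tau_hat, [hill_hat], sigma_hat])
    se, cv, ci = _wald_tables(names, values, hess)

    return FitResult(
        endpoint=endpoint,
        model="operational",
        estimates={n: float(v) for n, v in zip(names, values)},
        fixed={"baseline": baseline, "imax": imax,
               **{f"log10_kd_{d}": float(log10_kd[d]) for d in drugs}},
        se=se,
        cv_percent=cv,
        ci95=ci,
        loglik=-nll_min,
        converged=converged,
        n_arms=len(arms),
        n_subjects_total=int(sum(a.n_subjects for a in arms)),
        multistart=multistart_log,
        message=str(best.message),
    )


def fit_emax(
    arms: Sequence[TrialArm],
    baseline: float,
    imax: float = 1.0,
    starts: Iterable[float] | None = None,
    grad_tol: float = GRAD_TOL,
) -> FitResult:
    """Fit the inhibitory Emax model: free IC50, sigma profiled per drug."""
    if not arms:
        raise ValueError("no trial arms given")
    endpoint = arms[0].endpoint
    _check_arms(arms, endpoint)
    drugs = sorted({a.drug_id for a in arms})
    idx = {d: k for k, d in enumerate(drugs)}
    drug_idx = np.array([idx[a.drug_id] for a in arms])
    y = np.array([a.observed for a in arms])
    n = np.array([a.n_subjects for a in arms], dtype=float)
    cavg = np.array([a.cavg for a in arms])
    n_per = np.bincount(drug_idx, minlength=len(drugs))
    for d in drugs:
        if np.unique(cavg[drug_idx == idx[d]]).size < 2:
            raise ValueError(
                f"degenerate design: drug {d!r} has fewer than 2 distinct exposure levels"
            )

    def nll_of(ic50: float, sigma_vec: np.ndarray | None = None):
        yhat = baseline * (1.0 - imax * cavg / (ic50 + cavg))
        wsq = n * (y - yhat) ** 2
        ss = np.bincount(drug_idx, weights=wsq, minlength=len(drugs))
        if sigma_vec is None:
            sig2 = np.maximum(ss / n_per, SIGMA_FLOOR**2)
        else:
            sig2 = sigma_vec**2
        s2a = sig2[drug_idx]
        nll = np.sum(0.5 * np.log(2.0 * np.pi * s2a / n) + wsq / (2.0 * s2a))
        return float(nll), np.sqrt(sig2)

    if starts is None:
        starts = (0.1, 1.0, 5.0, 20.0, 100.0)
    multistart_log = []
    runs = []
    for ic0 in starts:
        res = minimize(
            lambda th: nll_of(float(np.exp(th[0])))[0],
            np.array([np.log(ic0)]),
            method="L-BFGS-B",
            bounds=[(np.log(1e-6), np.log(1e6))],
            options={"gtol": grad_tol, "ftol": 1e-12, "maxiter": 1000},
        )
        multistart_log.append({"start_ic50": ic0, "nll": float(res.fun),
                               "success": bool(res.success)})
        runs.append(res)
    best = _select_best(runs)

    polish = minimize(lambda th: nll_of(float(np.exp(th[0])))[0], best.x,
                      method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    theta_best = polish.x if polish.fun <= best.fun else best.x
    converged = bool(best.success) or bool(polish.success)
    ic50_hat = float(np.clip(np.exp(theta_best[0]), 1e-6, 1e6))
    nll_min, sigma_hat = nll_of(ic50_hat)

    def full_obj(theta_full: np.ndarray) -> float:
        return nll_of(float(np.exp(theta_full[0])), np.exp(theta_full[1:]))[0]

    theta_full = np.concatenate([[np.log(ic50_hat)], np.log(sigma_hat)])
    hess = _fd_hessian(full_obj, theta_full)
    names = ["ic50"] + [f"sigma_{d}" for d in drugs]
    values = np.concatenate([[ic50_hat], sigma_hat])
    se, cv, ci = _wald_tables(names, values, hess)

    return FitResult(
        endpoint=endpoint,
        model="emax",
        estimates={nme: float(v) for nme, v in zip(names, values)},
        fixed={"baseline": baseline, "imax": imax},
        se=se,
        cv_percent=cv,
        ci95=ci,
        loglik=-nll_min,
        converged=converged,
        n_arms=len(arms),
        n_subjects_total=int(sum(a.n_subjects for a in arms)),
        multistart=multistart_log,
        message=str(best.message),
    )
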