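"""Bivariate log-normal simulation and correlation of transducer constants.

The fitted transducer constants for the Pearl-Index model (tau_PI) and the
ovulation-rate model (tau_OR) form one (tau_PI, tau_OR) point per drug.
Taking natural logs, X = (ln tau_PI, ln tau_OR) is modelled as bivariate
normal with mean mu (per-component mean over drugs) and covariance Sigma
(sample covariance over drugs, denominator n_drugs - 1).  Pairs drawn from
exp(X) are then compared with a paired t-test and Pearson correlation.

With only two drugs the two-point sample covariance is rank-1, so
simulated pairs would be perfectly correlated (r = +/-1).  To propagate
estimation uncertainty, the Wald standard errors of ln tau (approximately
CV/100 of the natural-scale estimates) can be added to the diagonal of
Sigma, which breaks the degeneracy; this inflation is optional and off by
default at the function level, on by default in the pipeline
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TauDistribution",
    "TauPairs",
    "build_tau_distribution",
    "simulate_tau_pairs",
    "paired_t_test",
    "pearson_correlation",
]

PSD_TOL = 1e-10


@dataclass
class TauDistribution:
    """Bivariate normal law of (ln tau_PI, ln tau_OR).

    ``mu`` is the 2-vector of natural-log means, ``sigma_mat`` the 2x2
    covariance.  ``provenance`` records the input estimates and any
    uncertainty inflation applied.
    """

    mu: np.ndarray
    sigma_mat: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma_mat = np.asarray(self.sigma_mat, dtype=float)
        if self.mu.shape != (2,) or self.sigma_mat.shape != (2, 2):
            raise ValueError("mu must be length-2 and sigma_mat 2x2")
        if not np.allclose(self.sigma_mat, self.sigma_mat.T, atol=1e-12):
            raise ValueError("sigma_mat must be symmetric")
        if np.min(np.linalg.eigvalsh(self.sigma_mat)) < -1e-12:
            raise ValueError("sigma_mat must be positive semi-definite")


@dataclass
class TauPairs:
    """Simulated (tau_PI, tau_OR) pairs on the natural scale."""

    pairs: np.ndarray  # shape (n, 2), columns tau_pi, tau_or
    seed: int
    n: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float)
        if self.pairs.shape != (self.n, 2):
            raise ValueError(f"pairs must have shape ({self.n}, 2)")
        if np.any(self.pairs <= 0):
            raise ValueError("tau pairs must be positive")

    @property
    def tau_pi(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def tau_or(self) -> np.ndarray:
        return self.pairs[:, 1]


def build_tau_distribution(
    tau_pi: Mapping[str, float],
    tau_or: Mapping[str, float],
    se_inflation: Mapping[str, tuple[float, float]] | float | None = None,
) -> TauDistribution:
    """Build the bivariate log-normal law from per-drug tau estimates.

    Parameters
    ----------
    tau_pi, tau_or
        Per-drug transducer estimates for the two endpoints; the drug
        sets must coincide and contain at least two drugs.
    se_inflation
        Optional Wald uncertainty on the ln scale.  Either a map
        drug -> (se_ln_tau_pi, se_ln_tau_or) — the mean squared SE per
        component is added to the corresponding diagonal entry of
        Sigma — or a scalar applied to both components (0 disables).
    """
    if set(tau_pi) != set(tau_or):
        raise ValueError(
            f"drug sets differ: {sorted(tau_pi)} vs {sorted(tau_or)}"
        )
    drugs = sorted(tau_pi)
    if len(drugs) < 2:
        raise ValueError("at least two drugs are required (covariance undefined)")
    X = np.log(np.array([[tau_pi[d], tau_or[d]] for d in drugs], dtype=float))
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)

    inflation = np.zeros(2)
    if se_inflation is not None:
        if np.isscalar(se_inflation):
            inflation[:] = float(se_inflation) ** 2
        else:
            se_arr = np.array([list(se_inflation[d]) for d in drugs], dtype=float)
            inflation = np.mean(se_arr**2, axis=0)
        sigma = sigma + np.diag(inflation)

    return TauDistribution(
        mu=mu,
        sigma_mat=sigma,
        provenance={
            "drugs": drugs,
            "tau_pi": {d: float(tau_pi[d]) for d in drugs},
            "tau_or": {d: float(tau_or[d]) for d in drugs},
            "ln_se_inflation_diag": inflation.tolist(),
        },
    )


def simulate_tau_pairs(dist: TauDistribution, n: int, seed: int) -> TauPairs:
    """Draw ``n`` (tau_PI, tau_OR) pairs: exp of a bivariate normal sample.

    Sampling uses a Cholesky factor after symmetrisation; a covariance
    with eigenvalues below -1e-10 is rejected, and tiny negative
    eigenvalues are clipped to zero.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    S = 0.5 * (dist.sigma_mat + dist.sigma_mat.T)
    w, V = np.linalg.eigh(S)
    if np.min(w) < -PSD_TOL:
        raise ValueError(f"covariance is not PSD (min eigenvalue {np.min(w):.3e})")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)  # S = L @ L.T
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, 2))
    X = dist.mu + Z @ L.T
    return TauPairs(pairs=np.exp(X), seed=seed, n=n)


def paired_t_test(pairs: TauPairs) -> dict:
    """Two-sided paired t-test on tau_PI - tau_OR.

    Returns mean difference, its 95% CI, t, df and p.  With zero variance
    of the differences the test statistic is undefined: p is NaN, the CI
    has width zero and ``degenerate`` is flagged.
    """
    d = pairs.tau_pi - pairs.tau_or
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    dbar = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        return {
            "mean_diff": dbar, "ci95": (dbar, dbar), "t": float("nan"),
            "df": df, "p": float("nan"), "degenerate": True,
        }
    tcrit = stats.t.ppf(0.975, df)
    se = sd / np.sqrt(n)
    tstat = dbar / se
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return {
        "mean_diff": dbar,
        "ci95": (dbar - tcrit * se, dbar + tcrit * se),
        "t": float(tstat),
        "df": df,
        "p": float(p),
        "degenerate": False,
    }


def pearson_correlation(pairs: TauPairs) -> dict:
    """Pearson r between tau_PI and tau_OR with a Fisher-z 95% CI.

    CI = tanh(atanh(r) +/- 1.96/sqrt(n-3)); the two-sided p comes from
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x, y = pairs.tau_pi, pairs.tau_or
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs for the Fisher-z interval")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("a component is constant; correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) == 1.0:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        half = 1.96 / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return {"r": r, "ci95": (lo, hi), "p": float(p), "n": n}


def lognormal_correlation(mu: Sequence[float], sigma_mat: np.ndarray) -> float:
    """Analytic Pearson correlation of a bivariate log-normal vector.

    corr(Y1, Y2) = (exp(s12) - 1) / sqrt((exp(s11) - 1)(exp(s22) - 1))
    where sij are the normal-scale (co)variances.  Used as an independent
    oracle for simulation tests.
    """
    S = np.asarray(sigma_mat, dtype=float)
    num = np.exp(S[0, 1]) - 1.0
    den = np.sqrt((np.exp(S[0, 0]) - 1.0) * (np.exp(S[1, 1]) - 1.0))
    return float(num / den)
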