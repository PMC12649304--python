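"""Correlate intrinsic efficacy across endpoints.

Builds the bivariate log-normal distribution of (tau_PI, tau_OR) from the
published operational-model estimates, with the published Wald CV%
converted to ln-scale variance and added to the diagonal of the two-drug
covariance (the plain two-point covariance is rank-1, which would force a
perfect correlation).  Simulates 500 pairs and runs the paired t-test and
Pearson correlation with a Fisher-z interval.  The refit of the synthetic
datasets (step 02) reproduces the central values but with far smaller
uncertainty — its dense design is more informative than the real
meta-analysis — so the published uncertainty is the relevant input here.
Writes results/tau_pairs.csv and results/tau_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from cocpd.io import write_table
from cocpd.simulate import (
    PUBLISHED_TAU_CV_PERCENT,
    published_or_params,
    published_pi_params,
)
from cocpd.taucorr import (
    build_tau_distribution,
    paired_t_test,
    pearson_correlation,
    simulate_tau_pairs,
)

OUT = Path(__file__).resolve().parents[1] / "results"
N_PAIRS, SEED = 500, 103

tau_pi = published_pi_params().tau
tau_or = published_or_params().tau
se_inflation = {
    d: (PUBLISHED_TAU_CV_PERCENT["PI"][d] / 100.0,
        PUBLISHED_TAU_CV_PERCENT["OR"][d] / 100.0)
    for d in tau_pi
}
dist = build_tau_distribution(tau_pi, tau_or, se_inflation=se_inflation)
pairs = simulate_tau_pairs(dist, n=N_PAIRS, seed=SEED)
ttest = paired_t_test(pairs)
corr = pearson_correlation(pairs)

write_table(pd.DataFrame(pairs.pairs, columns=["tau_pi", "tau_or"]),
            OUT / "tau_pairs.csv")
summary = {
    "n_pairs": N_PAIRS, "seed": SEED,
    "mu_ln": dist.mu.tolist(), "sigma_ln": dist.sigma_mat.tolist(),
    "mean_diff_tau_pi_minus_tau_or": ttest["mean_diff"],
    "mean_diff_ci95": list(ttest["ci95"]), "t": ttest["t"], "p_t": ttest["p"],
    "pearson_r": corr["r"], "r_ci95": list(corr["ci95"]), "p_r": corr["p"],
}
with open(OUT / "tau_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)
    fh.write("\n")

print(f"simulated {N_PAIRS} (tau_PI, tau_OR) pairs (seed {SEED})")
print(f"mean difference tau_PI - tau_OR = {ttest['mean_diff']:.3f} "
      f"(95% CI {ttest['ci95'][0]:.3f} to {ttest['ci95'][1]:.3f}, p = {ttest['p']:.2e})")
print(f"Pearson r = {corr['r']:.3f} "
      f"(95% CI {corr['ci95'][0]:.3f} to {corr['ci95'][1]:.3f}, p = {corr['p']:.2e})")
print("wrote results/tau_pairs.csv, results/tau_summary.json")
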