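"""Synthetic trial-arm generation with the estimator's error structure.

Arms are generated on a grid of exposures specified directly in
log10-pmol/L (decoupling recovery experiments from any dose->exposure
table) with observed endpoint values

    y = operational_response(truth) + eps,   eps ~ N(0, sigma^2 / n)

matching the additive arm-level residual model of the pooled likelihood.
Observations are not truncated at zero: negative values are possible and
consistent with the additive-normal assumption.

:func:`generate_recovery_suite` produces the standard parameter-recovery
experiment: replicate datasets at the published Pearl-Index operational
parameters with 20 arms per drug on x in [1.8, 5.2], a span covering the
steep transition region of both drugs' response curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cocpd.model import (
    DEFAULT_DRUGS,
    DrugSpec,
    Endpoint,
    OperationalParams,
    TrialArm,
    operational_response,
)

__all__ = [
    "SynthDesign",
    "generate_arms",
    "generate_recovery_suite",
    "published_pi_params",
    "published_or_params",
    "dose_level_grid",
]


def published_pi_params() -> OperationalParams:
    """Published Pearl-Index operational-model parameter set (LNG/DRSP).

    Baseline 85 failures per 100 woman-years without contraception,
    full maximal suppression, a steep shared Hill factor, and per-drug
    transducer constants and residual scales.
    """
    return OperationalParams(
        endpoint=Endpoint.PI,
        baseline=85.0,
        imax=1.0,
        hill=9.653,
        tau={"LNG": 3.046, "DRSP": 2.602},
        log10_kd={"LNG": 3.556, "DRSP": 2.949},
        sigma={"LNG": 0.493, "DRSP": 0.572},
        fixed_flags={"baseline": True, "imax": True, "log10_kd": True},
    )


#: Published CV% of the transducer-constant estimates, per endpoint and
#: drug.  On the natural-log scale var(ln tau) ~ (CV/100)^2; used to
#: propagate estimation uncertainty into the tau-pair simulation.
PUBLISHED_TAU_CV_PERCENT = {
    "PI": {"LNG": 8.84, "DRSP": 9.59},
    "OR": {"LNG": 0.19, "DRSP": 0.26},
}


def published_or_params() -> OperationalParams:
    """Published ovulation-rate operational-model parameter set."""
    return OperationalParams(
        endpoint=Endpoint.OR,
        baseline=100.0,
        imax=1.0,
        hill=25.462,
        tau={"LNG": 2.172, "DRSP": 1.867},
        log10_kd={"LNG": 3.556, "DRSP": 2.949},
        sigma={"LNG": 6.572, "DRSP": 2.260},
        fixed_flags={"baseline": True, "imax": True, "log10_kd": True},
    )


#: Anchored average steady-state concentrations (ng/mL) at the marketed and
#: dose-ranging levels (no inducer, BMI < 25), matching the packaged
#: exposure fixture.
_DOSE_CAVG = {
    "PI": {"LNG": {90: 2.18, 100: 2.42, 150: 3.63},
           "DRSP": {3000: 32.79, 4000: 43.72}},
    "OR": {"LNG": {30: 0.54, 90: 2.18, 100: 2.42, 150: 3.63},
           "DRSP": {500: 5.47, 1000: 10.93, 2000: 21.86, 3000: 32.79, 4000: 43.72}},
}


def dose_level_grid(
    endpoint: Endpoint | str,
    specs: Mapping[str, DrugSpec] | None = None,
) -> dict[str, list[float]]:
    """Sparse exposure grid (log10 pmol/L) at the studied dose levels.

    An alternative to the wide even grid of the recovery suite: one grid
    point per dose level actually studied for the endpoint, so synthetic
    datasets mimic the sparse design of the real meta-analysis.
    """
    specs = DEFAULT_DRUGS if specs is None else specs
    table = _DOSE_CAVG[Endpoint(endpoint).value]
    return {
        drug: [float(np.log10(c * 1e6 / specs[drug].molecular_weight))
               for c in sorted(doses.values())]
        for drug, doses in table.items()
    }


@dataclass
class SynthDesign:
    """Design of a synthetic naive-pooled dataset.

    ``exposure_grid`` maps drug -> log10-pmol/L exposure values (one arm
    per grid point); all grid values must be > 0 so the log-domain model
    is defined.
    """

    true_params: OperationalParams
    exposure_grid: dict[str, Sequence[float]]
    n_per_arm: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        for drug, grid in self.exposure_grid.items():
            if drug not in self.true_params.tau:
                raise ValueError(f"drug {drug!r} not in true_params")
            g = np.asarray(grid, dtype=float)
            if np.any(g <= 0):
                raise ValueError(
                    f"exposure grid for {drug!r} must be > 0 (log10 pmol/L)"
                )


def generate_arms(
    design: SynthDesign,
    specs: Mapping[str, DrugSpec] | None = None,
) -> list[TrialArm]:
    """Simulate one arm per drug x grid point under the design's truth.

    The exposure x (log10 pmol/L) is converted back to ng/mL via the
    drug's molecular weight so arms carry concentrations in the unit the
    rest of the pipeline uses.  Reproducible given ``design.seed``.
    """
    specs = DEFAULT_DRUGS if specs is None else specs
    p = design.true_params
    rng = np.random.default_rng(design.seed)
    arms: list[TrialArm] = []
    for drug in sorted(design.exposure_grid):
        grid = np.asarray(design.exposure_grid[drug], dtype=float)
        cavg = 10.0**grid * specs[drug].molecular_weight / 1e6  # ng/mL
        mean = operational_response(cavg, drug, p, specs)
        sd = p.sigma[drug] / np.sqrt(design.n_per_arm)
        obs = mean + sd * rng.standard_normal(len(grid))
        for k, (c, y) in enumerate(zip(cavg, obs)):
            arms.append(TrialArm(
                study_id=f"synth-{drug}",
                arm_id=f"{drug}-{k:02d}",
                drug_id=drug,
                dose_ug=0.0,
                ee_dose_ug=0.0,
                endpoint=p.endpoint,
                observed=float(y),  # deliberately untruncated
                n_subjects=design.n_per_arm,
                cavg=float(c),
            ))
    return arms


def generate_recovery_suite(
    truth: OperationalParams | None = None,
    n_seeds: int = 20,
    n_per_arm: int = 5000,
    n_arms_per_drug: int = 20,
    grid_span: tuple[float, float] = (1.8, 5.2),
    base_seed: int = 1,
    specs: Mapping[str, DrugSpec] | None = None,
) -> tuple[list[list[TrialArm]], dict]:
    """Replicate datasets for a parameter-recovery experiment.

    Returns ``(datasets, manifest)``: one dataset per seed
    (``base_seed .. base_seed + n_seeds - 1``), each with
    ``n_arms_per_drug`` arms per drug on an even log10-pmol/L grid over
    ``grid_span``; the manifest records the generating truth, grid and
    seeds.
    """
    truth = published_pi_params() if truth is None else truth
    grid = np.linspace(grid_span[0], grid_span[1], n_arms_per_drug)
    seeds = [int(base_seed) + k for k in range(n_seeds)]
    datasets = []
    for s in seeds:
        design = SynthDesign(
            true_params=truth,
            exposure_grid={d: grid for d in truth.drugs},
            n_per_arm=n_per_arm,
            seed=s,
        )
        datasets.append(generate_arms(design, specs))
    manifest = {
        "truth": {
            "endpoint": truth.endpoint.value,
            "baseline": truth.baseline,
            "imax": truth.imax,
            "hill": truth.hill,
            "tau": dict(truth.tau),
            "log10_kd": dict(truth.log10_kd),
            "sigma": dict(truth.sigma),
        },
        "grid_log10_pmol_per_l": grid.tolist(),
        "n_per_arm": n_per_arm,
        "seeds": seeds,
    }
    return datasets, manifest
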