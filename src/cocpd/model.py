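"""Domain types, unit conversion and forward model evaluation.

Two dose-response models are implemented:

* a simple inhibitory Emax model on the ng/mL scale, the drug-specific
  baseline used historically for levonorgestrel Pearl-Index meta-analysis::

      E = BL * (1 - Imax * Cavg / (IC50 + Cavg))

* the Black-Leff operational model of agonism, which separates receptor
  affinity (dissociation constant KD, drug-specific) from intrinsic
  efficacy (transducer constant tau, drug-specific) under shared system
  parameters (baseline BL, maximal suppression Imax, Hill factor H)::

      E = BL * (1 - Imax * (tau*x)^H / ((kd + x)^H + (tau*x)^H))

  where, on the default ``log10`` concentration scale, x = log10(Cavg in
  pmol/L) and kd = log10(KD in pmol/L).  A ``linear`` scale variant using
  molar concentrations directly is also provided.

Endpoint units: the Pearl Index is expressed per 100 woman-years
(baseline 85, i.e. the pregnancy rate without contraception), the
ovulation rate as a percent (baseline 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "Endpoint",
    "ConcentrationUnit",
    "Concentration",
    "DrugSpec",
    "TrialArm",
    "EmaxParams",
    "OperationalParams",
    "to_molar",
    "from_molar",
    "emax_response",
    "operational_response",
]


class Endpoint(str, Enum):
    """Efficacy endpoint: Pearl Index or ovulation rate."""

    PI = "PI"
    OR = "OR"


class ConcentrationUnit(str, Enum):
    NG_PER_ML = "ng/mL"
    PMOL_PER_L = "pmol/L"
    LOG10_PMOL_PER_L = "log10_pmol/L"


@dataclass(frozen=True)
class Concentration:
    """A concentration with an explicit unit.

    ``ng/mL`` and ``pmol/L`` values must be positive; ``log10_pmol/L``
    may take any finite value.
    """

    value: float
    unit: ConcentrationUnit = ConcentrationUnit.NG_PER_ML

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"concentration value must be finite, got {self.value}")
        if self.unit in (ConcentrationUnit.NG_PER_ML, ConcentrationUnit.PMOL_PER_L):
            if self.value <= 0:
                raise ValueError(
                    f"concentration in {self.unit.value} must be > 0, got {self.value}"
                )


@dataclass(frozen=True)
class DrugSpec:
    """Progestin identity with the physical constants the model needs.

    Parameters
    ----------
    drug_id
        Short label, e.g. ``"LNG"`` (levonorgestrel) or ``"DRSP"``
        (drospirenone).  Any label is accepted; these two ship with
        default parameters.
    molecular_weight
        g/mol; used to convert ng/mL plasma concentrations to pmol/L.
    log10_kd
        log10 of the receptor dissociation constant expressed in pmol/L.
    """

    drug_id: str
    molecular_weight: float
    log10_kd: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(
                f"molecular_weight must be > 0, got {self.molecular_weight}"
            )
        if not np.isfinite(self.log10_kd):
            raise ValueError(f"log10_kd must be finite, got {self.log10_kd}")


#: Default physical constants.  Molecular weights from standard chemistry
#: references; log10 KD (pmol/L) from the published receptor-binding
#: literature for each progestin.
DEFAULT_DRUGS: dict[str, DrugSpec] = {
    "LNG": DrugSpec("LNG", molecular_weight=312.45, log10_kd=3.556),
    "DRSP": DrugSpec("DRSP", molecular_weight=366.49, log10_kd=2.949),
}


@dataclass
class TrialArm:
    """One study arm's endpoint observation.

    ``observed`` is the arm-level summary value (PI per 100 woman-years or
    OR in percent); ``n_subjects`` weights the arm in the pooled
    likelihood.  ``cavg`` (ng/mL) is the average steady-state progestin
    concentration, either given directly or resolved from an exposure
    table.
    """

    study_id: str
    arm_id: str
    drug_id: str
    dose_ug: float
    ee_dose_ug: float
    endpoint: Endpoint
    observed: float
    n_subjects: int
    cavg: float | None = None

    def __post_init__(self) -> None:
        self.endpoint = Endpoint(self.endpoint)
        if self.n_subjects < 1:
            raise ValueError(
                f"arm {self.study_id}/{self.arm_id}: n_subjects must be >= 1, "
                f"got {self.n_subjects}"
            )
        # observed may be negative for synthetic arms (untruncated additive
        # noise); file readers enforce observed >= 0 for real data
        if not np.isfinite(self.observed):
            raise ValueError(
                f"arm {self.study_id}/{self.arm_id}: observed must be finite"
            )
        if self.cavg is not None and self.cavg <= 0:
            raise ValueError(
                f"arm {self.study_id}/{self.arm_id}: cavg must be > 0, got {self.cavg}"
            )


@dataclass
class EmaxParams:
    """Parameters of the inhibitory Emax model (ng/mL scale)."""

    baseline: float
    imax: float
    ic50: float
    sigma: float

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"baseline must be > 0, got {self.baseline}")
        if not 0.0 <= self.imax <= 1.0:
            raise ValueError(f"imax must be in [0, 1], got {self.imax}")
        if self.ic50 <= 0:
            raise ValueError(f"ic50 must be > 0, got {self.ic50}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class OperationalParams:
    """Full operational-model parameter set for one endpoint.

    ``tau``, ``log10_kd`` and ``sigma`` are per-drug maps and must share
    the same drug set.  ``fixed_flags`` records which parameters were held
    fixed during estimation (informational).  ``concentration_scale``
    selects whether the Hill terms operate on x = log10(C in pmol/L)
    (default) or on the linear molar concentration.
    """

    endpoint: Endpoint
    baseline: float
    imax: float
    hill: float
    tau: dict[str, float]
    log10_kd: dict[str, float]
    sigma: dict[str, float]
    fixed_flags: dict[str, bool] = field(default_factory=dict)
    concentration_scale: str = "log10"

    def __post_init__(self) -> None:
        self.endpoint = Endpoint(self.endpoint)
        if self.baseline <= 0:
            raise ValueError(f"baseline must be > 0, got {self.baseline}")
        if not 0.0 <= self.imax <= 1.0:
            raise ValueError(f"imax must be in [0, 1], got {self.imax}")
        if self.hill <= 0:
            raise ValueError(f"hill must be > 0, got {self.hill}")
        if self.concentration_scale not in ("log10", "linear"):
            raise ValueError(
                f"concentration_scale must be 'log10' or 'linear', "
                f"got {self.concentration_scale!r}"
            )
        for drug, t in self.tau.items():
            if t <= 0:
                raise ValueError(f"tau[{drug}] must be > 0, got {t}")
            if drug not in self.log10_kd:
                raise ValueError(f"drug {drug!r} present in tau but missing from log10_kd")
            if drug not in self.sigma:
                raise ValueError(f"drug {drug!r} present in tau but missing from sigma")
        for drug, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma[{drug}] must be > 0, got {s}")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.tau)


def to_molar(c: Concentration, spec: DrugSpec) -> Concentration:
    """Convert ng/mL to pmol/L using the drug's molecular weight.

    pmol/L = ng/mL * 1e6 / MW[g/mol].
    """
    if c.unit is not ConcentrationUnit.NG_PER_ML:
        raise ValueError(f"to_molar expects ng/mL input, got {c.unit.value}")
    return Concentration(c.value * 1e6 / spec.molecular_weight, ConcentrationUnit.PMOL_PER_L)


def from_molar(c: Concentration, spec: DrugSpec) -> Concentration:
    """Exact inverse of :func:`to_molar`."""
    if c.unit is not ConcentrationUnit.PMOL_PER_L:
        raise ValueError(f"from_molar expects pmol/L input, got {c.unit.value}")
    return Concentration(c.value * spec.molecular_weight / 1e6, ConcentrationUnit.NG_PER_ML)


def ng_per_ml_to_pmol_per_l(cavg: float | np.ndarray, molecular_weight: float) -> float | np.ndarray:
    """Array-friendly ng/mL -> pmol/L conversion."""
    if molecular_weight <= 0:
        raise ValueError(f"molecular_weight must be > 0, got {molecular_weight}")
    return np.asarray(cavg, dtype=float) * 1e6 / molecular_weight


def emax_response(cavg: float | np.ndarray, p: EmaxParams) -> float | np.ndarray:
    """Inhibitory Emax response at average concentration ``cavg`` (ng/mL).

    Returns baseline * (1 - imax * cavg / (ic50 + cavg)); at cavg = 0 this
    is the baseline, at cavg = ic50 with imax = 1 exactly half of it.
    """
    c = np.asarray(cavg, dtype=float)
    if np.any(c < 0):
        raise ValueError("cavg must be >= 0")
    out = p.baseline * (1.0 - p.imax * c / (p.ic50 + c))
    return float(out) if np.isscalar(cavg) else out


def operational_response(
    cavg: float | np.ndarray,
    drug_id: str,
    p: OperationalParams,
    specs: Mapping[str, DrugSpec] | None = None,
) -> float | np.ndarray:
    """Operational-model response at average concentration ``cavg`` (ng/mL).

    On the default log10 scale the model is evaluated at
    x = log10(C[pmol/L]); the log-domain form is only defined for
    C > 1 pmol/L (x > 0).  At or below that boundary the drug occupies
    essentially no receptor and, by convention, the baseline response is
    returned with a warning rather than NaN.

    Parameters
    ----------
    cavg
        ng/mL, scalar or array.
    drug_id
        Key into ``p.tau`` / ``p.log10_kd``.
    p
        Parameter set; ``p.concentration_scale`` selects the log10 or
        linear molar form.
    specs
        Drug registry supplying molecular weights; defaults to the
        built-in LNG/DRSP registry.
    """
    specs = DEFAULT_DRUGS if specs is None else specs
    if drug_id not in p.tau:
        raise KeyError(f"drug {drug_id!r} has no tau in parameter set")
    if drug_id not in specs:
        raise KeyError(f"drug {drug_id!r} not in drug registry")
    tau = p.tau[drug_id]
    kd_log = p.log10_kd[drug_id]
    scalar_in = np.isscalar(cavg)
    c_molar = np.atleast_1d(ng_per_ml_to_pmol_per_l(cavg, specs[drug_id].molecular_weight))
    if np.any(c_molar <= 0):
        raise ValueError("cavg must be > 0")

    if p.concentration_scale == "log10":
        x = np.log10(c_molar)
        valid = x > 0
        if not np.all(valid):
            warnings.warn(
                "operational_response: concentration <= 1 pmol/L is outside the "
                "log-domain model; returning baseline (no suppression)",
                RuntimeWarning,
                stacklevel=2,
            )
        kd = kd_log
    else:
        x = c_molar
        valid = np.ones_like(x, dtype=bool)
        kd = 10.0 ** kd_log

    out = np.full_like(x, p.baseline, dtype=float)
    xv = x[valid]
    # work in logs to keep (tau*x)^H finite for steep Hill factors
    log_num = p.hill * np.log(tau * xv)
    log_kd_term = p.hill * np.log(kd + xv)
    m = np.maximum(log_num, log_kd_term)
    frac = np.exp(log_num - m) / (np.exp(log_kd_term - m) + np.exp(log_num - m))
    out[valid] = p.baseline * (1.0 - p.imax * frac)
    return float(out[0]) if scalar_in else out
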