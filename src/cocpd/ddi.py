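"""Exposure resolution and CYP3A4-induction / BMI scenario prediction.

Dose is translated to average steady-state concentration (Cavg, ng/mL)
through a lookup table stratified by drug, ethinyl-estradiol dose, BMI
group and co-administered CYP3A4 inducer.  The packaged default table
emulates external physiologically-based pharmacokinetic model output and
is anchored to published steady-state ranges (LNG 0.54-3.63 ng/mL over
30-150 ug, DRSP 5.47-43.72 ng/mL over 500-4000 ug); BMI and inducer
effects enter as multiplicative factors on Cavg.  Inter-individual
variability is log-normal: virtual subjects are drawn with median
``cavg_mean`` and a geometric CV.

Scenario predictions average the operational-model response over the
virtual population; each DDI scenario is compared with its no-induction
reference at the same drug, dose and BMI group via the incidence rate
ratio IRR = rate / reference_rate and the percent change
100*(IRR - 1).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cocpd.model import DEFAULT_DRUGS, DrugSpec, OperationalParams, operational_response

__all__ = [
    "BMI_GROUPS",
    "INDUCERS",
    "ExposureRecord",
    "Scenario",
    "ScenarioResult",
    "resolve_exposure",
    "simulate_virtual_population",
    "predict_scenario",
    "irr",
    "percent_change",
    "round_half_up",
    "ddi_summary_table",
]

BMI_GROUPS = ("lt25", "25to30", "ge30")
INDUCERS = ("none", "CBZ400", "RIF600", "custom")


@dataclass(frozen=True)
class ExposureRecord:
    """One dose -> Cavg mapping cell with inter-individual variability."""

    drug_id: str
    dose_ug: float
    ee_dose_ug: float
    bmi_group: str
    inducer: str
    cavg_ng_ml: float
    gcv_percent: float

    def __post_init__(self) -> None:
        if self.bmi_group not in BMI_GROUPS:
            raise ValueError(
                f"unknown bmi_group {self.bmi_group!r}; expected one of {BMI_GROUPS}"
            )
        if self.inducer not in INDUCERS:
            raise ValueError(
                f"unknown inducer {self.inducer!r}; expected one of {INDUCERS}"
            )
        if self.cavg_ng_ml <= 0:
            raise ValueError(f"cavg_ng_ml must be > 0, got {self.cavg_ng_ml}")
        if self.gcv_percent < 0:
            raise ValueError(f"gcv_percent must be >= 0, got {self.gcv_percent}")

    def stratum(self) -> tuple:
        return (self.drug_id, self.ee_dose_ug, self.bmi_group, self.inducer)


@dataclass(frozen=True)
class Scenario:
    """One DDI x BMI x dose prediction cell."""

    drug_id: str
    dose_ug: float
    ee_dose_ug: float
    bmi_group: str
    inducer: str
    n_virtual: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_virtual < 1:
            raise ValueError(f"n_virtual must be >= 1, got {self.n_virtual}")
        if self.bmi_group not in BMI_GROUPS:
            raise ValueError(f"unknown bmi_group {self.bmi_group!r}")
        if self.inducer not in INDUCERS:
            raise ValueError(f"unknown inducer {self.inducer!r}")

    def label(self) -> str:
        return (f"{self.drug_id}{self.dose_ug:g}/EE{self.ee_dose_ug:g}"
                f"/{self.bmi_group}/{self.inducer}")


@dataclass
class ScenarioResult:
    """Predicted endpoint for one scenario, relative to its reference."""

    scenario: Scenario
    mean_endpoint: float
    percent_change_vs_ref: float
    irr_vs_ref: float
    ci95: tuple[float, float]
    reference_mean: float = float("nan")
    extras: dict = field(default_factory=dict)


def resolve_exposure(
    table: Sequence[ExposureRecord],
    drug_id: str,
    dose_ug: float,
    ee_dose_ug: float,
    bmi_group: str,
    inducer: str,
) -> ExposureRecord:
    """Look up (or dose-interpolate) the exposure cell for a query.

    Exact matches are returned as-is.  Otherwise Cavg and the geometric
    CV are linearly interpolated in dose within the same
    drug/EE/BMI/inducer stratum; BMI and inducer strata are never
    interpolated across, and doses outside the stratum's dose range raise
    rather than extrapolate.
    """
    if not table:
        raise ValueError("exposure table is empty")
    stratum = [
        r for r in table
        if r.drug_id == drug_id and r.ee_dose_ug == ee_dose_ug
        and r.bmi_group == bmi_group and r.inducer == inducer
    ]
    if not stratum:
        raise LookupError(
            f"no exposure rows for stratum drug={drug_id} ee={ee_dose_ug} "
            f"bmi={bmi_group} inducer={inducer}"
        )
    for r in stratum:
        if r.dose_ug == dose_ug:
            return r
    doses = np.array(sorted(r.dose_ug for r in stratum))
    if dose_ug < doses[0] or dose_ug > doses[-1]:
        raise LookupError(
            f"dose {dose_ug} ug outside the stratum's dose range "
            f"[{doses[0]}, {doses[-1]}]; extrapolation is not allowed"
        )
    by_dose = {r.dose_ug: r for r in stratum}
    cavg = float(np.interp(dose_ug, doses, [by_dose[d].cavg_ng_ml for d in doses]))
    gcv = float(np.interp(dose_ug, doses, [by_dose[d].gcv_percent for d in doses]))
    return ExposureRecord(drug_id, dose_ug, ee_dose_ug, bmi_group, inducer, cavg, gcv)


def simulate_virtual_population(scenario: Scenario, record: ExposureRecord) -> np.ndarray:
    """Draw per-subject Cavg values (ng/mL) for a scenario.

    Log-normal with median ``record.cavg_ng_ml`` and geometric CV
    ``record.gcv_percent``; the log-scale SD is
    sqrt(ln(1 + (gcv/100)^2)).  Seeded by ``scenario.seed``.
    """
    if (scenario.drug_id, scenario.bmi_group, scenario.inducer) != (
        record.drug_id, record.bmi_group, record.inducer
    ):
        raise ValueError("exposure record does not match scenario strata")
    if record.gcv_percent < 0:
        raise ValueError("gcv_percent must be >= 0")
    sd_log = np.sqrt(np.log1p((record.gcv_percent / 100.0) ** 2))
    rng = np.random.default_rng(scenario.seed)
    z = rng.standard_normal(scenario.n_virtual)
    return record.cavg_ng_ml * np.exp(sd_log * z)


def irr(reference_rate: float, rate: float) -> float:
    """Incidence rate ratio: scenario rate divided by the reference rate."""
    if reference_rate <= 0:
        raise ValueError(f"reference rate must be > 0, got {reference_rate}")
    return rate / reference_rate


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (table convention), e.g. 0.15 -> 0.2."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def percent_change(reference: float, value: float) -> float:
    """Unrounded percent change 100*(value/reference - 1) vs the reference.

    Use :func:`round_half_up` (one decimal) when printing tables.
    """
    return 100.0 * (irr(reference, value) - 1.0)


def predict_scenario(
    scenario: Scenario,
    params: OperationalParams,
    reference: Scenario,
    table: Sequence[ExposureRecord],
    specs: Mapping[str, DrugSpec] | None = None,
) -> ScenarioResult:
    """Predict the scenario's mean endpoint and compare with its reference.

    The endpoint mean is the operational-model response averaged over the
    virtual population's Cavg draws; the 95% interval is the 2.5/97.5
    percentile of per-subject responses.  IRR and percent change are
    computed against the reference scenario's own population mean.
    """
    specs = DEFAULT_DRUGS if specs is None else specs

    def population_mean(s: Scenario) -> tuple[float, np.ndarray]:
        rec = resolve_exposure(table, s.drug_id, s.dose_ug, s.ee_dose_ug,
                               s.bmi_group, s.inducer)
        draws = simulate_virtual_population(s, rec)
        resp = operational_response(draws, s.drug_id, params, specs)
        return float(np.mean(resp)), np.asarray(resp)

    mean_val, resp = population_mean(scenario)
    if scenario == reference:
        ref_mean = mean_val
    else:
        ref_mean, _ = population_mean(reference)
    if ref_mean <= 0:
        raise ValueError("reference endpoint mean is not positive; IRR undefined")
    lo, hi = np.percentile(resp, [2.5, 97.5])
    ratio = irr(ref_mean, mean_val)
    return ScenarioResult(
        scenario=scenario,
        mean_endpoint=mean_val,
        percent_change_vs_ref=100.0 * (ratio - 1.0),
        irr_vs_ref=ratio,
        ci95=(float(lo), float(hi)),
        reference_mean=ref_mean,
    )


TABLE_COLUMNS = [
    "drug_id", "dose_ug", "ee_dose_ug", "bmi_group", "inducer", "n_virtual",
    "seed", "is_reference", "mean_endpoint", "ci95_lo", "ci95_hi",
    "irr_vs_ref", "percent_change_vs_ref", "percent_change_rounded",
]


def ddi_summary_table(
    scenarios: Sequence[tuple[Scenario, bool]],
    params: OperationalParams,
    table: Sequence[ExposureRecord],
    specs: Mapping[str, DrugSpec] | None = None,
) -> pd.DataFrame:
    """One row per scenario with mean endpoint, IRR and percent change.

    ``scenarios`` pairs each :class:`Scenario` with an ``is_reference``
    flag; every non-reference scenario is matched to the reference with
    the same drug, dose, EE dose and BMI group.  Column order is stable
    for byte-identical CSV output under fixed seeds.
    """
    refs: dict[tuple, Scenario] = {}
    for s, is_ref in scenarios:
        if is_ref:
            key = (s.drug_id, s.dose_ug, s.ee_dose_ug, s.bmi_group)
            if key in refs:
                raise ValueError(f"duplicate reference scenario for {key}")
            refs[key] = s
    rows = []
    for s, is_ref in scenarios:
        key = (s.drug_id, s.dose_ug, s.ee_dose_ug, s.bmi_group)
        ref = s if is_ref else refs.get(key)
        if ref is None:
            raise LookupError(
                f"scenario {s.label()} has no reference scenario for {key}"
            )
        res = predict_scenario(s, params, ref, table, specs)
        rows.append({
            "drug_id": s.drug_id,
            "dose_ug": s.dose_ug,
            "ee_dose_ug": s.ee_dose_ug,
            "bmi_group": s.bmi_group,
            "inducer": s.inducer,
            "n_virtual": s.n_virtual,
            "seed": s.seed,
            "is_reference": is_ref,
            "mean_endpoint": res.mean_endpoint,
            "ci95_lo": res.ci95[0],
            "ci95_hi": res.ci95[1],
            "irr_vs_ref": res.irr_vs_ref,
            "percent_change_vs_ref": res.percent_change_vs_ref,
            "percent_change_rounded": round_half_up(res.percent_change_vs_ref, 1),
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def forest_plot(df: pd.DataFrame, path) -> None:
    """Plain forest plot of IRR per scenario (plotting is a by-product)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df[~df["is_reference"]].reset_index(drop=True)
    labels = [
        f"{r.drug_id}{r.dose_ug:g}/EE{r.ee_dose_ug:g} {r.inducer} {r.bmi_group}"
        for r in sub.itertuples()
    ]
    fig, ax = plt.subplots(figsize=(6, 0.35 * max(len(sub), 4) + 1))
    y = np.arange(len(sub))
    ax.scatter(sub["irr_vs_ref"], y, color="tab:blue", zorder=3)
    ax.axvline(1.0, color="grey", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("incidence rate ratio vs no-induction reference")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
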