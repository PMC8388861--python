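"""Hepatocyte viability curves and IC50 → oral toxic-dose reversal.

Cell viability from a CCK-8 style plate assay is expressed relative to
vehicle controls, fitted to a four-parameter log-logistic (4PL) inhibition
curve, and the ENR IC50 is treated as the liver toxicity threshold: the
lowest repeated-oral dose whose predicted liver ENR peak concentration
reaches the IC50 is found by bisection on the PBPK model (and cross-checked
against the dose-linearity shortcut threshold / Cmax(1 mg/kg)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .parameters import ModelParameters, ParameterError
from . import pbpk

__all__ = [
    "ViabilityPlate",
    "InhibitionCurve",
    "ToxicDoseResult",
    "SafeDoseBound",
    "relative_viability",
    "fit_inhibition_curve",
    "reverse_toxic_dose",
    "safe_dose_statement",
]


def relative_viability(a: float, b: float, c: float) -> float:
    """Relative cell viability (%) from absorbances.

    ``a`` — mean absorbance of the drug-treated group, ``b`` — of the
    vehicle control group, ``c`` — of the blank.  Returns 100·(A−C)/(B−C).
    """
    if b <= c:
        raise ParameterError(
            f"control absorbance ({b}) must exceed blank ({c}); assay failure"
        )
    return 100.0 * (a - c) / (b - c)


@dataclass
class ViabilityPlate:
    """Plate records: compound, conc_ug_per_ml, absorbance, batch, role.

    ``role`` is one of treated / control / blank; controls are
    vehicle-matched per batch and blanks carry medium + reagent only.
    """

    records: pd.DataFrame

    REQUIRED = ("compound", "conc_ug_per_ml", "absorbance", "batch", "role")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.records.columns)
        if missing:
            raise ParameterError(f"plate records missing columns: {sorted(missing)}")
        treated = self.records[self.records["role"] == "treated"]
        if (treated["conc_ug_per_ml"] <= 0).any():
            raise ParameterError("treated concentrations must be > 0")

    def viabilities(self, compound: str) -> pd.DataFrame:
        """Per (concentration, batch) relative viability for *compound*.

        Within each batch, the treated absorbance at each concentration is
        referenced to that batch's control and blank means.
        """
        df = self.records
        rows = []
        for batch, grp in df.groupby("batch"):
            b = grp.loc[grp["role"] == "control", "absorbance"].mean()
            c = grp.loc[grp["role"] == "blank", "absorbance"].mean()
            treated = grp[(grp["role"] == "treated") & (grp["compound"] == compound)]
            for conc, sub in treated.groupby("conc_ug_per_ml"):
                rows.append(
                    {
                        "conc_ug_per_ml": float(conc),
                        "batch": batch,
                        "viability_percent": relative_viability(
                            sub["absorbance"].mean(), b, c
                        ),
                    }
                )
        if not rows:
            raise ParameterError(f"no treated wells for compound {compound!r}")
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ViabilityPlate":
        return cls(pd.read_csv(path))


def four_pl(log10_c, top, bottom, log10_ic50, hill):
    """4-parameter log-logistic viability (%) at log10 concentration.

    Decreasing in concentration for hill < 0; viability at the IC50 is
    (top+bottom)/2 by construction.
    """
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ic50 - log10_c) * hill))


@dataclass
class InhibitionCurve:
    """Fitted 4PL inhibition curve with the IC50 on the linear scale."""

    top: float
    bottom: float
    log10_ic50: float
    hill: float
    residual_sd: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.bottom > self.top:
            raise ParameterError("bottom must not exceed top")

    @property
    def ic50(self) -> float:
        return 10.0**self.log10_ic50

    def viability(self, conc_ug_per_ml) -> np.ndarray | float:
        return four_pl(
            np.log10(conc_ug_per_ml), self.top, self.bottom, self.log10_ic50, self.hill
        )


def fit_inhibition_curve(
    plate: ViabilityPlate,
    compound: str,
    weight_replicates: bool = False,
    allow_extrapolation: bool = False,
) -> InhibitionCurve:
    """Fit the 4PL model to a compound's viability data.

    By default the mean viability across batches at each concentration is
    fitted; ``weight_replicates=True`` fits every replicate instead.  An
    IC50 outside the tested concentration range is refused unless
    ``allow_extrapolation`` is set.
    """
    vdf = plate.viabilities(compound)
    if weight_replicates:
        x = np.log10(vdf["conc_ug_per_ml"].to_numpy())
        y = vdf["viability_percent"].to_numpy()
    else:
        mean = vdf.groupby("conc_ug_per_ml")["viability_percent"].mean()
        x = np.log10(mean.index.to_numpy())
        y = mean.to_numpy()
    if len(np.unique(x)) < 4:
        raise ParameterError("need >= 4 distinct concentrations for a 4PL fit")

    p0 = (100.0, 5.0, float(np.median(x)), -1.0)
    bounds = ([80.0, 0.0, x.min() - 2.0, -10.0], [110.0, 30.0, x.max() + 2.0, -0.05])
    try:
        popt, _ = curve_fit(four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise ParameterError(f"4PL fit did not converge: {exc}") from exc
    top, bottom, log10_ic50, hill = (float(v) for v in popt)
    if not allow_extrapolation and not (x.min() <= log10_ic50 <= x.max()):
        raise ParameterError(
            f"fitted IC50 (10^{log10_ic50:.3f} µg/mL) lies outside the tested "
            "range; extrapolated potency is refused by default"
        )
    resid = y - four_pl(x, *popt)
    dof = max(len(y) - 4, 1)
    return InhibitionCurve(
        top, bottom, log10_ic50, hill,
        residual_sd=float(np.sqrt(resid @ resid / dof)), converged=True,
    )


@dataclass
class ToxicDoseResult:
    """Lowest oral dose whose liver ENR Cmax reaches the toxicity threshold."""

    dose_mg_per_kg: float
    threshold_ug_per_ml: float
    liver_cmax_ug_per_ml: float
    tmax_h: float
    cip_at_tmax_ug_per_ml: float
    granularity_mg_per_kg: float
    regimen: dict = field(default_factory=dict)


def _liver_profile(params: ModelParameters, dose: float):
    p = params.copy()
    p.dosing.dose_mg_per_kg = dose
    result = pbpk.simulate(p)
    c_max, t_max = pbpk.cmax(result, "liver", "ENR")
    cip = float(
        np.interp(t_max, result.time_h, result.concentration("CIP", "liver"))
    )
    return c_max, t_max, cip


def reverse_toxic_dose(
    params: ModelParameters,
    threshold_ug_per_ml: float,
    dose_bounds: tuple[float, float] = (1.0, 500.0),
    granularity_mg_per_kg: float = 1.0,
) -> ToxicDoseResult:
    """Smallest dose (to *granularity*) whose liver ENR Cmax ≥ threshold.

    Found by bisection on the dose under the parameter set's regimen
    (interval and number of doses fixed; dose varied).  The model is linear
    in dose, so threshold / Cmax(1 mg/kg) gives the same answer up to
    granularity; both routes are computed and a discrepancy beyond one
    granularity step raises.
    """
    if threshold_ug_per_ml <= 0:
        raise ParameterError("threshold must be > 0")
    lo, hi = dose_bounds
    if not 0 < lo < hi:
        raise ParameterError("dose bounds must satisfy 0 < lo < hi")
    g = granularity_mg_per_kg

    cmax_lo, _, _ = _liver_profile(params, lo)
    if cmax_lo >= threshold_ug_per_ml:
        hi = lo
    else:
        cmax_hi, _, _ = _liver_profile(params, hi)
        if cmax_hi < threshold_ug_per_ml:
            raise ParameterError(
                f"threshold {threshold_ug_per_ml} µg/mL unreachable below "
                f"{hi} mg/kg (Cmax there: {cmax_hi:.3g} µg/mL)"
            )
        # bisect on the granularity grid: lo infeasible, hi feasible
        lo_k, hi_k = math.floor(lo / g), math.ceil(hi / g)
        while hi_k - lo_k > 1:
            mid_k = (lo_k + hi_k) // 2
            c_mid, _, _ = _liver_profile(params, mid_k * g)
            if c_mid >= threshold_ug_per_ml:
                hi_k = mid_k
            else:
                lo_k = mid_k
        hi = hi_k * g

    # linearity cross-check
    unit_cmax, _, _ = _liver_profile(params, 1.0)
    linear_dose = g * math.ceil(threshold_ug_per_ml / unit_cmax / g - 1e-9)
    if abs(linear_dose - hi) > g + 1e-9:
        raise ParameterError(
            f"bisection ({hi} mg/kg) and dose-linearity ({linear_dose} mg/kg) "
            "disagree by more than one granularity step"
        )
    c_max, t_max, cip = _liver_profile(params, hi)
    return ToxicDoseResult(
        dose_mg_per_kg=float(hi),
        threshold_ug_per_ml=threshold_ug_per_ml,
        liver_cmax_ug_per_ml=c_max,
        tmax_h=t_max,
        cip_at_tmax_ug_per_ml=cip,
        granularity_mg_per_kg=g,
        regimen={
            "interval_h": params.dosing.interval_h,
            "n_doses": params.dosing.n_doses,
        },
    )


@dataclass
class SafeDoseBound:
    """Inclusive upper bound of the orally safe dose range."""

    max_safe_dose_mg_per_kg: float
    regimen: dict
    statement: str


def safe_dose_statement(
    toxic: ToxicDoseResult, granularity_mg_per_kg: float | None = None
) -> SafeDoseBound:
    """Safe-range bound from a reversed toxic dose.

    The bound equals the reversed dose, floored conservatively to the
    requested granularity; it never exceeds the dose whose Cmax first meets
    the threshold.
    """
    g = granularity_mg_per_kg or toxic.granularity_mg_per_kg
    bound = g * math.floor(toxic.dose_mg_per_kg / g + 1e-9)
    regimen = dict(toxic.regimen)
    stmt = (
        f"safe ≤ {bound:g} mg/kg b.w. orally, "
        f"every {regimen.get('interval_h', '?')} h × {regimen.get('n_doses', '?')} doses"
    )
    return SafeDoseBound(float(bound), regimen, stmt)
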