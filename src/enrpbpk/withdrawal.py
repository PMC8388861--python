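"""Withdrawal-time estimation against tissue maximum residue limits.

Two estimators are provided:

* :func:`wt_mc` — the population rule: the first whole day after the last
  administration on which the ENR+CIP marker is below the tissue MRL in at
  least 99% of a simulated population.
* :func:`wt_tolerance_regression` — the regulatory comparator: ordinary
  least squares of ln(concentration) on time, with a one-sided upper
  tolerance limit covering the 99th percentile of the residue distribution
  with 95% confidence; the WT is the first whole day at which that bound is
  at or below the MRL.

Marker concentrations and MRLs are in µg/kg (1 µg/mL of model output equals
1000 µg/kg at tissue density 1 g/mL).  Withdrawal times are whole days,
rounded up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .parameters import EDIBLE_TISSUES, ParameterError
from .population import PopulationResult
from .residues import ResidueDataset

__all__ = [
    "MRLSet",
    "WTResult",
    "HorizonError",
    "tolerance_factor",
    "wt_mc",
    "wt_tolerance_regression",
    "final_wt",
]

DEFAULT_MRLS_UG_PER_KG = {"muscle": 100.0, "fat": 100.0, "liver": 200.0, "kidney": 300.0}


class HorizonError(RuntimeError):
    """The required coverage/crossing was not reached within the grid."""


@dataclass
class MRLSet:
    """Maximum residue limits (µg/kg) per edible tissue."""

    limits: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MRLS_UG_PER_KG)
    )

    def __post_init__(self) -> None:
        for tissue, mrl in self.limits.items():
            if mrl <= 0:
                raise ParameterError(f"MRL for {tissue} must be > 0, got {mrl}")

    def __getitem__(self, tissue: str) -> float:
        try:
            return self.limits[tissue]
        except KeyError:
            raise ParameterError(f"no MRL for tissue {tissue!r}") from None


@dataclass
class WTResult:
    """A withdrawal time for one tissue with estimation diagnostics."""

    tissue: str
    wt_days: int
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wt_days < 0 or self.wt_days != int(self.wt_days):
            raise ParameterError("wt_days must be a non-negative integer")


def wt_mc(
    pop: PopulationResult,
    mrls: MRLSet | None = None,
    coverage: float = 0.99,
    tissues: tuple[str, ...] | None = None,
    require_confidence: float | None = None,
) -> dict[str, WTResult]:
    """Population withdrawal time per tissue from Monte Carlo depletion curves.

    The WT is the smallest whole day (post last administration) at which the
    fraction of individuals whose marker concentration is below the MRL
    reaches *coverage*.  With ``require_confidence`` set (e.g. 0.95), the
    stricter rule is used instead: the day at which the distribution-free
    upper confidence bound on the *coverage* quantile (an order statistic
    chosen from the binomial distribution) is below the MRL.
    """
    if not 0 < coverage < 1:
        raise ParameterError("coverage must be in (0, 1)")
    mrls = mrls or MRLSet()
    tissues = tissues or tuple(t for t in EDIBLE_TISSUES if t in pop.marker_ug_per_kg)
    out: dict[str, WTResult] = {}
    for tissue in tissues:
        traces = pop.marker_ug_per_kg[tissue]
        ok = np.isfinite(traces).all(axis=1)
        traces = traces[ok]
        n = len(traces)
        mrl = mrls[tissue]
        frac_below = (traces < mrl).mean(axis=0)
        if require_confidence is None:
            compliant = frac_below >= coverage
        else:
            # k-th order statistic as an upper tolerance bound for the
            # coverage quantile at the stated confidence
            k = int(stats.binom.ppf(require_confidence, n, coverage)) + 1
            k = min(k, n)
            upper = np.sort(traces, axis=0)[k - 1]
            compliant = upper < mrl
        days_ok = np.flatnonzero(compliant)
        diag = {
            "coverage_by_day": dict(zip(pop.days.tolist(), frac_below.tolist())),
            "n": n,
            "mrl_ug_per_kg": mrl,
        }
        if days_ok.size == 0:
            raise HorizonError(
                f"{tissue}: {coverage:.0%} coverage not reached by day "
                f"{pop.days.max():g}; extend the day grid"
            )
        out[tissue] = WTResult(
            tissue, int(pop.days[days_ok[0]]), "mc_population", diag
        )
    return out


def tolerance_factor(
    p: float, confidence: float, df: int, leverage: float
) -> float:
    """One-sided normal tolerance factor k from the noncentral t distribution.

    The upper tolerance bound at a design point with *leverage* h is
    ŷ + k·s with k = t'_{confidence, df, δ}·√h, δ = z_p/√h.  For a plain
    random sample, df = n−1 and h = 1/n recover the published k-factor
    tables.
    """
    if not 0 < p < 1 or not 0 < confidence < 1:
        raise ParameterError("p and confidence must be in (0, 1)")
    if df < 1 or leverage <= 0:
        raise ParameterError("df must be >= 1 and leverage > 0")
    delta = stats.norm.ppf(p) / math.sqrt(leverage)
    return float(stats.nct.ppf(confidence, df, delta) * math.sqrt(leverage))


def wt_tolerance_regression(
    data: ResidueDataset,
    mrl: float,
    percentile: float = 0.99,
    confidence: float = 0.95,
    loq_policy: str = "exclude",
    horizon_days: float = 60.0,
) -> WTResult:
    """Withdrawal time by log-linear regression with an upper tolerance limit.

    Fits OLS of ln(concentration, µg/kg) on time (days post last dose),
    pooling animals, on a single-tissue marker dataset.  The one-sided upper
    tolerance bound for the *percentile* quantile at *confidence* is placed
    along the regression line using the noncentral-t factor with n−2 degrees
    of freedom and the leverage of each prediction time.  The WT is the
    first whole day from which the bound stays at or below ln(MRL).

    ``loq_policy`` — "exclude" drops records flagged below the LOQ (the
    regulatory default); "half_loq" substitutes LOQ/2.
    """
    if mrl <= 0:
        raise ParameterError("MRL must be > 0")
    df_rec = data.records
    tissues = df_rec["tissue"].unique()
    if len(tissues) != 1:
        raise ParameterError(
            f"regression needs a single tissue, got {sorted(tissues)}"
        )
    tissue = str(tissues[0])
    if loq_policy == "exclude":
        df_rec = df_rec[~df_rec["below_loq"]]
        conc = df_rec["conc_ug_per_kg"].to_numpy(dtype=float)
    elif loq_policy == "half_loq":
        conc = df_rec["conc_ug_per_kg"].to_numpy(dtype=float).copy()
        conc[df_rec["below_loq"].to_numpy()] = data.loq_ug_per_kg / 2.0
    else:
        raise ParameterError(f"unknown loq_policy {loq_policy!r}")
    t = df_rec["time_days"].to_numpy(dtype=float)
    if len(t) < 3 or len(np.unique(t)) < 3:
        raise ParameterError("need quantifiable data at >= 3 time points")
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive for the log transform")

    y = np.log(conc)
    n = len(y)
    tbar = t.mean()
    sxx = float(((t - tbar) ** 2).sum())
    if sxx == 0:
        raise ParameterError("no spread in sampling times")
    slope = float(((t - tbar) @ (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * tbar)
    if slope >= 0:
        raise ParameterError(
            f"non-depleting data (slope {slope:.3g} >= 0); no withdrawal time"
        )
    resid = y - (intercept + slope * t)
    dof = n - 2
    s = math.sqrt(float(resid @ resid) / dof) if dof > 0 else 0.0

    def bound(tq: np.ndarray) -> np.ndarray:
        h = 1.0 / n + (tq - tbar) ** 2 / sxx
        if s == 0:
            return intercept + slope * tq
        k = np.array([tolerance_factor(percentile, confidence, dof, hi) for hi in h])
        return intercept + slope * tq + k * s

    grid = np.arange(0.0, horizon_days + 1e-9, 0.05)
    below = bound(grid) <= math.log(mrl)
    # first grid time from which the bound stays below the MRL
    ok_from = np.flatnonzero(below & (np.flip(np.logical_and.accumulate(np.flip(below)))))
    if ok_from.size == 0:
        raise HorizonError(
            f"tolerance bound never settles below MRL within {horizon_days} d"
        )
    t_cross = grid[ok_from[0]]
    wt_days = int(math.ceil(t_cross - 1e-9))
    return WTResult(
        tissue,
        wt_days,
        "tolerance_regression",
        {
            "slope_per_day": slope,
            "intercept_ln_ug_per_kg": intercept,
            "residual_sd": s,
            "n": n,
            "crossing_day": float(t_cross),
            "mrl_ug_per_kg": mrl,
            "loq_policy": loq_policy,
        },
    )


def final_wt(results: list[WTResult] | dict[str, WTResult]) -> WTResult:
    """The product-level WT: the longest tissue WT (ties keep input order)."""
    if isinstance(results, dict):
        results = list(results.values())
    if not results:
        raise ParameterError("need at least one tissue WT")
    best = max(results, key=lambda r: r.wt_days)
    return WTResult(
        best.tissue, best.wt_days, best.method,
        {"per_tissue": {r.tissue: r.wt_days for r in results}},
    )
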