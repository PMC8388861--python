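"""Local parameter sensitivity of end-of-simulation tissue residues.

The normalized sensitivity coefficient (NSC) of a model output r with
respect to a parameter p is the elasticity (Δr/r)·(p/Δp), estimated here by
a forward finite difference at a +1% perturbation.  The output of interest
is the ENR+CIP marker concentration in an edible tissue at the end of the
simulation (default 228 h) — the quantity that drives the withdrawal time.

Because every flow, volume and clearance is re-derived from body weight at
simulation time, perturbing BW exercises all its scaling paths at once,
which is what makes |NSC(BW)| exceed 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .parameters import EDIBLE_TISSUES, ModelParameters, ParameterError
from . import pbpk

__all__ = ["NSCResult", "elasticity", "nsc", "classify", "sensitive_set"]

HIGH_THRESHOLD = 0.5
MEDIUM_THRESHOLD = 0.2


@dataclass
class NSCResult:
    parameter: str
    tissue: str
    nsc: float
    klass: str

    def __post_init__(self) -> None:
        if self.klass != classify(self.nsc):
            raise ParameterError("klass inconsistent with |nsc| thresholds")


def classify(value: float) -> str:
    """Sensitivity class from |NSC|: high ≥ 0.5 > medium ≥ 0.2 > insensitive."""
    if not math.isfinite(value):
        raise ParameterError(f"NSC must be finite, got {value}")
    a = abs(value)
    if a >= HIGH_THRESHOLD:
        return "high"
    if a >= MEDIUM_THRESHOLD:
        return "medium"
    return "insensitive"


def elasticity(f: Callable[[float], float], p: float, delta_frac: float = 0.01) -> float:
    """Forward-difference elasticity (Δr/r)·(p/Δp) of f at parameter value p.

    The generic finite-difference core behind :func:`nsc`; usable with any
    scalar response, e.g. closed-form reductions in verification.
    """
    if p == 0:
        raise ParameterError("cannot perturb a parameter whose value is 0")
    r = f(p)
    if r == 0:
        raise ParameterError("model output is 0 at the baseline; NSC undefined")
    r_pert = f(p * (1.0 + delta_frac))
    return (r_pert - r) / r / delta_frac


def _marker_at(params: ModelParameters, tissue: str, time_h: float) -> float:
    grid = np.unique(np.concatenate([np.arange(0.0, time_h, 4.0), [time_h]]))
    result = pbpk.simulate(params, output_grid=grid)
    return float(pbpk.total_marker(result, tissue)[-1])


def nsc(
    params: ModelParameters,
    parameter: str,
    tissue: str,
    time_h: float | None = None,
    delta_frac: float = 0.01,
    central: bool = False,
) -> NSCResult:
    """NSC of the tissue ENR+CIP marker at *time_h* w.r.t. *parameter*.

    Forward one-sided difference at +1% by default; ``central=True`` uses a
    symmetric ±delta_frac difference instead.
    """
    if time_h is None:
        time_h = params.dosing.t_end_h
    if time_h > params.dosing.t_end_h:
        raise ParameterError("target time beyond the simulation span")

    def response(value: float) -> float:
        trial = params.copy()
        trial.set(parameter, value)
        return _marker_at(trial, tissue, time_h)

    p = params.get(parameter)
    if central:
        if p == 0:
            raise ParameterError("cannot perturb a parameter whose value is 0")
        r = response(p)
        if r == 0:
            raise ParameterError("model output is 0 at the baseline; NSC undefined")
        val = (response(p * (1 + delta_frac)) - response(p * (1 - delta_frac))) / r / (
            2 * delta_frac
        )
    else:
        val = elasticity(response, p, delta_frac)
    return NSCResult(parameter, tissue, val, classify(val))


def sensitive_set(
    params: ModelParameters,
    targets: tuple[str, ...] = EDIBLE_TISSUES,
    parameters: tuple[str, ...] | None = None,
    time_h: float | None = None,
    threshold: float = MEDIUM_THRESHOLD,
    delta_frac: float = 0.01,
) -> dict[str, float]:
    """Parameters with |NSC| ≥ *threshold* on any target tissue.

    Returns {parameter: max |NSC| over targets}, sorted descending.
    Baseline simulations are shared across parameters per tissue.
    """
    if not targets:
        raise ParameterError("targets must be non-empty")
    if parameters is None:
        parameters = tuple(
            n for n in params.parameter_names if n not in ("QCC",)
        )
    out: dict[str, float] = {}
    if time_h is None:
        time_h = params.dosing.t_end_h

    baselines = {t: _marker_at(params, t, time_h) for t in targets}
    p_values = {name: params.get(name) for name in parameters}
    for name in parameters:
        p = p_values[name]
        if p == 0:
            continue  # nothing to perturb; a zero-valued rate has no NSC
        trial = params.copy()
        trial.set(name, p * (1 + delta_frac))
        best = 0.0
        for tissue in targets:
            r = baselines[tissue]
            if r == 0:
                raise ParameterError(f"marker is 0 in {tissue}; NSC undefined")
            r_pert = _marker_at(trial, tissue, time_h)
            val = (r_pert - r) / r / delta_frac
            best = max(best, abs(val))
        if best >= threshold:
            out[name] = best
    return dict(sorted(out.items(), key=lambda kv: -kv[1]))
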