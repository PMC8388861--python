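"""Synthetic residue studies and viability plates.

The generators emulate the statistical structure of a pig residue-depletion
slaughter study (3 animals per time point at 0.042, 0.5, 1, 2, 3, 5 days
post treatment; four edible tissues; ENR and CIP with a 0.02 µg/mL LOQ) and
of a CCK-8 viability plate (10–1000 µg/mL, 3 batches), so that every
pipeline stage is testable without animal data.  All generators are pure
functions of (inputs, seed).

Inter-animal variability is a single multiplicative log-normal deviation
per animal (mean-preserving; σ² = ln(1 + CV²)), applied to the model
prediction at the animal's slaughter time across its tissues — residue
concentrations are positive and right-skewed, matching the log-linear
depletion model the tolerance regression assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ANALYTES, EDIBLE_TISSUES, ModelParameters, ParameterError, default_parameters
from .residues import COLUMNS, ResidueDataset
from .toxicity import InhibitionCurve, ViabilityPlate
from .withdrawal import MRLSet
from . import pbpk

__all__ = [
    "ResidueStudyDesign",
    "generate_residue_study",
    "generate_viability_plate",
    "FixtureBundle",
    "end_to_end_fixture",
]

DEFAULT_TIMES_DAYS = (0.042, 0.5, 1.0, 2.0, 3.0, 5.0)
DEFAULT_PLATE_CONCENTRATIONS = (10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)


@dataclass
class ResidueStudyDesign:
    """Design of a synthetic slaughter study."""

    times_days: tuple[float, ...] = DEFAULT_TIMES_DAYS
    n_per_time: int = 3
    tissues: tuple[str, ...] = EDIBLE_TISSUES
    analytes: tuple[str, ...] = ANALYTES
    loq_ug_per_ml: float = 0.02
    inter_animal_cv: float = 0.25
    n_controls: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times_days, dtype=float)
        if times.ndim != 1 or len(times) == 0 or np.any(np.diff(times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if self.n_per_time < 1:
            raise ParameterError("n_per_time must be >= 1")
        if self.loq_ug_per_ml <= 0:
            raise ParameterError("LOQ must be > 0")
        if self.inter_animal_cv < 0:
            raise ParameterError("inter_animal_cv must be >= 0")


def generate_residue_study(
    params: ModelParameters, design: ResidueStudyDesign
) -> ResidueDataset:
    """Simulate the model and dress its depletion curves as a slaughter study.

    Each treated animal carries one log-normal deviation (CV =
    ``inter_animal_cv``) multiplying the model-predicted concentration at
    its slaughter time in every tissue/analyte; records below the LOQ are
    flagged.  Control animals contribute all-below-LOQ records.
    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    last = params.dosing.last_dose_time
    times_h = last + np.asarray(design.times_days) * 24.0
    run = params.copy()
    run.dosing.t_end_h = max(run.dosing.t_end_h, float(times_h.max()) + 1.0)
    grid = np.unique(np.concatenate([[0.0], times_h]))
    result = pbpk.simulate(run, output_grid=grid)
    idx = np.searchsorted(grid, times_h)

    cv = design.inter_animal_cv
    sigma = float(np.sqrt(np.log1p(cv**2)))
    loq_ugkg = design.loq_ug_per_ml * 1000.0

    rows = []
    animal = 0
    for j, t_day in enumerate(design.times_days):
        for _ in range(design.n_per_time):
            animal += 1
            aid = f"P{animal:02d}"
            # mean-preserving log-normal animal effect
            factor = float(np.exp(rng.normal(-(sigma**2) / 2.0, sigma))) if cv > 0 else 1.0
            for tissue in design.tissues:
                for analyte in design.analytes:
                    pred = float(result.concentration(analyte, tissue)[idx[j]])
                    conc = pred * 1000.0 * factor
                    rows.append(
                        (aid, tissue, t_day, analyte, conc, conc < loq_ugkg)
                    )
    for k in range(design.n_controls):
        aid = f"C{k + 1:02d}"
        t_day = design.times_days[0] if k % 2 == 0 else design.times_days[-1]
        for tissue in design.tissues:
            for analyte in design.analytes:
                rows.append((aid, tissue, t_day, analyte, 0.0, True))

    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return ResidueDataset(df, loq_ug_per_kg=loq_ugkg)


def generate_viability_plate(
    truth: InhibitionCurve,
    compound: str = "ENR",
    concentrations: tuple[float, ...] = DEFAULT_PLATE_CONCENTRATIONS,
    noise_sd_percent: float = 3.7,
    n_batches: int = 3,
    seed: int | None = None,
    control_absorbance: float = 0.9,
    blank_absorbance: float = 0.1,
) -> ViabilityPlate:
    """Construct plate absorbances whose relative viability follows *truth*.

    Treated-well absorbance is back-calculated so that
    ``relative_viability(A, B, C)`` returns the truth-curve viability plus
    additive Gaussian noise of SD *noise_sd_percent* (in percentage
    points).  Control and blank wells are included per batch.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    b, c = control_absorbance, blank_absorbance
    rows = []
    for batch in range(1, n_batches + 1):
        rows.append((compound, np.nan, b, batch, "control"))
        rows.append((compound, np.nan, c, batch, "blank"))
        v_true = truth.viability(conc)
        noise = rng.normal(0.0, noise_sd_percent, size=len(conc)) if noise_sd_percent > 0 else 0.0
        v_obs = np.asarray(v_true + noise)
        a = c + (b - c) * v_obs / 100.0
        for ci, ai in zip(conc, a):
            rows.append((compound, float(ci), float(ai), batch, "treated"))
    df = pd.DataFrame(
        rows, columns=["compound", "conc_ug_per_ml", "absorbance", "batch", "role"]
    )
    return ViabilityPlate(df)


@dataclass
class FixtureBundle:
    """A self-contained end-to-end test bundle with generating ground truth."""

    params: ModelParameters
    residue_study: ResidueDataset
    plate_enr: ViabilityPlate
    plate_cip: ViabilityPlate
    mrls: MRLSet
    truth: dict = field(default_factory=dict)


def end_to_end_fixture(
    seed: int,
    inter_animal_cv: float = 0.25,
    plate_noise_sd_percent: float = 3.7,
) -> FixtureBundle:
    """Bundle the default model with one synthetic study + viability plates.

    Ground truth attached for regression testing: the MRL-crossing day of
    each tissue's generating marker curve, the unit-dose liver ENR Cmax
    (for the dose-linearity oracle), and the generating IC50s.
    """
    params = default_parameters()
    rng = np.random.default_rng(seed)
    study = generate_residue_study(
        params,
        ResidueStudyDesign(
            inter_animal_cv=inter_animal_cv, seed=int(rng.integers(2**31 - 1))
        ),
    )
    truth_enr = InhibitionCurve(top=100.0, bottom=0.0, log10_ic50=2.354, hill=-1.0)
    truth_cip = InhibitionCurve(top=100.0, bottom=0.0, log10_ic50=2.854, hill=-1.0)
    plate_enr = generate_viability_plate(
        truth_enr, "ENR", noise_sd_percent=plate_noise_sd_percent,
        seed=int(rng.integers(2**31 - 1)),
    )
    plate_cip = generate_viability_plate(
        truth_cip, "CIP", noise_sd_percent=plate_noise_sd_percent,
        seed=int(rng.integers(2**31 - 1)),
    )
    mrls = MRLSet()

    # generating-model ground truth
    last = params.dosing.last_dose_time
    horizon_days = 12.0
    run = params.copy()
    run.dosing.t_end_h = last + horizon_days * 24.0
    grid = np.arange(0.0, run.dosing.t_end_h + 1e-9, 0.5)
    result = pbpk.simulate(run, output_grid=grid)
    crossing = {}
    for tissue in EDIBLE_TISSUES:
        marker = pbpk.total_marker(result, tissue) * 1000.0
        post = grid >= last
        t_post = (grid[post] - last) / 24.0
        m_post = marker[post]
        below = m_post < mrls[tissue]
        idx = np.flatnonzero(below & np.logical_and.accumulate(below[::-1])[::-1])
        crossing[tissue] = float(t_post[idx[0]]) if idx.size else float("nan")
    unit = params.copy()
    unit.dosing.dose_mg_per_kg = 1.0
    unit_cmax, _ = pbpk.cmax(pbpk.simulate(unit), "liver", "ENR")
    truth = {
        "mrl_crossing_days": crossing,
        "unit_dose_liver_cmax_ug_per_ml": float(unit_cmax),
        "ic50_enr_ug_per_ml": truth_enr.ic50,
        "ic50_cip_ug_per_ml": truth_cip.ic50,
    }
    return FixtureBundle(params, study, plate_enr, plate_cip, mrls, truth)
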