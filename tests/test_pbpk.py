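import numpy as np
import pandas as pd
import pytest

import enrpbpk as ep
from enrpbpk import pbpk
from enrpbpk.parameters import ParameterError
from enrpbpk.residues import COLUMNS, ResidueDataset


def _max_rel_err(a: ep.SimulationResult, b: ep.SimulationResult) -> float:
    errs = []
    for key, trace in a.conc.items():
        other = b.conc[key]
        scale = max(float(np.max(np.abs(other))), 1e-12)
        errs.append(float(np.max(np.abs(trace - other))) / scale)
    return max(errs)


def test_zero_dose_gives_identically_zero_concentrations(params):
    p = params.copy()
    p.dosing.dose_mg_per_kg = 0.0
    r = ep.simulate(p)
    for trace in r.conc.values():
        assert np.all(trace == 0.0)


def test_mass_balance_within_0p1_percent(depletion_result):
    err = depletion_result.mass_balance_error()
    assert float(err["ENR"].max()) < 1e-3
    assert float(err["CIP"].max()) < 1e-3


def test_all_states_non_negative(depletion_result):
    for trace in depletion_result.conc.values():
        assert np.all(trace >= 0.0)
    for trace in depletion_result.amounts.values():
        assert np.all(trace >= 0.0)


@pytest.mark.parametrize("lam", [0.5, 2.0, 26.0])
def test_dose_linearity(params, label_result, lam):
    p = params.copy()
    p.dosing.dose_mg_per_kg = params.dosing.dose_mg_per_kg * lam
    scaled = ep.simulate(p)
    for key, trace in label_result.conc.items():
        ref = lam * trace
        scale = max(float(np.max(ref)), 1e-12)
        assert float(np.max(np.abs(scaled.conc[key] - ref))) / scale < 1e-5


def test_adaptive_solver_matches_rk4_oracle(params):
    p = params.copy()
    p.dosing.n_doses = 1
    p.dosing.t_end_h = 12.0
    grid = np.arange(0.0, 12.0 + 1e-9, 0.5)
    adaptive = ep.simulate(p, output_grid=grid)
    fixed = ep.integrate_rk4(p, step_h=0.002, output_grid=grid)
    assert _max_rel_err(adaptive, fixed) < 1e-3


def test_superposition_of_time_shifted_single_doses(params):
    p = params.copy()
    p.dosing.n_doses = 3
    p.dosing.t_end_h = 60.0
    grid = np.arange(0.0, 60.0 + 1e-9, 1.0)
    multi = ep.simulate(p, output_grid=grid)

    single = params.copy()
    single.dosing.n_doses = 1
    single.dosing.t_end_h = 60.0
    one = ep.simulate(single, output_grid=grid)
    for tissue in ("liver", "muscle"):
        trace = one.concentration("ENR", tissue)
        summed = np.zeros_like(trace)
        for k in range(3):
            shift = int(k * 12)  # grid step is 1 h
            summed[shift:] += trace[: len(trace) - shift]
        ref = multi.concentration("ENR", tissue)
        assert np.max(np.abs(summed - ref)) / ref.max() < 1e-4


def test_output_grid_validation(params):
    with pytest.raises(ParameterError):
        ep.simulate(params, output_grid=[0.0, 500.0])
    with pytest.raises(ParameterError):
        ep.simulate(params, output_grid=[5.0, 5.0, 6.0])


def test_dose_event_not_interpolated(params, label_result):
    # the stomach amount jumps by dose*BW at each administration
    t = label_result.time_h
    stomach = label_result.amounts[("ENR", "stomach")]
    i = int(np.searchsorted(t, 12.0))
    assert t[i] == 12.0
    jump = stomach[i] - stomach[i - 1]
    assert jump > 0.8 * params.dosing.dose_mg_per_kg * params.physiology.BW


# ----------------------------- total_marker -----------------------------


def test_total_marker_additivity(label_result):
    for tissue in ep.EDIBLE_TISSUES:
        total = ep.total_marker(label_result, tissue)
        enr = label_result.concentration("ENR", tissue)
        cip = label_result.concentration("CIP", tissue)
        assert np.allclose(total, enr + cip)
        assert np.all(total >= enr) and np.all(total >= cip)
    with pytest.raises(ParameterError):
        ep.total_marker(label_result, "spleen")


def test_total_marker_reduces_to_enr_without_metabolism(params):
    p = params.copy()
    p.chemical.Frac = 0.0
    r = ep.simulate(p)
    for tissue in ep.EDIBLE_TISSUES:
        assert np.allclose(ep.total_marker(r, tissue), r.concentration("ENR", tissue))


# --------------------------------- cmax ---------------------------------


def _fake_result(time_h, trace, params):
    return ep.SimulationResult(
        time_h=np.asarray(time_h, dtype=float),
        conc={("ENR", "liver"): np.asarray(trace, dtype=float)},
        amounts={},
        dose_total_mg=0.0,
        params=params,
    )


def test_cmax_monotone_decreasing_trace(params):
    t = np.linspace(0, 10, 50)
    r = _fake_result(t, np.exp(-t), params)
    c, tm = ep.cmax(r, "liver", "ENR")
    assert tm == t[0] and c == 1.0


def test_cmax_bateman_closed_form(params):
    ka, ke = 0.8, 0.1
    t = np.arange(0.0, 48.0, 0.05)
    bateman = ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    r = _fake_result(t, bateman, params)
    _, tmax = ep.cmax(r, "liver", "ENR")
    expected = np.log(ka / ke) / (ka - ke)
    assert abs(tmax - expected) <= 0.05  # within one grid step


def test_cmax_empty_trace_error(params):
    r = _fake_result([], [], params)
    with pytest.raises(ParameterError):
        ep.cmax(r, "liver", "ENR")


def test_cmax_on_simulation_peaks_near_last_dose(label_result, params):
    c, tm = ep.cmax(label_result, "liver", "ENR")
    assert c > 0
    assert params.dosing.last_dose_time <= tm <= params.dosing.last_dose_time + 24


# ---------------------------- goodness of fit ----------------------------


def _study_grid(params, study):
    last = params.dosing.last_dose_time
    t_obs = last + study.records["time_days"].unique() * 24.0
    p = params.copy()
    p.dosing.t_end_h = max(p.dosing.t_end_h, float(t_obs.max()) + 1.0)
    grid = np.unique(np.concatenate([np.arange(0.0, p.dosing.t_end_h, 1.0), t_obs]))
    return ep.simulate(p, output_grid=grid)


def test_gof_perfect_on_noise_free_data(params, noise_free_study):
    result = _study_grid(params, noise_free_study)
    gof = ep.goodness_of_fit(noise_free_study.subset(analyte="ENR"), result)
    assert (gof["r2"] > 0.999).all()
    assert gof["passed"].all()


def test_gof_exactly_linear_pairs(params):
    # observed 1,2,3 µg/kg against predictions on the line pred = 2·obs
    t = np.array([108.0, 132.0, 156.0])
    r = _fake_result(t, np.array([2.0, 4.0, 6.0]) / 1000.0, params)
    records = pd.DataFrame(
        [("A", "liver", d, "ENR", c, False) for d, c in zip((0.0, 1.0, 2.0), (1.0, 2.0, 3.0))],
        columns=list(COLUMNS),
    )
    gof = ep.goodness_of_fit(ResidueDataset(records), r)
    assert gof["r2"].iloc[0] == pytest.approx(1.0)


def test_gof_validation_errors(params):
    t = np.array([108.0, 132.0, 156.0])
    r = _fake_result(t, np.array([1.0, 2.0, 3.0]) / 1000.0, params)
    two = pd.DataFrame(
        [("A", "liver", 0.0, "ENR", 1.0, False), ("A", "liver", 1.0, "ENR", 2.0, False)],
        columns=list(COLUMNS),
    )
    with pytest.raises(ParameterError):
        ep.goodness_of_fit(ResidueDataset(two), r)
    flat = pd.DataFrame(
        [("A", "liver", d, "ENR", 5.0, False) for d in (0.0, 1.0, 2.0)],
        columns=list(COLUMNS),
    )
    with pytest.raises(ParameterError):
        ep.goodness_of_fit(ResidueDataset(flat), r)


# ------------------------------- calibrate -------------------------------


def test_calibrate_noop_without_adjustables(params, noise_free_study):
    res = ep.calibrate(params, noise_free_study, adjustable=[])
    assert res.params.to_dict() == params.to_dict()
    assert res.initial_objective == res.final_objective


def test_calibrate_fixed_point_at_truth(params, noise_free_study):
    res = ep.calibrate(params, noise_free_study, adjustable=["Ka"])
    assert res.final_objective < 1e-6
    assert res.params.get("Ka") == pytest.approx(params.get("Ka"), rel=1e-3)


def test_calibrate_recovers_perturbed_ka(params, noise_free_study):
    start = params.copy()
    start.set("Ka", params.get("Ka") * 2.0)
    res = ep.calibrate(start, noise_free_study, adjustable=["Ka"])
    assert res.final_objective < res.initial_objective
    assert res.params.get("Ka") == pytest.approx(params.get("Ka"), rel=0.05)
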