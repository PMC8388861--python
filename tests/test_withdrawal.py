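import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import enrpbpk as ep
from enrpbpk.parameters import ParameterError
from enrpbpk.population import PopulationResult
from enrpbpk.residues import COLUMNS, ResidueDataset
from enrpbpk.withdrawal import HorizonError, tolerance_factor


def _pop(traces_by_tissue: dict, days=None) -> PopulationResult:
    any_tr = next(iter(traces_by_tissue.values()))
    days = np.arange(any_tr.shape[1]) if days is None else np.asarray(days)
    return PopulationResult(
        samples=pd.DataFrame(index=range(any_tr.shape[0])),
        days=days,
        marker_ug_per_kg={k: np.asarray(v, dtype=float) for k, v in traces_by_tissue.items()},
    )


def _exp_pop(n, c0, k_per_day, days, rng=None, cv=0.0):
    """n exponential depletion curves c0·exp(−k·d) with log-normal spread."""
    days = np.asarray(days, dtype=float)
    base = c0 * np.exp(-k_per_day * days)
    if cv == 0 or rng is None:
        return np.tile(base, (n, 1))
    f = rng.lognormal(0, cv, size=n)
    return f[:, None] * base[None, :]


# --------------------------------- wt_mc ---------------------------------


def test_wt_mc_all_zero_population():
    zeros = np.zeros((50, 8))
    wt = ep.wt_mc(_pop({t: zeros for t in ep.EDIBLE_TISSUES}))
    assert all(r.wt_days == 0 for r in wt.values())


def test_wt_mc_single_curve_crossing_oracle():
    # deterministic curve crossing 200 µg/kg at 80.5 h (≈3.35 d) post last
    # dose → first compliant whole day is 4
    days = np.arange(0, 10)
    k = math.log(10) / 1.919  # arbitrary depletion rate
    t_cross_d = 80.5 / 24.0
    c0 = 200.0 * math.exp(k * t_cross_d)
    traces = _exp_pop(1, c0, k, days)
    wt = ep.wt_mc(_pop({"liver": traces}), ep.MRLSet())
    brute = int(min(d for d in days if c0 * math.exp(-k * d) < 200.0))
    assert wt["liver"].wt_days == brute == 4


def test_wt_mc_coverage_ordering():
    rng = np.random.default_rng(5)
    days = np.arange(0, 12)
    traces = _exp_pop(400, 3000.0, 0.9, days, rng, cv=0.5)
    pop = _pop({"muscle": traces})
    hi = ep.wt_mc(pop, coverage=0.99)["muscle"].wt_days
    lo = ep.wt_mc(pop, coverage=0.5)["muscle"].wt_days
    assert hi >= lo


def test_wt_mc_monotone_in_mrl():
    rng = np.random.default_rng(11)
    days = np.arange(0, 12)
    pop = _pop({"muscle": _exp_pop(200, 3000.0, 0.9, days, rng, cv=0.4)})
    wt_low = ep.wt_mc(pop, ep.MRLSet({"muscle": 50.0}))["muscle"].wt_days
    wt_high = ep.wt_mc(pop, ep.MRLSet({"muscle": 500.0}))["muscle"].wt_days
    assert wt_high <= wt_low


def test_wt_mc_confidence_variant_is_conservative():
    rng = np.random.default_rng(3)
    days = np.arange(0, 14)
    pop = _pop({"kidney": _exp_pop(300, 5000.0, 0.8, days, rng, cv=0.5)})
    plain = ep.wt_mc(pop)["kidney"].wt_days
    conf = ep.wt_mc(pop, require_confidence=0.95)["kidney"].wt_days
    assert conf >= plain


def test_wt_mc_horizon_error():
    days = np.arange(0, 4)
    pop = _pop({"liver": _exp_pop(10, 1e6, 0.1, days)})
    with pytest.raises(HorizonError):
        ep.wt_mc(pop)


def test_wt_mc_unit_error_sentinel():
    # a 1000× µg/mL-vs-µg/kg mistake shifts the WT by days
    days = np.arange(0, 14)
    traces = _exp_pop(50, 4000.0, 0.9, days)
    right = ep.wt_mc(_pop({"liver": traces}))["liver"].wt_days
    wrong = ep.wt_mc(_pop({"liver": traces / 1000.0}))["liver"].wt_days
    assert right - wrong >= 2


def test_mrlset_defaults_and_validation():
    m = ep.MRLSet()
    assert (m["muscle"], m["fat"], m["liver"], m["kidney"]) == (100, 100, 200, 300)
    with pytest.raises(ParameterError):
        ep.MRLSet({"muscle": 0.0})
    with pytest.raises(ParameterError):
        m["brain"]


# ------------------------- tolerance regression -------------------------


def _line_dataset(c0_ugkg, k_per_day, times, n_per_time=3, noise=None, tissue="kidney"):
    rows = []
    i = 0
    for t in times:
        for j in range(n_per_time):
            i += 1
            ln_c = math.log(c0_ugkg) - k_per_day * t
            if noise is not None:
                ln_c += noise[(i - 1) % len(noise)]
            rows.append((f"P{i:02d}", tissue, t, "ENR+CIP", math.exp(ln_c), False))
    return ResidueDataset(pd.DataFrame(rows, columns=list(COLUMNS)))


def test_tolerance_factor_matches_published_tables():
    # one-sided normal K factors, p = 0.99, 95% confidence (df = n−1, h = 1/n)
    published = {10: 3.981, 20: 3.295, 30: 3.064}
    for n, k_ref in published.items():
        k = tolerance_factor(0.99, 0.95, df=n - 1, leverage=1.0 / n)
        assert k == pytest.approx(k_ref, abs=0.005)


def test_zero_variance_regression_band_collapses_to_line():
    # ln C = ln(2000) − 0.05·t (t in hours) → crossing of MRL 200 at
    # ln(10)/0.05 ≈ 46.05 h ≈ 1.92 d → WT = 2 d
    k_day = 0.05 * 24.0
    data = _line_dataset(2000.0, k_day, times=[0.5, 1.0, 2.0, 3.0])
    wt = ep.wt_tolerance_regression(data, mrl=200.0)
    assert wt.wt_days == 2
    assert wt.diagnostics["residual_sd"] == pytest.approx(0.0, abs=1e-9)
    assert wt.diagnostics["crossing_day"] == pytest.approx(46.05 / 24.0, abs=0.06)


def test_tolerance_band_lies_above_line_crossing():
    noise = [0.2, -0.2, 0.1, -0.1, 0.15, -0.15]
    data = _line_dataset(5000.0, 1.0, times=[0.5, 1, 2, 3, 5], noise=noise)
    wt = ep.wt_tolerance_regression(data, mrl=300.0)
    naive_cross = math.ceil(
        (wt.diagnostics["intercept_ln_ug_per_kg"] - math.log(300.0))
        / -wt.diagnostics["slope_per_day"]
    )
    assert wt.wt_days >= naive_cross


def test_doubling_noise_never_decreases_wt():
    base = [0.25, -0.25, 0.12, -0.12, 0.2, -0.2]
    d1 = _line_dataset(5000.0, 1.0, times=[0.5, 1, 2, 3, 5], noise=base)
    d2 = _line_dataset(5000.0, 1.0, times=[0.5, 1, 2, 3, 5], noise=[2 * e for e in base])
    wt1 = ep.wt_tolerance_regression(d1, mrl=300.0)
    wt2 = ep.wt_tolerance_regression(d2, mrl=300.0)
    assert wt2.wt_days >= wt1.wt_days


def test_regression_rejects_non_depleting_data():
    data = _line_dataset(100.0, -0.5, times=[0.5, 1, 2, 3])  # rising
    with pytest.raises(ParameterError):
        ep.wt_tolerance_regression(data, mrl=200.0)


def test_regression_loq_policies():
    rows = [
        ("P1", "kidney", 0.5, "ENR+CIP", 3000.0, False),
        ("P2", "kidney", 1.0, "ENR+CIP", 1500.0, False),
        ("P3", "kidney", 2.0, "ENR+CIP", 400.0, False),
        ("P4", "kidney", 3.0, "ENR+CIP", 100.0, False),
        ("P5", "kidney", 5.0, "ENR+CIP", 0.0, True),
    ]
    data = ResidueDataset(pd.DataFrame(rows, columns=list(COLUMNS)))
    wt_ex = ep.wt_tolerance_regression(data, mrl=300.0, loq_policy="exclude")
    assert wt_ex.diagnostics["n"] == 4
    wt_half = ep.wt_tolerance_regression(data, mrl=300.0, loq_policy="half_loq")
    assert wt_half.diagnostics["n"] == 5
    with pytest.raises(ParameterError):
        ep.wt_tolerance_regression(data, mrl=300.0, loq_policy="drop_study")


def test_regression_all_below_loq_degenerate():
    rows = [("P%d" % i, "fat", t, "ENR+CIP", 0.0, True) for i, t in enumerate((1, 2, 3))]
    data = ResidueDataset(pd.DataFrame(rows, columns=list(COLUMNS)))
    with pytest.raises(ParameterError):
        ep.wt_tolerance_regression(data, mrl=100.0)


# ------------------------------- final_wt -------------------------------


def test_final_wt_is_longest_tissue():
    results = [
        ep.WTResult("muscle", 5, "mc_population"),
        ep.WTResult("fat", 3, "mc_population"),
        ep.WTResult("liver", 6, "mc_population"),
        ep.WTResult("kidney", 4, "mc_population"),
    ]
    final = ep.final_wt(results)
    assert final.wt_days == 6 and final.tissue == "liver"
    assert final.diagnostics["per_tissue"] == {"muscle": 5, "fat": 3, "liver": 6, "kidney": 4}


def test_final_wt_single_and_empty():
    one = ep.WTResult("fat", 3, "tolerance_regression")
    assert ep.final_wt([one]).wt_days == 3
    with pytest.raises(ParameterError):
        ep.final_wt([])


@settings(derandomize=True, max_examples=30)
@given(st.permutations([("muscle", 5), ("fat", 3), ("liver", 6), ("kidney", 4)]))
def test_final_wt_order_invariant(order):
    results = [ep.WTResult(t, d, "mc_population") for t, d in order]
    assert ep.final_wt(results).wt_days == 6
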