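import numpy as np
import pytest

import enrpbpk as ep


@pytest.fixture(scope="session")
def params():
    return ep.default_parameters()


@pytest.fixture(scope="session")
def label_result(params):
    """One simulation of the label regimen, shared across tests."""
    return ep.simulate(params)


@pytest.fixture(scope="session")
def depletion_result(params):
    """Label regimen extended 14 days past the last dose, hourly grid."""
    p = params.copy()
    p.dosing.t_end_h = p.dosing.last_dose_time + 14 * 24.0
    grid = np.arange(0.0, p.dosing.t_end_h + 1e-9, 1.0)
    return ep.simulate(p, output_grid=grid)


@pytest.fixture(scope="session")
def noise_free_study(params):
    """Synthetic residue study with zero inter-animal variability."""
    design = ep.ResidueStudyDesign(inter_animal_cv=0.0, n_controls=0, seed=0)
    return ep.generate_residue_study(params, design)


@pytest.fixture(scope="session")
def small_population(params):
    """A 40-pig Monte Carlo population over the sensitive parameter set."""
    sensitive = ["BW", "Frac", "KmC", "KurineC", "Kurine1C",
                 "Pl", "Pl1", "Pk", "Pk1", "Pm", "Pm1", "Pf", "Pf1"]
    dists = ep.build_distributions(params, sensitive)
    samples = ep.sample_population(dists, n=40, seed=2024)
    return ep.simulate_population(params, samples, days=np.arange(0, 15))
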