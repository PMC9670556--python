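"""Shared fixtures: small synthetic fields, a study-condition generator spec
(emission values matching the fitted four-state model reported for Hudson Bay
bears) and a modest simulated dataset with one pooled fit."""

import numpy as np
import pytest

import icebear as ib
from icebear.hmm import EmissionParams, HMMSpec, TransitionModel, fit_hmm
from icebear.preprocess import Bout, annotate_covariates, compute_steps

#: baseline transition log-odds (slots D->ARS, D->O, ARS->D, ARS->O,
#: O->D, O->ARS, O->O'): persistent states with plausible exchange rates
BASE_TRANS = np.array([-1.5, -3.0, -1.2, -2.2, -2.5, -1.7, -2.5])


@pytest.fixture(scope="session")
def grid():
    return ib.GridSpec(nt=600, dt=2.0, x0=-2500.0, dx=100.0, nx=51,
                       y0=-2500.0, dy=100.0, ny=51)


@pytest.fixture(scope="session")
def wind_field(grid):
    return ib.simulate_wind_field(mean_speed=25.0, variability=8.0,
                                  correlation_scales=(12.0, 300.0),
                                  grid=grid, seed=11)


@pytest.fixture(scope="session")
def tide_field(grid):
    return ib.simulate_tide_field(speed=0.29, period=12.0, grid=grid)


def make_truth_spec():
    """Generator spec with the study-condition emission values: step means
    0.63 (drift, at the 0.29 km/h median tide), 0.76, 2.04 km/h; sds
    0.31/0.59/0.93; concentrations 3.64/0.62/4.28; olfactory bias 92 deg
    relative to wind (alpha1=-0.011, alpha2=0.303)."""
    em = EmissionParams(
        mu_step=np.array([0.5, 0.76, 2.04]),   # 0.5 + 0.45*0.29 = 0.6305
        sigma_step=np.array([0.31, 0.59, 0.93]),
        kappa=np.array([3.64, 0.62, 4.28]),
        beta_tide=0.45, alpha1_drift=2.4,
        alpha1_olf=-0.011, alpha2_olf=0.303)
    tm = TransitionModel()
    tm.coef[:, 0] = BASE_TRANS
    return HMMSpec(em, tm)


@pytest.fixture(scope="session")
def truth_spec():
    return make_truth_spec()


def simulate_annotated(spec, wind, tide, n_tracks, T, seed0=100,
                       scalar_fields=None, attributes_by_track=None, **kw):
    """Simulate tracks and return (annotated step series, truths)."""
    series, truths = [], []
    for i in range(n_tracks):
        attrs = (attributes_by_track or {}).get(i, kw.pop("attributes", None)
                                                if "attributes" in kw else None)
        track, truth = ib.simulate_track(spec, wind, tide, T=T,
                                         seed=seed0 + i,
                                         animal_id=f"bear{i:02d}",
                                         scalar_fields=scalar_fields,
                                         attributes=attrs, **kw)
        steps = compute_steps(Bout(track.animal_id, track.data,
                                   dict(track.attributes)))
        steps = annotate_covariates(steps, wind=wind, tide=tide, clamp=True,
                                    scalar_fields=scalar_fields,
                                    attributes=track.attributes)
        series.append(steps)
        truths.append(truth)
    return series, truths


@pytest.fixture(scope="session")
def sim_dataset(truth_spec, wind_field, tide_field):
    return simulate_annotated(truth_spec, wind_field, tide_field,
                              n_tracks=4, T=400)


@pytest.fixture(scope="session")
def base_fit(sim_dataset):
    series, _ = sim_dataset
    return fit_hmm(series, n_restarts=2, seed=0, compute_hessian=True)
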