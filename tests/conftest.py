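"""Shared fixtures: small synthetic landscapes and ground-truth parameters."""

import numpy as np
import pytest

from movescape.hmm import HmmParams, StepSeries, stationary_probs, transition_matrix
from movescape.landscape import LandscapeConfig, generate_landscape
from movescape.pipeline import (
    default_design_spec,
    default_true_hmm,
    default_true_ssf,
)


@pytest.fixture(scope="session")
def small_landscape():
    """A 70 x 110 cell valley (8.4 x 13.2 km) with two towns and trails."""
    cfg = LandscapeConfig(
        n_rows=70, n_cols=110,
        valley_halfwidth_m=1500.0, ridge_ramp_m=1200.0,
        town_size_m=(1200.0, 2000.0),
        n_spur_trails=8,
    )
    return generate_landscape(cfg, seed=5)


@pytest.fixture(scope="session")
def truth_hmm() -> HmmParams:
    return default_true_hmm()


@pytest.fixture(scope="session")
def truth_ssf() -> dict:
    return default_true_ssf()


@pytest.fixture(scope="session")
def design_spec():
    return default_design_spec()


def simulate_hmm_series(
    params: HmmParams, T: int, seed: int, animal_id: str = "a",
    return_states: bool = False,
):
    """Direct emission-level simulation of one step series (no landscape):
    covariates are a 2-h diurnal clock plus random town-distance and
    trail-density values."""
    r = np.random.default_rng(seed)
    hours = (r.integers(12) * 2 + np.arange(T) * 2) % 24
    cols = {"c_hour": np.cos(2 * np.pi * hours / 24)}
    k = len(params.covariate_names)
    for name in params.covariate_names:
        if name == "c_hour":
            continue
        if name == "trail_density":
            cols[name] = r.gamma(1.5, 0.8, T)
        else:
            cols[name] = r.uniform(0, 1, T)
    X = np.column_stack([cols[n] for n in params.covariate_names])
    Gam = transition_matrix(params.beta, X)
    s = np.zeros(T, dtype=int)
    pi0 = stationary_probs(params.beta, X[0])
    s[0] = r.random() < pi0[1]
    for t in range(1, T):
        s[t] = r.random() < Gam[t, s[t - 1], 1]
    a = (params.mu / params.sigma) ** 2
    th = params.sigma**2 / params.mu
    lengths = np.maximum(r.gamma(a[s], th[s]), 1.0)
    angles = r.vonmises(params.angle_mean[s], np.maximum(params.kappa[s], 1e-9))
    angles[0] = np.nan
    series = StepSeries(
        animal_id=animal_id, lengths=lengths, angles=angles, X=X,
        covariate_names=params.covariate_names, hour=hours.astype(float),
        segment_id=np.zeros(T, dtype=int),
        x0=np.zeros(T), y0=np.zeros(T), x1=np.zeros(T), y1=np.zeros(T),
        bearing=np.zeros(T),
    )
    return (series, s) if return_states else series
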