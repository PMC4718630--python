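"""Shared fixtures: small simulated surveys and fitted models reused
across test modules (session-scoped to keep MCMC cost down)."""

import warnings

import numpy as np
import pytest

import wpimon as w


@pytest.fixture(scope="session")
def default_bundle():
    """One 60-point, 5-year survey of a declining species (psi1=0.6,
    phi=0.8, gamma=0.1, p=0.3) — Case-1 detection level."""
    cfg = w.CommunityConfig(rng_seed=3)
    return cfg, w.simulate_bundle(cfg)


@pytest.fixture(scope="session")
def default_history(default_bundle):
    _, b = default_bundle
    return w.prepare_populations(b["events"], b["deployments"],
                                 b["traits"])["species_01"]


@pytest.fixture(scope="session")
def case2_fit(default_history):
    return w.DynamicOccupancyModel(case=2, seed=1).fit(default_history)


@pytest.fixture(scope="session")
def case1_fit(default_bundle, default_history):
    _, b = default_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return w.DynamicOccupancyModel(case=1, seed=2).fit(
            default_history, b["covariates"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_history(values, years=None):
    """DetectionHistory from a raw (J, T, K) array."""
    values = np.asarray(values, dtype=float)
    J, T, _ = values.shape
    years = years or list(range(2010, 2010 + T))
    return w.DetectionHistory(values, [f"pt{j:02d}" for j in range(J)], years)


def make_draws(psi, years=None, case=2, population="pop", site="S"):
    psi = np.asarray(psi, dtype=float)
    years = years or list(range(2010, 2010 + psi.shape[1]))
    return w.PosteriorDraws(psi=psi, years=years, case=case,
                            population=population, site=site)
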