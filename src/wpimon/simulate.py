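"""Synthetic camera-trap surveys with known ground truth.

Generates data with exactly the statistical structure the downstream
analysis assumes: point-level occupancy evolving between years through
survival/colonization dynamics (optionally driven by logit-linear
covariate effects), within-year closure, and imperfect daily detection at
occupied points only. Deployments are staggered so the annual site window
spans the full season (~15 periods of 7-8 days) while each point is active
for a contiguous block of days.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CommunityConfig, SpeciesParams
from .containers import CovariateSet, TruthRecord

SEASON_START_MONTH, SEASON_START_DAY = 1, 15


def _rng(config: CommunityConfig, stream: int) -> np.random.Generator:
    # independent reproducible stream per generation stage
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(config.rng_seed), spawn_key=(stream,)))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def season_start(config: CommunityConfig, year: int) -> datetime:
    return datetime(year, SEASON_START_MONTH, SEASON_START_DAY)


def deployment_start_days(config: CommunityConfig) -> np.ndarray:
    """Day offset (within the season window) at which each point starts.

    Points start in consecutive blocks so that the union of deployments
    covers the whole season window.
    """
    J = config.n_points
    span = config.season_days - config.deploy_days
    if J == 1:
        return np.zeros(1, dtype=int)
    return np.round(np.arange(J) * span / (J - 1)).astype(int)


def deployment_mask(config: CommunityConfig) -> np.ndarray:
    """(n_points, season_days) boolean: point active on that day."""
    starts = deployment_start_days(config)
    days = np.arange(config.season_days)
    return (days >= starts[:, None]) & (days < (starts + config.deploy_days)[:, None])


def simulate_covariates(config: CommunityConfig) -> CovariateSet:
    """Draw point-level, year-level and point-by-year covariates."""
    rng = _rng(config, 0)
    J, T = config.n_points, config.n_years
    point_ids = [f"{config.site}-{j + 1:03d}" for j in range(J)]
    years = [config.first_year + t for t in range(T)]
    elev = rng.normal(config.elev_mean, config.elev_sd, J)
    edge = np.abs(rng.normal(config.edge_mean, config.edge_sd, J))
    rain = rng.normal(config.rain_mean, config.rain_sd, T)
    max_temp = rng.normal(config.max_temp_mean, config.max_temp_sd, T)
    min_temp = rng.normal(config.min_temp_mean, config.min_temp_sd, T)
    peop = (rng.random((J, T)) < config.peop_prob).astype(float)
    return CovariateSet(point_ids, years, elev, edge, rain, max_temp,
                        min_temp, peop)


def _species_rates(sp: SpeciesParams, cov: CovariateSet):
    """Per-point psi1 and per-(point, year) phi/gamma with covariate
    effects applied on the logit scale to standardized covariates."""
    beta = np.asarray(sp.beta, dtype=float)
    z_elev, z_edge = _zscore(cov.elev), _zscore(cov.edge)
    z_rain, z_maxT, z_minT = (_zscore(cov.rain), _zscore(cov.max_temp),
                              _zscore(cov.min_temp))
    J, T = cov.peop.shape
    with np.errstate(divide="ignore"):
        l_psi1 = np.log(sp.psi1 / (1 - sp.psi1)) if 0 < sp.psi1 < 1 else (
            np.inf if sp.psi1 == 1 else -np.inf)
        l_phi = np.log(sp.phi / (1 - sp.phi)) if 0 < sp.phi < 1 else (
            np.inf if sp.phi == 1 else -np.inf)
        l_gam = np.log(sp.gamma / (1 - sp.gamma)) if 0 < sp.gamma < 1 else (
            np.inf if sp.gamma == 1 else -np.inf)
    psi1 = _logistic(l_psi1 + beta[0] * z_elev + beta[1] * cov.peop[:, 0]
                     + beta[2] * z_edge)
    # transitions from year t to t+1 use source-year covariates
    yr = (beta[3] * z_rain + beta[4] * z_maxT + beta[5] * z_minT)[:T - 1]
    phi = _logistic(l_phi + yr[None, :] + beta[6] * cov.peop[:, :T - 1])
    yr = (beta[7] * z_rain + beta[8] * z_maxT + beta[9] * z_minT)[:T - 1]
    gam = _logistic(l_gam + yr[None, :] + beta[10] * cov.peop[:, :T - 1])
    return psi1, phi, gam


def simulate_community(config: CommunityConfig,
                       covariates: CovariateSet) -> list[TruthRecord]:
    """Simulate latent occupancy states for every species in the pool.

    First-year occupancy is Bernoulli(psi1) per point; afterwards an
    occupied point persists with probability phi and an empty point is
    colonized with probability gamma (point-specific when covariate
    effects are nonzero). Occupancy is closed within years.
    """
    if len(covariates.point_ids) != config.n_points or \
            len(covariates.years) != config.n_years:
        raise ValueError("covariate dimensions do not match config")
    rng = _rng(config, 1)
    J, T = config.n_points, config.n_years
    out = []
    for sp in config.species:
        psi1, phi, gam = _species_rates(sp, covariates)
        z = np.zeros((J, T), dtype=int)
        z[:, 0] = rng.random(J) < psi1
        for t in range(T - 1):
            stay = rng.random(J) < phi[:, t]
            col = rng.random(J) < gam[:, t]
            z[:, t + 1] = np.where(z[:, t] == 1, stay, col)
        # population-level annual expectation from the same dynamics
        psi_annual = np.empty(T)
        psi_annual[0] = float(np.mean(psi1))
        for t in range(T - 1):
            psi_annual[t + 1] = (psi_annual[t] * np.mean(phi[:, t])
                                 + (1 - psi_annual[t]) * np.mean(gam[:, t]))
        out.append(TruthRecord(
            species=sp.name, z=z, psi_annual=psi_annual,
            realized_occupancy=z.mean(axis=0),
            params=dataclasses.asdict(sp)))
    return out


def daily_detection_prob(p_period: float, config: CommunityConfig) -> float:
    """Convert per-period detection to per-day: ground-truth p is defined
    on the grouped (~7-8 day) scale the models operate on."""
    period_len = config.season_days / config.n_periods
    return 1.0 - (1.0 - p_period) ** (1.0 / period_len)


def simulate_detections(truth: list[TruthRecord],
                        config: CommunityConfig) -> pd.DataFrame:
    """Generate the photographic-event table from latent occupancy.

    Detections occur only at occupied points on active deployment days,
    each day independently with the derived daily probability. A detected
    day yields one photographic event at a random time of day, possibly
    with extra images less than a minute later (which the event-collapsing
    step must merge back into a single event).
    """
    rng = _rng(config, 2)
    mask = deployment_mask(config)
    J = config.n_points
    point_ids = [f"{config.site}-{j + 1:03d}" for j in range(J)]
    rows = []
    for rec in truth:
        sp = next(s for s in config.species if s.name == rec.species)
        p_day = daily_detection_prob(sp.p, config)
        for t in range(config.n_years):
            start = season_start(config, config.first_year + t)
            occ = rec.z[:, t] == 1
            hits = (rng.random((J, config.season_days)) < p_day) & mask \
                & occ[:, None]
            for j, d in zip(*np.nonzero(hits)):
                secs = int(rng.integers(6 * 3600, 18 * 3600))
                ts = start + timedelta(days=int(d), seconds=secs)
                n_extra = int(rng.poisson(config.extra_images_rate))
                for i in range(1 + n_extra):
                    rows.append((config.site, point_ids[j], rec.species,
                                 ts + timedelta(seconds=15 * i)))
    events = pd.DataFrame(rows,
                          columns=["site", "point", "species", "timestamp"])
    return events.sort_values(
        ["site", "point", "species", "timestamp"]).reset_index(drop=True)


def deployments_frame(config: CommunityConfig,
                      covariates: CovariateSet) -> pd.DataFrame:
    """Per (point, year) deployment windows with point attributes."""
    starts = deployment_start_days(config)
    rows = []
    for t, year in enumerate(covariates.years):
        base = season_start(config, year)
        for j, pid in enumerate(covariates.point_ids):
            d0 = base + timedelta(days=int(starts[j]))
            d1 = d0 + timedelta(days=config.deploy_days - 1)
            rows.append((config.site, pid,
                         round(-3.0 + 0.01 * (j % 10), 4),
                         round(-60.0 + 0.01 * (j // 10), 4),
                         round(covariates.elev[j], 1),
                         round(covariates.edge[j], 1),
                         d0.date().isoformat(), d1.date().isoformat()))
    return pd.DataFrame(rows, columns=["site", "point", "lat", "lon",
                                       "elev_m", "edge_m", "start_date",
                                       "end_date"])


def traits_frame(config: CommunityConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.name, s.taxon_class, s.mass_g, s.guild, s.iucn, s.hunted,
          s.terrestrial) for s in config.species],
        columns=["species", "class", "mass_g", "guild", "iucn", "hunted",
                 "terrestrial"])


def sites_frame(config: CommunityConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [(config.site, config.pa_size_ha, config.prop_forested,
          config.edge_density, config.pop_den)],
        columns=["site", "pa_size_ha", "prop_forested", "edge_density",
                 "pop_den"])


def simulate_bundle(config: CommunityConfig) -> dict:
    """Run the full generator; returns all tables plus ground truth."""
    cov = simulate_covariates(config)
    truth = simulate_community(config, cov)
    events = simulate_detections(truth, config)
    points, climate, peop = cov.to_frames()
    return {
        "events": events,
        "deployments": deployments_frame(config, cov),
        "climate": climate,
        "peop": peop,
        "traits": traits_frame(config),
        "sites": sites_frame(config),
        "covariates": cov,
        "truth": truth,
    }


def write_fixture_bundle(config: CommunityConfig, out_dir) -> dict:
    """Write the survey bundle as plain CSV plus a ground-truth JSON.

    Files: events.csv, deployments.csv, climate.csv, peop.csv, traits.csv,
    sites.csv, truth.json. Returns {name: path}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config)
    paths = {}
    for name in ("events", "deployments", "climate", "peop", "traits",
                 "sites"):
        path = out_dir / f"{name}.csv"
        bundle[name].to_csv(path, index=False)
        paths[name] = path
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            [
                {
                    "species": r.species,
                    "z": r.z.tolist(),
                    "psi_annual": r.psi_annual.tolist(),
                    "realized_occupancy": r.realized_occupancy.tolist(),
                    "params": r.params,
                }
                for r in bundle["truth"]
            ],
            fh, indent=1)
    paths["truth"] = truth_path
    return paths


def read_bundle(out_dir) -> dict:
    """Round-trip reader for :func:`write_fixture_bundle` CSV output."""
    out_dir = Path(out_dir)
    out = {}
    for name in ("events", "deployments", "climate", "peop", "traits",
                 "sites"):
        out[name] = pd.read_csv(out_dir / f"{name}.csv")
    out["events"]["timestamp"] = pd.to_datetime(out["events"]["timestamp"])
    return out
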