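"""Configuration objects for simulation and model fitting.

A :class:`CommunityConfig` describes one simulated camera-trap survey:
the sampling design (points, years, season window, per-point deployment
length) and the community of species with their true occupancy dynamics.
The defaults mirror a standard tropical-forest camera-trap protocol:
60 sampling points at ~1 point / 1-2 km^2, each deployed for at least 30
consecutive days within an annual dry-season window of ~105-120 days,
repeated for 3-8 years.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: order of the 11 covariate effects on the logit scale:
#: initial occupancy (elev, peop, edge), survival (rain, maxT, minT, peop),
#: colonization (rain, maxT, minT, peop).
BETA_NAMES = (
    "psi1_elev", "psi1_peop", "psi1_edge",
    "phi_rain", "phi_maxT", "phi_minT", "phi_peop",
    "gam_rain", "gam_maxT", "gam_minT", "gam_peop",
)


@dataclass
class SpeciesParams:
    """True parameters and traits of one simulated species.

    Probabilities: ``psi1`` initial occupancy, ``phi`` year-to-year
    survival, ``gamma`` colonization, ``p`` per-period detection.
    ``beta`` holds the 11 logit-scale covariate effects (order of
    :data:`BETA_NAMES`); all-zero means constant dynamics.
    """

    name: str
    psi1: float = 0.6
    phi: float = 0.8
    gamma: float = 0.1
    p: float = 0.3
    beta: tuple = (0.0,) * 11
    taxon_class: str = "Mammalia"
    mass_g: float = 5000.0
    guild: str = "Herbivore"
    iucn: str = "LC"
    hunted: str = "No"
    terrestrial: bool = True

    def __post_init__(self):
        for attr in ("psi1", "phi", "gamma", "p"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")
        if len(self.beta) != 11:
            raise ValueError(f"{self.name}: beta must have 11 entries")


@dataclass
class CommunityConfig:
    """Survey design, covariate generation and species pool for one site."""

    site: str = "SIM"
    n_points: int = 60
    n_years: int = 5
    season_days: int = 112
    deploy_days: int = 30
    n_periods: int = 15
    first_year: int = 2010
    species: Sequence[SpeciesParams] = field(
        default_factory=lambda: [SpeciesParams("species_01")]
    )
    # covariate generation
    elev_mean: float = 1200.0
    elev_sd: float = 300.0
    edge_mean: float = 2000.0
    edge_sd: float = 600.0
    rain_mean: float = 900.0
    rain_sd: float = 150.0
    max_temp_mean: float = 30.0
    max_temp_sd: float = 1.5
    min_temp_mean: float = 18.0
    min_temp_sd: float = 1.0
    peop_prob: float = 0.2
    #: mean extra images per photographic event (exercises the >=1-min rule)
    extra_images_rate: float = 0.3
    rng_seed: int = 0
    # site attributes written to the fixture bundle
    pa_size_ha: float = 100_000.0
    prop_forested: float = 0.8
    edge_density: float = 12.0
    pop_den: float = 20.0

    def __post_init__(self):
        if self.n_points <= 0 or self.n_years < 2:
            raise ValueError("n_points must be positive and n_years >= 2")
        if not 1 <= self.n_periods <= self.season_days:
            raise ValueError("need 1 <= n_periods <= season_days")
        if self.deploy_days > self.season_days or self.deploy_days <= 0:
            raise ValueError("need 0 < deploy_days <= season_days")
        if not 0.0 <= self.peop_prob <= 1.0:
            raise ValueError("peop_prob outside [0, 1]")
        self.species = [
            s if isinstance(s, SpeciesParams) else SpeciesParams(**s)
            for s in self.species
        ]

    @classmethod
    def from_file(cls, path) -> "CommunityConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MCMCConfig:
    """Chain settings for the dynamic occupancy samplers.

    ``profile="full"`` uses the full-length runs (Case 1: 3 chains of
    250,000 iterations; Case 2: 3 chains of 30,000 with 29,000 burn-in and
    thinning by 3); ``profile="fast"`` is the scaled-down default used for
    routine work and testing (3 chains of 5,000). Both retain 1,000 total
    posterior draws split evenly across chains.
    """

    profile: str = "fast"
    n_chains: int = 3
    n_iter: int | None = None
    burn_in: int | None = None
    thin: int = 1
    keep_total: int = 1000
    rng_seed: int = 0
    slab_sd: float = 10.0
    adapt_interval: int = 50

    _PROFILES = {
        "fast": {1: 5000, 2: 5000},
        "full": {1: 250_000, 2: 30_000},
    }

    def resolve(self, case: int) -> tuple[int, int, int]:
        """Return (n_iter, burn_in, thin) for the given case level."""
        if self.profile not in self._PROFILES:
            raise ValueError(f"unknown MCMC profile {self.profile!r}")
        n_iter = self.n_iter or self._PROFILES[self.profile][case]
        thin = self.thin
        if self.profile == "full" and case == 2 and self.thin == 1:
            thin = 3
        keep_per_chain = -(-self.keep_total // self.n_chains)
        burn = self.burn_in
        if burn is None:
            burn = n_iter - keep_per_chain * thin
        if not 0 <= burn < n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        return n_iter, burn, thin
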