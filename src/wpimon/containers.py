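"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class CovariateSet:
    """Site covariates: per-point (elev, edge), per-year climate
    (rain, max_temp, min_temp) and the per-point-per-year binary people
    covariate."""

    point_ids: list
    years: list
    elev: np.ndarray        # (J,)
    edge: np.ndarray        # (J,)
    rain: np.ndarray        # (T,)
    max_temp: np.ndarray    # (T,)
    min_temp: np.ndarray    # (T,)
    peop: np.ndarray        # (J, T) binary

    def __post_init__(self):
        J, T = len(self.point_ids), len(self.years)
        for name in ("elev", "edge", "rain", "max_temp", "min_temp", "peop"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.elev.shape != (J,) or self.edge.shape != (J,):
            raise ValueError("point covariates must have shape (n_points,)")
        if self.rain.shape != (T,):
            raise ValueError("year covariates must have shape (n_years,)")
        if self.peop.shape != (J, T):
            raise ValueError("peop must have shape (n_points, n_years)")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """(point table, climate table, peop long table)."""
        points = pd.DataFrame(
            {"point": self.point_ids, "elev_m": self.elev, "edge_m": self.edge}
        )
        climate = pd.DataFrame(
            {
                "year": self.years,
                "rain_mm": self.rain,
                "max_temp_c": self.max_temp,
                "min_temp_c": self.min_temp,
            }
        )
        peop = pd.DataFrame(
            [
                (p, y, int(self.peop[j, t]))
                for j, p in enumerate(self.point_ids)
                for t, y in enumerate(self.years)
            ],
            columns=["point", "year", "peop"],
        )
        return points, climate, peop


@dataclass
class DetectionHistory:
    """Grouped detection history of one population.

    ``values`` is a (points x years x periods) array with entries 1
    (detected), 0 (sampled, not detected) or NaN (point not sampled on any
    day of the period).
    """

    values: np.ndarray
    point_ids: list
    years: list
    population: str = ""
    site: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (points, years, periods)")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, (0.0, 1.0)).all():
            raise ValueError("entries must be 0, 1 or NaN")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]

    @property
    def n_periods(self) -> int:
        return self.values.shape[2]

    def annual_summaries(self) -> tuple[np.ndarray, np.ndarray]:
        """Per (point, year): number of detections and of sampled periods."""
        k = np.nansum(self.values, axis=2)
        n = np.sum(~np.isnan(self.values), axis=2)
        return k, n.astype(int)

    def is_empty(self) -> bool:
        return not np.any(~np.isnan(self.values))


@dataclass
class CaseLevel:
    """Detection-level stratum of a population (1 high, 2 medium, 3 low)."""

    level: int
    annual_detection_rate: float
    mean_detections_per_year: float


@dataclass
class TruthRecord:
    """Ground truth for one simulated species: latent occupancy states and
    the parameters that generated them."""

    species: str
    z: np.ndarray                      # (J, T) binary
    psi_annual: np.ndarray             # (T,) recursion values
    realized_occupancy: np.ndarray     # (T,) mean of z per year
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=int)
        if self.z.ndim != 2:
            raise ValueError("z must be (n_points, n_years)")


@dataclass
class PosteriorDraws:
    """Posterior annual-occupancy draws of one population — the common
    currency of the WPI and trend stages."""

    psi: np.ndarray                    # (n_draws, n_years)
    years: list
    case: int
    population: str = ""
    site: str = ""
    param_draws: dict = field(default_factory=dict)
    inclusion_prob: dict | None = None
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.ndim != 2:
            raise ValueError("psi must be (n_draws, n_years)")
        if np.nanmin(self.psi) < 0 or np.nanmax(self.psi) > 1:
            raise ValueError("occupancy draws must lie in [0, 1]")

    @property
    def n_draws(self) -> int:
        return self.psi.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n, T = self.psi.shape
        return pd.DataFrame(
            {
                "population": self.population,
                "site": self.site,
                "draw": np.repeat(np.arange(n), T),
                "year": np.tile(self.years, n),
                "psi": self.psi.ravel(),
            }
        )


@dataclass
class WpiSeries:
    """Posterior distribution of the Wildlife Picture Index per year."""

    level: str                         # site | regional | global | subset
    years: list
    draws: np.ndarray                  # (n_draws, n_years)
    central: np.ndarray                # per-year central tendency
    envelopes: dict                    # {50: (lo, hi), 80: ..., 95: ...}
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = {"level": self.level, "group": self.group, "year": self.years,
                "central": self.central}
        for lev, (lo, hi) in sorted(self.envelopes.items()):
            rows[f"lo{lev}"] = lo
            rows[f"hi{lev}"] = hi
        return pd.DataFrame(rows)


@dataclass
class TrendFit:
    """Distribution of logistic-trend slopes/intercepts across posterior
    realizations of one population."""

    slope_draws: np.ndarray
    intercept_draws: np.ndarray
    median_slope: float
    interval_80: tuple

    @property
    def n_draws(self) -> int:
        return self.slope_draws.size


@dataclass
class StatusRecord:
    """Occupancy-trend status of one population."""

    population: str
    site: str
    case: int
    status: str                        # Decreasing | Stable | Increasing | Unknown
    fit: TrendFit | None = None

    STATUSES = ("Decreasing", "Stable", "Increasing", "Unknown")

    def __post_init__(self):
        if self.status not in self.STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def status_frame(records: Sequence[StatusRecord]) -> pd.DataFrame:
    """Flatten status records to the CSV schema used by the CLI."""
    rows = []
    for r in records:
        lo, hi = (r.fit.interval_80 if r.fit else (np.nan, np.nan))
        rows.append(
            {
                "population": r.population,
                "site": r.site,
                "case": r.case,
                "median_slope": r.fit.median_slope if r.fit else np.nan,
                "slope_lo10": lo,
                "slope_hi90": hi,
                "status": r.status,
            }
        )
    return pd.DataFrame(rows)
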