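"""The Wildlife Picture Index (WPI).

WPI_{s,t} = exp( (1/n) * sum_i log( psi_ist / psi_is1 ) ): the geometric
mean, over the n populations of community s, of each population's
occupancy in year t relative to its baseline-year occupancy. Computed per
posterior realization, which yields a full posterior distribution of the
index each year; the index at the baseline year is identically 1.
"""

from __future__ import annotations

import numpy as np

from .containers import PosteriorDraws, WpiSeries
from .diagnostics import half_sample_mode

PSI_FLOOR = 1e-6
ENVELOPE_LEVELS = (50, 80, 95)


def _central(draws: np.ndarray) -> np.ndarray:
    """Median or half-sample mode per year, whichever is lowest."""
    med = np.median(draws, axis=0)
    mode = np.array([half_sample_mode(draws[:, t])
                     for t in range(draws.shape[1])])
    return np.minimum(med, mode)


def _envelopes(draws: np.ndarray) -> dict:
    out = {}
    for lev in ENVELOPE_LEVELS:
        half = (100 - lev) / 2
        out[lev] = (np.percentile(draws, half, axis=0),
                    np.percentile(draws, 100 - half, axis=0))
    return out


def _log_ratio_draws(pop: PosteriorDraws, years: list, baseline_year) -> np.ndarray:
    """(n_draws, n_years) log relative-occupancy draws of one population."""
    if list(pop.years) != list(years):
        raise ValueError(
            f"population {pop.population!r} has years {pop.years}, "
            f"expected {years}")
    b = list(years).index(baseline_year)
    psi = np.clip(pop.psi, PSI_FLOOR, None)
    return np.log(psi) - np.log(psi[:, b])[:, None]


def compute_wpi(draws_by_population: list[PosteriorDraws],
                baseline_year=None, level: str = "site",
                group: str = "") -> WpiSeries:
    """Eq-5 WPI posterior for one community.

    Populations must share the year axis and draw count; draws are paired
    by realization index across populations (independent posteriors, so
    index pairing is one valid convolution of the distributions).
    """
    if not draws_by_population:
        raise ValueError("no populations supplied")
    years = list(draws_by_population[0].years)
    if baseline_year is None:
        baseline_year = years[0]
    if baseline_year not in years:
        raise ValueError(f"baseline year {baseline_year} not in year axis")
    n_draws = {p.n_draws for p in draws_by_population}
    if len(n_draws) != 1:
        raise ValueError("populations have unequal draw counts")
    logs = np.stack([_log_ratio_draws(p, years, baseline_year)
                     for p in draws_by_population])
    draws = np.exp(np.nanmean(logs, axis=0))
    return WpiSeries(level=level, group=group, years=years, draws=draws,
                     central=_central(draws), envelopes=_envelopes(draws))


def subset_wpi(draws_by_population: list[PosteriorDraws], traits,
               trait_filter, baseline_year=None,
               group: str = "subset") -> WpiSeries:
    """Eq-5 WPI over the populations whose species satisfy a trait
    predicate (e.g. an IUCN class or dietary guild).

    ``traits`` maps population/species name to a trait record (dict-like
    rows); ``trait_filter(record) -> bool``.
    """
    chosen = []
    for pop in draws_by_population:
        key = pop.population.split(":", 1)[-1]
        rec = traits.get(key) if hasattr(traits, "get") else traits[key]
        if trait_filter(rec):
            chosen.append(pop)
    if not chosen:
        raise ValueError("trait filter matched no populations")
    return compute_wpi(chosen, baseline_year=baseline_year, level="subset",
                       group=group)


def aggregate_wpi(series_list: list[WpiSeries], weights: list[int],
                  level: str = "regional", group: str = "") -> WpiSeries:
    """Convolve site WPI distributions into one multi-site index.

    Per draw and year the aggregate is the population-count-weighted
    geometric mean of the site indices, which equals the pooled-community
    geometric mean when the sites share a baseline. Sites enter from
    their own baseline year; a later-starting site's baseline year is
    excluded for that site (its index there is the constant 1 and carries
    no information).
    """
    if not series_list:
        raise ValueError("no site series supplied")
    if len(weights) != len(series_list):
        raise ValueError("need one weight per site series")
    all_years = sorted({y for s in series_list for y in s.years})
    first_start = min(s.years[0] for s in series_list)
    n_draws = series_list[0].draws.shape[0]
    agg = np.full((n_draws, len(all_years)), np.nan)
    for ti, year in enumerate(all_years):
        num = np.zeros(n_draws)
        den = 0.0
        for s, wgt in zip(series_list, weights):
            if year not in s.years:
                continue
            if year == s.years[0] and s.years[0] > first_start:
                continue  # later-starting site's baseline carries no spread
            col = list(s.years).index(year)
            num += wgt * np.log(np.clip(s.draws[:, col], PSI_FLOOR, None))
            den += wgt
        if den > 0:
            agg[:, ti] = np.exp(num / den)
    return WpiSeries(level=level, group=group, years=all_years, draws=agg,
                     central=_central(agg), envelopes=_envelopes(agg))
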