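"""Long-term occupancy trend classification.

For each posterior realization of a population's annual occupancy
trajectory, a logistic curve psi(t) = 1 / (1 + exp(-(alpha + beta t))) is
fitted through time; because each realization is a deterministic
trajectory within (0,1), the fit is the exact ordinary-least-squares line
of logit(psi) on t. The distribution of slopes over the realizations
yields the trend call: 80th-percentile interval (10th-90th quantiles)
entirely below zero = Decreasing, entirely above = Increasing, otherwise
Stable — except that low-detection (Case 3) populations whose interval
straddles zero are labelled Unknown, since with so few detections "no
detectable change" reflects lack of power, not stability.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .containers import PosteriorDraws, StatusRecord, TrendFit

EPS = 1e-6
INTERVAL = (10.0, 90.0)


def fit_trend(draws: PosteriorDraws | np.ndarray, years=None) -> TrendFit:
    """Per-realization logistic trend fit; returns the slope/intercept
    distributions. Years with no draws (all NaN) are dropped; at least 3
    observed years are required."""
    if isinstance(draws, PosteriorDraws):
        psi = draws.psi
        years = np.asarray(draws.years, dtype=float)
    else:
        psi = np.asarray(draws, dtype=float)
        years = (np.arange(psi.shape[1], dtype=float) if years is None
                 else np.asarray(years, dtype=float))
    ok = ~np.all(np.isnan(psi), axis=0)
    psi, years = psi[:, ok], years[ok]
    if psi.shape[1] < 3:
        raise ValueError("need >= 3 observed years to fit a trend")
    t = years - years.mean()  # centering: symmetric design, same slope
    lo = np.log(np.clip(psi, EPS, 1 - EPS) / (1 - np.clip(psi, EPS, 1 - EPS)))
    denom = np.sum(t ** 2)
    slopes = lo @ t / denom
    intercepts = lo.mean(axis=1) - slopes * years.mean()
    q10, q90 = np.percentile(slopes, INTERVAL)  # linear interpolation
    return TrendFit(slope_draws=slopes, intercept_draws=intercepts,
                    median_slope=float(np.median(slopes)),
                    interval_80=(float(q10), float(q90)))


def classify_status(fit: TrendFit, case: int, population: str = "",
                    site: str = "") -> StatusRecord:
    """Trend call from the 80th-percentile slope interval.

    An interval touching zero exactly counts as straddling (conservative:
    early warnings are preferred to missed declines, so the significance
    cut is strict)."""
    lo, hi = fit.interval_80
    if hi < 0:
        status = "Decreasing"
    elif lo > 0:
        status = "Increasing"
    elif case == 3:
        status = "Unknown"
    else:
        status = "Stable"
    return StatusRecord(population=population, site=site, case=case,
                        status=status, fit=fit)


def classify_population(draws: PosteriorDraws) -> StatusRecord:
    return classify_status(fit_trend(draws), draws.case,
                           population=draws.population, site=draws.site)


def status_table(records, collapse_unknown: bool = False) -> pd.DataFrame:
    """Case x status contingency table of population trend calls.

    With ``collapse_unknown`` the Unknown column is merged into a single
    no-detectable-change column alongside Stable (the 3-status view)."""
    if not records:
        raise ValueError("no status records")
    counts = Counter((r.case, r.status) for r in records)
    cols = (["Decreasing", "Stable", "Increasing", "Unknown"]
            if not collapse_unknown
            else ["Decreasing", "NoChange", "Increasing"])
    cases = sorted({r.case for r in records})
    rows = []
    for case in cases:
        if collapse_unknown:
            rows.append([counts[(case, "Decreasing")],
                         counts[(case, "Stable")] + counts[(case, "Unknown")],
                         counts[(case, "Increasing")]])
        else:
            rows.append([counts[(case, s)] for s in cols])
    return pd.DataFrame(rows, index=pd.Index(cases, name="case"),
                        columns=cols)
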