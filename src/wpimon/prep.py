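"""From photographic events to grouped detection histories.

The observational record for one population is condensed into a
points x days presence-absence matrix per year (1 photographed, 0 sampled
without a photograph, NaN not sampled), then grouped into 15 contiguous
time periods of ~7-8 days each. Populations are stratified by detection
level: Case 1 (>8% annual detection), Case 2 (>=5 detections/year but
<=8%), Case 3 (<5 detections/year).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import CaseLevel, DetectionHistory

logger = logging.getLogger(__name__)

MIN_MASS_G = 100.0
ARBOREAL_MIN_EVENTS = 5
CASE1_RATE = 0.08
CASE3_DETECTIONS = 5.0


def collapse_events(events: pd.DataFrame,
                    min_separation: pd.Timedelta = pd.Timedelta(minutes=1)
                    ) -> pd.DataFrame:
    """Merge images into photographic events.

    Within each (point, species), an image closer than ``min_separation``
    to the previously retained event is merged into it (greedy
    left-to-right); images exactly ``min_separation`` apart are distinct
    events. Returns the retained rows sorted by point, species, time.
    """
    if events.empty:
        return events.copy()
    ev = events.copy()
    try:
        ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    except (ValueError, TypeError) as exc:
        bad = None
        for i, v in enumerate(events["timestamp"]):
            try:
                pd.to_datetime(v)
            except (ValueError, TypeError):
                bad = i
                break
        raise ValueError(f"malformed timestamp in events row {bad}") from exc
    keys = [c for c in ("site", "point", "species") if c in ev.columns]
    ev = ev.sort_values(keys + ["timestamp"], kind="stable")
    keep = np.zeros(len(ev), dtype=bool)
    for _, idx in ev.groupby(keys, sort=False).indices.items():
        times = ev["timestamp"].to_numpy()[idx]
        last = None
        for pos, t in zip(idx, times):
            if last is None or (t - last) >= min_separation.to_timedelta64():
                keep[pos] = True
                last = t
    return ev.iloc[keep].reset_index(drop=True)


def filter_species(traits: pd.DataFrame, events: pd.DataFrame) -> list[str]:
    """Apply the species-inclusion rules.

    Retained: mass >= 100 g AND (ground-dwelling OR arboreal with >=5
    photographic events in every surveyed year at at least one site).
    Species appearing in events but missing from the trait table are
    excluded with a warning.
    """
    known = set(traits["species"])
    orphan = sorted(set(events["species"]) - known)
    if orphan:
        warnings.warn(f"species missing from trait table, excluded: {orphan}")
    ev = events.copy()
    ev["year"] = pd.to_datetime(ev["timestamp"]).dt.year
    kept = []
    for _, row in traits.iterrows():
        if row["mass_g"] < MIN_MASS_G:
            continue
        if bool(row.get("terrestrial", True)):
            kept.append(row["species"])
            continue
        sub = ev[ev["species"] == row["species"]]
        if sub.empty:
            continue
        ok = False
        for site, site_ev in sub.groupby("site"):
            surveyed_years = sorted(ev[ev["site"] == site]["year"].unique())
            counts = site_ev.groupby("year").size()
            if all(counts.get(y, 0) >= ARBOREAL_MIN_EVENTS
                   for y in surveyed_years):
                ok = True
                break
        if ok:
            kept.append(row["species"])
        else:
            logger.info("arboreal species %s excluded (<%d events in some "
                        "surveyed year at every site)", row["species"],
                        ARBOREAL_MIN_EVENTS)
    return kept


def build_history(events: pd.DataFrame, deployments: pd.DataFrame,
                  species: str, year: int) -> tuple[np.ndarray, list, pd.Timestamp]:
    """Day-level detection matrix for one species and year.

    Returns (matrix, point_ids, window_start): matrix is
    points x days over the site season window (first deployment start to
    last deployment end in that year), with 1 = photographed that day,
    0 = sampled without photograph, NaN = point not active.
    """
    dep = deployments.copy()
    dep["start_date"] = pd.to_datetime(dep["start_date"])
    dep["end_date"] = pd.to_datetime(dep["end_date"])
    dep = dep[dep["start_date"].dt.year == year]
    if dep.empty:
        raise ValueError(f"no deployments in year {year}")
    t0 = dep["start_date"].min()
    t1 = dep["end_date"].max()
    n_days = (t1 - t0).days + 1
    point_ids = sorted(dep["point"].unique())
    jdx = {p: j for j, p in enumerate(point_ids)}
    mat = np.full((len(point_ids), n_days), np.nan)
    for _, row in dep.iterrows():
        a = (row["start_date"] - t0).days
        b = (row["end_date"] - t0).days
        mat[jdx[row["point"]], a:b + 1] = 0.0
    ev = events[events["species"] == species].copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    ev = ev[ev["timestamp"].dt.year == year]
    for _, row in ev.iterrows():
        if row["point"] not in jdx:
            raise ValueError(
                f"event at point {row['point']!r} with no deployment window")
        d = (row["timestamp"].normalize() - t0).days
        if not 0 <= d < n_days or np.isnan(mat[jdx[row["point"]], d]):
            raise ValueError(
                f"event at {row['point']} on {row['timestamp'].date()} "
                "outside its deployment window")
        mat[jdx[row["point"]], d] = 1.0
    return mat, point_ids, t0


def period_slices(n_days: int, n_periods: int = 15) -> list[slice]:
    """Split ``n_days`` into ``n_periods`` contiguous blocks; the first
    ``n_days % n_periods`` blocks are one day longer."""
    if n_days < n_periods:
        raise ValueError(f"cannot form {n_periods} periods from {n_days} days")
    base, extra = divmod(n_days, n_periods)
    out, pos = [], 0
    for i in range(n_periods):
        ln = base + (1 if i < extra else 0)
        out.append(slice(pos, pos + ln))
        pos += ln
    return out


def group_periods(day_matrix: np.ndarray, n_periods: int = 15) -> np.ndarray:
    """Collapse a points x days matrix to points x periods.

    A period is 1 if any constituent day is 1, 0 if at least one day was
    sampled and none is 1, NaN if no day was sampled.
    """
    day_matrix = np.asarray(day_matrix, dtype=float)
    out = np.full((day_matrix.shape[0], n_periods), np.nan)
    for i, sl in enumerate(period_slices(day_matrix.shape[1], n_periods)):
        block = day_matrix[:, sl]
        sampled = ~np.isnan(block)
        any_sampled = sampled.any(axis=1)
        hit = np.nansum(np.where(sampled, block, 0.0), axis=1) > 0
        out[any_sampled, i] = hit[any_sampled].astype(float)
    return out


def build_detection_history(events: pd.DataFrame, deployments: pd.DataFrame,
                            species: str, years=None, n_periods: int = 15,
                            site: str = "") -> DetectionHistory:
    """Grouped detection history across all surveyed years."""
    dep_years = sorted(pd.to_datetime(deployments["start_date"]).dt.year.unique())
    years = list(years) if years is not None else dep_years
    mats, pids = [], None
    for year in years:
        day_mat, point_ids, _ = build_history(events, deployments, species, year)
        if pids is None:
            pids = point_ids
        elif point_ids != pids:
            raise ValueError("point set differs between years")
        mats.append(group_periods(day_mat, n_periods))
    values = np.stack(mats, axis=1)  # (J, T, K)
    return DetectionHistory(values=values, point_ids=pids, years=years,
                            population=f"{site}:{species}" if site else species,
                            site=site)


def classify_case(history: DetectionHistory) -> CaseLevel:
    """Assign the detection-level stratum of a population.

    The annual detection rate is total detections over total sampled
    grouped cells (missing cells excluded from the denominator); mean
    detections per year is total detections / number of years. Level 1 if
    rate > 8%; else level 3 if mean detections < 5; else level 2.
    """
    if history.is_empty():
        raise ValueError("empty detection history")
    y_total = float(np.nansum(history.values))
    cells = int(np.sum(~np.isnan(history.values)))
    rate = y_total / cells
    mean_det = y_total / history.n_years
    if rate > CASE1_RATE:
        level = 1
    elif mean_det < CASE3_DETECTIONS:
        level = 3
    else:
        level = 2
    return CaseLevel(level=level, annual_detection_rate=rate,
                     mean_detections_per_year=mean_det)


def prepare_populations(events: pd.DataFrame, deployments: pd.DataFrame,
                        traits: pd.DataFrame, n_periods: int = 15,
                        site: str = "") -> dict[str, DetectionHistory]:
    """Full preparation stage: collapse events, filter species, build one
    grouped history per retained population (species with at least one
    event). Populations with empty histories are dropped and logged."""
    ev = collapse_events(events)
    species = filter_species(traits, ev)
    out = {}
    for sp in species:
        if not (ev["species"] == sp).any():
            logger.info("species %s has no events at %s; skipped", sp, site)
            continue
        hist = build_detection_history(ev, deployments, sp,
                                       n_periods=n_periods, site=site)
        if hist.is_empty():
            logger.info("population %s has empty history; skipped", sp)
            continue
        out[sp] = hist
    return out
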