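"""Community-level status analyses.

G-tests of independence between categorical factors and occupancy-status
frequencies (with Bonferroni control over the six factor families),
binomial GLMs of per-site status proportions against continuous site
covariates with AIC comparison to the null model, and the landscape
classification chain (sqrt-transformed edge density, Mahalanobis
distances, UPGMA clustering cut at height 1.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

FACTORS = ("class", "iucn", "mass_category", "guild", "landscape", "hunting")
BONFERRONI_ALPHA = 0.05 / 6  # six factor families examined
STATUS_ORDER = ("Decreasing", "Stable", "Increasing", "Unknown")


@dataclass
class GTestResult:
    G: float
    df: int
    p: float
    significant: bool | None = None


def g_test(table) -> GTestResult:
    """Log-likelihood-ratio goodness-of-fit test of independence.

    G = 2 sum O ln(O/E) over cells with O > 0, E from the independence
    model; p from the chi-square tail with (r-1)(c-1) df.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=1) == 0) or np.any(tab.sum(axis=0) == 0):
        raise ValueError("zero row or column marginal")
    g, p, df, _ = st.chi2_contingency(tab, correction=False,
                                      lambda_="log-likelihood")
    return GTestResult(G=float(g), df=int(df), p=float(p))


def mass_category(mass_g: float) -> str:
    """Order-of-magnitude body-mass bins: 100-1,000 g / 1,001-10,000 g /
    >10,000 g."""
    if mass_g < 100:
        raise ValueError("species below 100 g are excluded from monitoring")
    if mass_g <= 1000:
        return "100-1000g"
    if mass_g <= 10000:
        return "1001-10000g"
    return ">10000g"


def status_by_factor(status_df: pd.DataFrame, factor: str,
                     alpha_family: float = 0.05,
                     n_tests: int = 6) -> tuple[GTestResult, pd.DataFrame]:
    """G-test of status composition across the levels of one factor.

    ``status_df`` needs columns ``status`` and the factor column (for
    ``mass_category`` a ``mass_g`` column is binned on the fly). Factor
    levels with zero populations are dropped with a warning. The
    significance flag applies the Bonferroni-corrected threshold
    alpha_family / n_tests (0.05/6 = 0.008 by default).
    """
    df = status_df.copy()
    if factor == "mass_category" and "mass_category" not in df.columns:
        df["mass_category"] = df["mass_g"].map(mass_category)
    if factor not in df.columns:
        raise ValueError(f"factor {factor!r} not present")
    statuses = [s for s in STATUS_ORDER if (df["status"] == s).any()]
    table = pd.crosstab(df[factor], df["status"])[statuses]
    empty = table.index[table.sum(axis=1) == 0]
    if len(empty):
        warnings.warn(f"dropping empty {factor} levels: {list(empty)}")
        table = table.drop(index=empty)
    res = g_test(table.to_numpy())
    res.significant = res.p < alpha_family / n_tests
    return res, table


@dataclass
class GlmResult:
    response: str
    covariate: str
    intercept: float
    slope: float
    aic: float
    null_aic: float
    separation_warning: bool = False

    @property
    def delta_aic(self) -> float:
        """null AIC minus covariate-model AIC (positive favors covariate)."""
        return self.null_aic - self.aic


def site_proportion_glm(site_table: pd.DataFrame, response: str,
                        covariate: str, weighted: bool = True) -> GlmResult:
    """Binomial GLM of per-site status proportions on one site covariate.

    ``site_table`` needs columns ``n_<response>`` (populations with that
    status per site), ``n_total`` and the covariate. Fits events/trials
    (weights = populations per site) unless ``weighted=False``, which
    treats every site proportion as a single binomial trial of size 1
    rescaled (unweighted variant). AIC is computed from the nominal
    parameter count (-2 log L + 2k, k = number of regression columns), so
    a covariate that adds no fit — e.g. an identically-zero column —
    costs exactly 2 AIC relative to the null model.
    """
    import statsmodels.api as sm

    if len(site_table) < 3:
        raise ValueError("need >= 3 sites")
    succ = site_table[f"n_{response}"].to_numpy(dtype=float)
    tot = site_table["n_total"].to_numpy(dtype=float)
    if not weighted:
        with np.errstate(invalid="ignore"):
            prop = succ / tot
        succ, tot = prop, np.ones_like(prop)
    fail = tot - succ
    x = site_table[covariate].to_numpy(dtype=float)
    endog = np.column_stack([succ, fail])
    exog = sm.add_constant(x)
    sep = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        except Exception as exc:  # complete separation can break IRLS
            raise RuntimeError(f"GLM failed for {covariate}: {exc}") from exc
        sep = any("separation" in str(c.message).lower()
                  or "converge" in str(c.message).lower() for c in caught)
    null = sm.GLM(endog, np.ones((len(succ), 1)),
                  family=sm.families.Binomial()).fit()
    if sep:
        warnings.warn(f"possible separation fitting {covariate}; "
                      "coefficients reported anyway")
    return GlmResult(response=response, covariate=covariate,
                     intercept=float(fit.params[0]), slope=float(fit.params[1]),
                     aic=float(-2 * fit.llf + 2 * exog.shape[1]),
                     null_aic=float(-2 * null.llf + 2),
                     separation_warning=sep)


def landscape_cluster(site_metrics: pd.DataFrame,
                      cut_height: float = 1.5) -> pd.Series:
    """Classify site landscapes from (prop_forested, edge_density).

    Edge density is square-root transformed, pairwise Mahalanobis
    distances remove the correlation between the two connectivity
    metrics, and UPGMA (average-linkage) agglomeration is cut at the
    given dendrogram height.
    """
    need = {"prop_forested", "edge_density"}
    if not need.issubset(site_metrics.columns):
        raise ValueError(f"site metrics need columns {sorted(need)}")
    if len(site_metrics) < 2:
        raise ValueError("need >= 2 sites")
    if (site_metrics["edge_density"] < 0).any():
        raise ValueError("edge_density must be non-negative")
    X = np.column_stack([site_metrics["prop_forested"].to_numpy(dtype=float),
                         np.sqrt(site_metrics["edge_density"].to_numpy(dtype=float))])
    if np.allclose(X, X[0]):  # indistinguishable sites: one landscape type
        return pd.Series(np.ones(len(X), dtype=np.int32),
                         index=site_metrics.index, name="landscape")
    cov = np.cov(X.T)
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("singular metric covariance (collinear metrics); "
                         "jitter the values or drop a metric")
    d = pdist(X, metric="mahalanobis", VI=np.linalg.inv(cov))
    lk = linkage(d, method="average")
    labels = fcluster(lk, t=cut_height, criterion="distance")
    return pd.Series(labels, index=site_metrics.index, name="landscape")


def analysis_report(status_df: pd.DataFrame, site_table: pd.DataFrame,
                    factors=FACTORS,
                    responses=("increasing", "decreasing"),
                    covariates=("log_pa_size", "pop_den", "prop_forested",
                                "edge_density", "prop_hunted",
                                "n_years")) -> dict:
    """Run every factor G-test and site-proportion GLM; returns a plain
    dict suitable for JSON export."""
    report = {"g_tests": {}, "glms": []}
    for factor in factors:
        if factor not in status_df.columns and not (
                factor == "mass_category" and "mass_g" in status_df.columns):
            continue
        try:
            res, table = status_by_factor(status_df, factor)
        except ValueError as exc:  # degenerate table (e.g. single level)
            report["g_tests"][factor] = {"skipped": str(exc)}
            continue
        report["g_tests"][factor] = {
            "G": res.G, "df": res.df, "p": res.p,
            "significant_bonferroni": bool(res.significant),
            "table": table.to_dict(),
        }
    for resp in responses:
        for cov in covariates:
            if cov not in site_table.columns:
                continue
            g = site_proportion_glm(site_table, resp, cov)
            report["glms"].append({
                "response": resp, "covariate": cov, "slope": g.slope,
                "intercept": g.intercept, "aic": g.aic,
                "null_aic": g.null_aic, "delta_aic": g.delta_aic,
            })
    return report


def stacked_bar_export(status_df: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Relative status frequencies per factor level (plain-table stand-in
    for relative multiple bar plots)."""
    table = pd.crosstab(status_df[factor], status_df["status"])
    return table.div(table.sum(axis=1), axis=0)
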