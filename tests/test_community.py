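"""G-tests, site-proportion GLMs, mass binning and landscape clustering."""

import numpy as np
import pandas as pd
import pytest

import wpimon as w
from wpimon.community import (BONFERRONI_ALPHA, GTestResult, analysis_report,
                              stacked_bar_export)


class TestGTest:
    def test_proportional_rows_give_zero(self):
        res = w.g_test([[10, 20, 30], [20, 40, 60]])
        assert res.G == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_degrees_of_freedom(self):
        assert w.g_test([[5, 5], [5, 5]]).df == 1
        assert w.g_test([[5, 5, 5], [5, 5, 5], [5, 5, 5]]).df == 4

    def test_zero_observed_cells_contribute_zero(self):
        res = w.g_test([[10, 0], [5, 5]])
        assert np.isfinite(res.G) and res.G > 0

    def test_matches_mutual_information_identity(self, rng):
        # G = 2 N * I(rows; cols) in nats
        for _ in range(20):
            tab = rng.integers(1, 40, size=(3, 4)).astype(float)
            n = tab.sum()
            p = tab / n
            pr, pc = p.sum(1, keepdims=True), p.sum(0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(p > 0, p * np.log(p / (pr * pc)), 0.0)
            assert w.g_test(tab).G == pytest.approx(2 * n * terms.sum(),
                                                    abs=1e-10)

    @pytest.mark.parametrize("k", [2, 3])
    def test_additive_under_pooling_of_identical_tables(self, k, rng):
        tab = rng.integers(1, 30, size=(2, 3)).astype(float)
        assert w.g_test(k * tab).G == pytest.approx(k * w.g_test(tab).G,
                                                    abs=1e-8)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            w.g_test([[0, 0], [3, 4]])


class TestStatusByFactor:
    def _df(self):
        rng = np.random.default_rng(1)
        n = 120
        return pd.DataFrame({
            "status": rng.choice(["Decreasing", "Stable", "Increasing",
                                  "Unknown"], n),
            "guild": rng.choice(["Carnivore", "Herbivore", "Omnivore"], n),
            "mass_g": rng.choice([500.0, 1000.0, 1001.0, 20000.0], n),
        })

    def test_bonferroni_threshold(self):
        assert BONFERRONI_ALPHA == pytest.approx(0.05 / 6)
        res = GTestResult(G=1.0, df=2, p=0.01)
        res.significant = res.p < BONFERRONI_ALPHA
        assert not res.significant  # p = 0.01 not significant at 0.008
        res2 = GTestResult(G=1.0, df=2, p=0.007)
        res2.significant = res2.p < BONFERRONI_ALPHA
        assert res2.significant

    def test_factor_table_and_flag(self):
        res, table = w.status_by_factor(self._df(), "guild")
        assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)
        assert res.significant == (res.p < 0.05 / 6)

    def test_mass_binning_boundaries(self):
        assert w.mass_category(100.0) == "100-1000g"
        assert w.mass_category(1000.0) == "100-1000g"
        assert w.mass_category(1001.0) == "1001-10000g"
        assert w.mass_category(10000.0) == "1001-10000g"
        assert w.mass_category(10001.0) == ">10000g"
        with pytest.raises(ValueError):
            w.mass_category(99.0)

    def test_mass_category_built_on_the_fly(self):
        res, table = w.status_by_factor(self._df(), "mass_category")
        assert set(table.index) <= {"100-1000g", "1001-10000g", ">10000g"}


class TestSiteProportionGlm:
    def _sites(self, slope=0.0, rng=None, n=12):
        rng = rng or np.random.default_rng(2)
        x = rng.normal(0, 1, n)
        tot = rng.integers(20, 60, n)
        p = 1 / (1 + np.exp(-(-0.8 + slope * x)))
        inc = rng.binomial(tot, p)
        return pd.DataFrame({"site": [f"S{i}" for i in range(n)],
                             "n_total": tot, "n_increasing": inc,
                             "n_decreasing": tot - inc, "cov": x,
                             "zero": np.zeros(n)})

    def test_constant_covariate_equals_null_with_two_aic_penalty(self):
        g = w.site_proportion_glm(self._sites(), "increasing", "zero")
        assert g.aic == pytest.approx(g.null_aic + 2.0, abs=1e-6)
        assert g.slope == pytest.approx(0.0, abs=1e-8)

    def test_interceptonly_matches_pooled_proportion_closed_form(self):
        df = self._sites()
        g = w.site_proportion_glm(df, "increasing", "zero")
        pooled = df["n_increasing"].sum() / df["n_total"].sum()
        assert g.intercept == pytest.approx(np.log(pooled / (1 - pooled)),
                                            abs=1e-6)

    def test_strong_effect_recovered_and_preferred_by_aic(self):
        g = w.site_proportion_glm(self._sites(slope=1.5), "increasing", "cov")
        assert g.slope > 0
        assert g.delta_aic > 2.0  # covariate model beats null

    def test_needs_three_sites(self):
        with pytest.raises(ValueError):
            w.site_proportion_glm(self._sites().iloc[:2], "increasing", "cov")

    def test_unweighted_variant_runs(self):
        g = w.site_proportion_glm(self._sites(), "increasing", "cov",
                                  weighted=False)
        assert np.isfinite(g.aic)


class TestLandscapeCluster:
    def _metrics(self, groups, spread=0.002, rng=None):
        rng = rng or np.random.default_rng(3)
        rows = []
        for (pf, ed), n in groups:
            for _ in range(n):
                rows.append((pf + rng.normal(0, spread),
                             max(ed + rng.normal(0, spread), 0.0)))
        return pd.DataFrame(rows, columns=["prop_forested", "edge_density"])

    def test_three_separated_groups_recovered(self):
        m = self._metrics([((0.9, 2.0), 5), ((0.3, 2.0), 5), ((0.6, 40.0), 5)])
        labels = w.landscape_cluster(m)
        assert labels.nunique() == 3
        # members of each planted group share a label
        for a in range(3):
            assert labels.iloc[a * 5:(a + 1) * 5].nunique() == 1

    def test_identical_sites_form_single_cluster(self):
        m = pd.DataFrame({"prop_forested": [0.5] * 6,
                          "edge_density": [10.0] * 6})
        assert w.landscape_cluster(m).nunique() == 1

    def test_upgma_merge_heights_match_hand_agglomeration(self):
        # four sites; hand-run average-linkage on the same Mahalanobis
        # distances, then compare the partition at the cut height
        m = pd.DataFrame({"prop_forested": [0.1, 0.15, 0.8, 0.85],
                          "edge_density": [4.0, 4.41, 25.0, 26.01]})
        X = np.column_stack([m["prop_forested"],
                             np.sqrt(m["edge_density"])])
        VI = np.linalg.inv(np.cov(X.T))
        def d(i, j):
            diff = X[i] - X[j]
            return float(np.sqrt(diff @ VI @ diff))
        # hand UPGMA trace
        dist = {frozenset({i, j}): d(i, j)
                for i in range(4) for j in range(i + 1, 4)}
        clusters = [{0}, {1}, {2}, {3}]
        merges = []
        while len(clusters) > 1:
            best = min(((a, b) for i, a in enumerate(clusters)
                        for b in clusters[i + 1:]),
                       key=lambda ab: np.mean([d(i, j) for i in ab[0]
                                               for j in ab[1]]))
            h = np.mean([d(i, j) for i in best[0] for j in best[1]])
            merges.append(h)
            clusters = [c for c in clusters if c not in best] + \
                [best[0] | best[1]]
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist
        lk = linkage(pdist(X, metric="mahalanobis", VI=VI), method="average")
        np.testing.assert_allclose(sorted(lk[:, 2]), sorted(merges),
                                   atol=1e-10)
        # and the production chain runs on the same table
        assert len(w.landscape_cluster(m)) == 4

    def test_labels_invariant_to_site_order(self):
        m = self._metrics([((0.9, 2.0), 4), ((0.2, 30.0), 4)])
        lab = w.landscape_cluster(m)
        perm = np.random.default_rng(0).permutation(len(m))
        lab2 = w.landscape_cluster(m.iloc[perm].reset_index(drop=True))
        # same partition, possibly renamed labels
        for i in range(len(m)):
            for j in range(len(m)):
                same1 = lab.iloc[perm[i]] == lab.iloc[perm[j]]
                same2 = lab2.iloc[i] == lab2.iloc[j]
                assert same1 == same2

    def test_collinear_metrics_rejected(self):
        m = pd.DataFrame({"prop_forested": [0.1, 0.2, 0.3, 0.4],
                          "edge_density": [0.01, 0.04, 0.09, 0.16]})
        # sqrt(edge) = prop * 1.0 exactly -> singular covariance
        with pytest.raises(ValueError, match="singular"):
            w.landscape_cluster(m)


def test_analysis_report_and_stacked_bar_export():
    rng = np.random.default_rng(4)
    status = pd.DataFrame({
        "status": rng.choice(["Decreasing", "Stable", "Increasing",
                              "Unknown"], 80),
        "guild": rng.choice(["Carnivore", "Herbivore"], 80),
        "class": rng.choice(["Mammalia", "Aves"], 80),
        "mass_g": rng.choice([500.0, 5000.0], 80),
    })
    sites = pd.DataFrame({
        "site": [f"S{i}" for i in range(6)],
        "n_total": [40, 30, 50, 20, 25, 35],
        "n_increasing": [5, 6, 10, 2, 4, 7],
        "n_decreasing": [8, 5, 12, 3, 6, 9],
        "pop_den": np.arange(6, dtype=float),
    })
    rep = analysis_report(status, sites,
                          factors=("class", "guild", "mass_category"),
                          covariates=("pop_den",))
    assert set(rep["g_tests"]) == {"class", "guild", "mass_category"}
    assert len(rep["glms"]) == 2  # increasing + decreasing vs pop_den
    bars = stacked_bar_export(status, "guild")
    np.testing.assert_allclose(bars.sum(axis=1), 1.0)
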