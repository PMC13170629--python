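"""Edge GLM, component extraction, and the permutation NBS."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from axonet import (ConnectivityMatrix, EdgeStatMap, NBS, edge_glm,
                    threshold_components, nbs_test, threshold_sweep)


# ---------------------------------------------------------------- oracles
def ols_oracle(y, X):
    """Closed-form normal-equations OLS: betas, t-stats, p-values."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtX)))
    t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), df)
    return beta, t, p, df


def union_find_components(edges):
    """Brute-force union-find partition of an edge list."""
    parent = {}

    def find(a):
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for a, b in edges:
        groups.setdefault(find(a), []).append((min(a, b), max(a, b)))
    return sorted((sorted(es) for es in groups.values()),
                  key=lambda es: (-len(es), es[0]))


def _toy_connectomes(weights_per_edge, n_nodes=4, edge=(0, 1)):
    """One varying edge plus a second constant edge, per participant."""
    conns = {}
    for i, w in enumerate(weights_per_edge):
        m = np.zeros((n_nodes, n_nodes))
        m[edge[0], edge[1]] = m[edge[1], edge[0]] = w
        m[2, 3] = m[3, 2] = 0.5
        conns[f"p{i}"] = ConnectivityMatrix(m, "FA")
    return conns


def _statmap_from(tmat, mask=None):
    n = tmat.shape[0]
    if mask is None:
        mask = ~np.eye(n, dtype=bool)
    return EdgeStatMap(n, tmat, df=10, mask=mask)


class TestEdgeGlm:
    def test_matches_closed_form_oracle_to_1e10(self):
        rng = np.random.default_rng(1)
        n = 10
        x = pd.Series(rng.standard_normal(n),
                      index=[f"p{i}" for i in range(n)])
        cov = pd.DataFrame({"c": rng.standard_normal(n)}, index=x.index)
        w = 0.4 + 0.1 * x.to_numpy() + 0.05 * cov["c"].to_numpy() \
            + 0.02 * rng.standard_normal(n)
        conns = _toy_connectomes(w)
        sm_res = edge_glm(conns, x, cov)
        X = np.column_stack([np.ones(n), x, cov["c"]])
        _, t_or, _, df_or = ols_oracle(w, X)
        assert sm_res.df == df_or
        assert sm_res.t[0, 1] == pytest.approx(t_or[1], abs=1e-10)
        assert sm_res.t[0, 1] == sm_res.t[1, 0]

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = 18
        x = pd.Series(rng.standard_normal(n),
                      index=[f"p{i}" for i in range(n)])
        cov = pd.DataFrame({"a": rng.standard_normal(n),
                            "b": rng.standard_normal(n)}, index=x.index)
        w = rng.uniform(0.2, 0.8, n)
        res = edge_glm(_toy_connectomes(w), x, cov)
        X = sm.add_constant(np.column_stack([x, cov]))
        fit = sm.OLS(w, X).fit()
        assert res.t[0, 1] == pytest.approx(fit.tvalues[1], abs=1e-10)

    def test_constant_edges_dropped_from_mask(self):
        x = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8],
                      index=[f"p{i}" for i in range(8)])
        conns = _toy_connectomes(np.full(8, 0.4))
        res = edge_glm(conns, x)
        assert not res.mask.any()

    def test_duplicated_predictor_collinearity_error(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.standard_normal(10),
                      index=[f"p{i}" for i in range(10)])
        cov = pd.DataFrame({"dup": x})
        conns = _toy_connectomes(rng.uniform(0.2, 0.8, 10))
        with pytest.raises(ValueError, match="collinear"):
            edge_glm(conns, x, cov)

    def test_missing_participant_rejected(self):
        x = pd.Series(np.arange(9.0), index=[f"p{i}" for i in range(9)])
        conns = _toy_connectomes(np.arange(8) / 10 + 0.1)
        with pytest.raises(ValueError, match="without connectomes"):
            edge_glm(conns, x)


class TestThresholdComponents:
    def test_hand_graph_two_components(self):
        t = np.zeros((7, 7))
        for a, b in [(1, 2), (2, 3), (5, 6)]:
            t[a, b] = t[b, a] = 4.0
        comps = threshold_components(_statmap_from(t), 3.2)
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].edges == [(1, 2), (2, 3)]
        assert comps[1].edges == [(5, 6)]

    def test_empty_when_nothing_supra(self):
        comps = threshold_components(_statmap_from(np.ones((5, 5))), 3.2)
        assert comps == []

    def test_negative_direction(self):
        t = np.zeros((4, 4))
        t[0, 1] = t[1, 0] = -5.0
        comps = threshold_components(_statmap_from(t), 3.2, "negative")
        assert [c.edges for c in comps] == [[(0, 1)]]
        assert threshold_components(_statmap_from(t), 3.2, "positive") == []

    def test_matches_union_find_oracle_on_random_graphs(self):
        """Partition equality against brute-force union-find on 100
        random 20-node supra-threshold graphs."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            t = np.zeros((20, 20))
            iu = np.triu_indices(20, 1)
            supra = rng.random(iu[0].size) < 0.08
            t[iu[0][supra], iu[1][supra]] = 5.0
            t = t + t.T
            comps = threshold_components(_statmap_from(t), 3.2)
            oracle = union_find_components(
                list(zip(iu[0][supra], iu[1][supra])))
            assert [c.edges for c in comps] == [
                [(int(a), int(b)) for a, b in es] for es in oracle]

    def test_supra_sets_nested_in_threshold(self):
        rng = np.random.default_rng(8)
        t = rng.standard_normal((15, 15)) * 2
        t = np.triu(t, 1) + np.triu(t, 1).T
        sm = _statmap_from(t)
        e1 = {e for c in threshold_components(sm, 2.0) for e in c.edges}
        e2 = {e for c in threshold_components(sm, 3.0) for e in c.edges}
        assert e2 <= e1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_components(_statmap_from(np.zeros((3, 3))), -1.0)


class TestNbs:
    def _planted(self, seed):
        from axonet import CohortConfig, generate_cohort, \
            generate_connectomes
        cohort = generate_cohort(CohortConfig(seed=seed))
        conns = generate_connectomes(
            cohort, n_nodes=20,
            planted_components=[[(0, 1), (1, 2), (2, 3)]],
            edge_effect=0.025, seed=seed + 1)
        an = cohort[cohort["group"] == "AN"].set_index("id")
        mats = {p: conns[p]["FA"] for p in an.index}
        return mats, an

    def test_reproducible_p_values_within_bounds(self):
        mats, an = self._planted(21)
        a = nbs_test(mats, an["log_nfl"], an[["age", "motion"]],
                     n_perm=200, seed=5)
        b = nbs_test(mats, an["log_nfl"], an[["age", "motion"]],
                     n_perm=200, seed=5)
        assert [c.fwe_p for c in a.components] == \
            [c.fwe_p for c in b.components]
        for c in a.components:
            assert 1 / 201 <= c.fwe_p <= 1.0
        np.testing.assert_array_equal(a.null_max_size, b.null_max_size)

    def test_planted_component_detected(self):
        mats, an = self._planted(22)
        res = nbs_test(mats, an["log_nfl"], an[["age", "motion"]],
                       n_perm=500, seed=6)
        assert res.significant
        edges = {e for c in res.significant for e in c.edges}
        assert {(0, 1), (1, 2), (2, 3)} <= edges

    def test_constant_predictor_warns_no_components(self, caplog):
        mats, an = self._planted(23)
        const = pd.Series(1.0, index=an.index)
        with caplog.at_level("WARNING", logger="axonet.nbs"):
            res = nbs_test(mats, const, n_perm=100, seed=1)
        assert "zero variance" in caplog.text
        assert res.components == []

    def test_n_perm_guard(self):
        mats, an = self._planted(24)
        with pytest.raises(ValueError, match="n_perm"):
            nbs_test(mats, an["log_nfl"], n_perm=50)

    def test_node_relabeling_permutes_components(self):
        mats, an = self._planted(25)
        perm = np.random.default_rng(0).permutation(20)
        inv = np.argsort(perm)
        mats_perm = {p: ConnectivityMatrix(m.values[np.ix_(perm, perm)],
                                           "FA")
                     for p, m in mats.items()}
        r1 = NBS(mats, an["log_nfl"]).statmap
        r2 = NBS(mats_perm, an["log_nfl"]).statmap
        c1 = threshold_components(r1, 3.2)
        c2 = threshold_components(r2, 3.2)
        # edge (a, b) of the permuted matrices is (perm[a], perm[b])
        # in the original indexing
        mapped = sorted(
            sorted(tuple(sorted((int(perm[a]), int(perm[b]))))
                   for a, b in c.edges) for c in c2)
        orig = sorted(sorted((int(a), int(b)) for a, b in c.edges)
                      for c in c1)
        assert mapped == orig

    def test_freedman_lane_option_runs(self):
        mats, an = self._planted(26)
        res = NBS(mats, an["log_nfl"], an[["age"]],
                  permute="freedman_lane").fit(3.2, 100, seed=2)
        for c in res.components:
            assert 0 < c.fwe_p <= 1


class TestThresholdSweep:
    def test_single_threshold_matches_fit(self):
        from tests_helpers import planted_setup
        mats, an = planted_setup(31)
        model = NBS(mats, an["log_nfl"], an[["age", "motion"]])
        res = model.fit(3.2, 200, seed=9)
        sweep = model.threshold_sweep([3.2], n_perm=200, seed=9)
        assert sweep.loc[0, "n_significant"] == len(res.significant)
        assert sweep.loc[0, "largest_component"] == \
            (res.components[0].size if res.components else 0)

    def test_largest_component_monotone_in_threshold(self):
        from tests_helpers import planted_setup
        mats, an = planted_setup(32)
        sweep = threshold_sweep(mats, an["log_nfl"],
                                an[["age", "motion"]],
                                thresholds=[2.0, 3.2, 4.0], n_perm=100,
                                seed=3)
        sizes = sweep["largest_component"].to_numpy()
        assert (np.diff(sizes) <= 0).all()

    def test_non_increasing_thresholds_rejected(self):
        from tests_helpers import planted_setup
        mats, an = planted_setup(33)
        with pytest.raises(ValueError, match="increasing"):
            threshold_sweep(mats, an["log_nfl"], thresholds=[3.0, 2.0],
                            n_perm=100)
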