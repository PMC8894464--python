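"""Cross-system statistics: RDA, permutation tests, stepwise regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ccmnet import (
    ValidationError,
    assemble_cross_system_table,
    correlate_with_environment,
    paired_permutation_test,
    rank_group_compare,
    rda,
    rda_permutation_test,
    stepwise_regression,
)
from ccmnet.network import CausalLink, SiteNetwork
from ccmnet.cross_system import PREDICTOR_COLUMNS


def synthetic_networks(n_sites=6, seed=0):
    rng = np.random.default_rng(seed)
    variables = ("richness", "biomass", "no3", "po4", "temperature")
    nets = []
    for i in range(n_sites):
        links = {}
        for c, e in itertools.permutations(variables, 2):
            ls = rng.uniform(0.05, 1.0)
            links[(c, e)] = CausalLink(c, e, LS=ls, significant=bool(rng.random() < 0.5))
        from ccmnet import standardize_network

        net = SiteNetwork(site=f"s{i}", variables=variables, links=links,
                          exogenous=frozenset({"temperature"}))
        nets.append(standardize_network(net))
    return nets


def synthetic_metadata(sites, seed=1):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "depth": 10 ** rng.uniform(0.5, 2, len(sites)),
            "area": 10 ** rng.uniform(0, 3, len(sites)),
            "mean_richness": rng.uniform(5, 50, len(sites)),
            "mean_temperature": rng.uniform(5, 25, len(sites)),
            "mean_po4": 10 ** rng.uniform(-2, 0, len(sites)),
            "mean_no3": 10 ** rng.uniform(-1, 1, len(sites)),
            "mean_biomass": 10 ** rng.uniform(-1, 1.5, len(sites)),
        },
        index=sites,
    )


class TestAssemble:
    def test_blocks_and_standardization(self):
        nets = synthetic_networks()
        meta = synthetic_metadata([n.site for n in nets])
        table = assemble_cross_system_table(nets, meta)
        assert table.block("links_to_biomass").shape == (6, 4)
        assert table.block("links_to_richness").shape == (6, 4)
        assert table.block("pairwise_loops").shape == (6, 6)
        assert table.block("triangular_loops").shape == (6, 4)
        for c in table.predictors.columns:
            assert table.predictors[c].mean() == pytest.approx(0, abs=1e-12)
            assert table.predictors[c].std(ddof=1) == pytest.approx(1)

    def test_site_with_missing_metadata_dropped(self):
        nets = synthetic_networks()
        meta = synthetic_metadata([n.site for n in nets])
        meta.loc["s2", "depth"] = np.nan
        table = assemble_cross_system_table(nets, meta)
        assert "s2" not in table.sites
        assert len(table.sites) == 5

    def test_too_few_sites_rejected(self):
        nets = synthetic_networks(2)
        meta = synthetic_metadata([n.site for n in nets])
        with pytest.raises(ValidationError):
            assemble_cross_system_table(nets, meta)


class TestRDA:
    def test_perfect_linear_response_fully_explained(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        B = rng.normal(size=(3, 4))
        Y = X @ B
        result = rda(pd.DataFrame(Y), pd.DataFrame(X, columns=list("abc")))
        assert result.explained_variance == pytest.approx(1.0, abs=1e-9)

    def test_univariate_rda_equals_regression_r2(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=25)
        result = rda(y, pd.DataFrame(X))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        r2 = sm.OLS(y - y.mean(), sm.add_constant(Xs)).fit().rsquared
        assert result.explained_variance == pytest.approx(r2, abs=1e-9)

    def test_null_explained_variance_near_baseline(self):
        # independent responses: E[R^2] ~ p/(n-1) per response dimension
        rng = np.random.default_rng(4)
        evs = []
        for _ in range(20):
            X = rng.normal(size=(40, 3))
            Y = rng.normal(size=(40, 5))
            evs.append(rda(Y, X).explained_variance)
        assert abs(np.mean(evs) - 3 / 39) < 0.03

    def test_collinear_predictor_dropped(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 2))
        X3 = np.column_stack([X, X[:, 0] + X[:, 1]])
        Y = rng.normal(size=(15, 2))
        result = rda(Y, X3)
        assert len(result.predictor_names) == 2

    def test_permutation_p_minimum_for_perfect_fit(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 2))
        Y = X @ rng.normal(size=(2, 3))
        _, p = rda_permutation_test(Y, X, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_permutation_null_uniformish(self):
        rng = np.random.default_rng(7)
        hits = 0
        for seed in range(20):
            X = rng.normal(size=(20, 2))
            Y = rng.normal(size=(20, 3))
            _, p = rda_permutation_test(Y, X, n_perm=199, seed=seed)
            hits += p <= 0.05
        assert hits <= 3

    def test_permutation_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 2))
        Y = rng.normal(size=(12, 2))
        _, p1 = rda_permutation_test(Y, X, n_perm=299, seed=5)
        _, p2 = rda_permutation_test(Y, X, n_perm=299, seed=5)
        assert p1 == p2


class TestPairedPermutation:
    def test_identical_samples_give_p_one(self):
        a = np.arange(10.0)
        _, p = paired_permutation_test(a, a, n_perm=999, seed=0)
        assert p == 1.0

    def test_agrees_with_exact_enumeration(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.4, 1, 10)
        b = rng.normal(0.0, 1, 10)
        d = a - b
        obs = d.mean()
        # brute force over all 2^10 sign patterns
        count = 0
        n = len(d)
        for bits in range(2**n):
            signs = np.array([1.0 if bits >> i & 1 else -1.0 for i in range(n)])
            if abs((signs * d).mean()) >= abs(obs) - 1e-15:
                count += 1
        exact = count / 2**n
        _, p = paired_permutation_test(a, b, n_perm=20000, seed=1)
        assert p == pytest.approx(exact, abs=0.02)

    def test_all_positive_differences_small_p(self):
        a = np.full(19, 1.0)
        b = np.zeros(19)
        _, p = paired_permutation_test(a, b, n_perm=20000, seed=2)
        assert p < 0.001

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=12), rng.normal(size=12)
        _, p1 = paired_permutation_test(a, b, n_perm=999, seed=3)
        _, p2 = paired_permutation_test(b, a, n_perm=999, seed=3)
        assert p1 == p2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_permutation_test(np.ones(5), np.ones(6))


class TestStepwise:
    def test_recovers_single_true_predictor(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        y = 2.0 * x1 + rng.normal(0, 1e-6, 30)
        res = stepwise_regression(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert res.selected == ("x1",)
        # coefficient on the standardized scale: 2 * sd(x1)
        assert res.coefficients["x1"] == pytest.approx(2.0 * x1.std(ddof=1), rel=1e-3)

    def test_f_degrees_of_freedom_structure(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(19, 3)), columns=["a", "b", "c"])
        y = X @ [1.0, -1.0, 0.5] + rng.normal(0, 0.1, 19)
        res = stepwise_regression(y.to_numpy(), X)
        assert res.selected == ("a", "b", "c") or set(res.selected) == {"a", "b", "c"}
        assert res.df == (3, 15)

    def test_pure_noise_rarely_selects(self):
        rng = np.random.default_rng(13)
        empty = 0
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(19, 4)), columns=list("abcd"))
            y = rng.normal(size=19)
            if stepwise_regression(y, X).selected == ():
                empty += 1
        assert empty >= 12  # AIC keeps a spurious term occasionally


class TestKruskalWallis:
    def test_hand_computed_two_groups(self):
        h, p = rank_group_compare([(1, 2, 3), (10, 11, 12)])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups(self):
        h, p = rank_group_compare([(1.0, 2, 3), (1.0, 2, 3), (1.0, 2, 3)])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_within_group_permutation_invariance(self):
        h1, _ = rank_group_compare([(3, 1, 2), (12, 10, 11)])
        h2, _ = rank_group_compare([(1, 2, 3), (10, 11, 12)])
        assert h1 == pytest.approx(h2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            rank_group_compare([(1.0,), (2.0, 3.0)])


class TestCorrelation:
    def test_perfect_correlation_minimum_p(self):
        x = np.arange(12.0)
        r, p = correlate_with_environment(x, x, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_affine_invariance(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r1, _ = correlate_with_environment(x, y, n_perm=99, seed=1)
        r2, _ = correlate_with_environment(3 * x + 1, 0.5 * y - 2, n_perm=99, seed=1)
        assert r1 == pytest.approx(r2)

    def test_null_type_one_rate(self):
        rng = np.random.default_rng(15)
        hits = 0
        for seed in range(20):
            x, y = rng.normal(size=19), rng.normal(size=19)
            _, p = correlate_with_environment(x, y, n_perm=499, seed=seed)
            hits += p <= 0.05
        assert hits / 20 < 0.15

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            correlate_with_environment(np.ones(6), np.arange(6.0))
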