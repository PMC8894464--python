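"""Network assembly, SLS standardization, loop weights, recovery scoring."""

import numpy as np
import pytest

from ccmnet import (
    GroundTruthNetwork,
    ValidationError,
    all_pairwise_loops,
    directional_bias,
    pairwise_loop,
    recovery_metrics,
    standardize_network,
    triangular_loops,
)
from ccmnet.network import CausalLink, SiteNetwork

VARS = ("richness", "biomass", "no3", "po4", "temperature")


def make_network(ls_by_edge, significant=(), variables=VARS, exogenous=("temperature",),
                 default_ls=0.1):
    links = {}
    for cause in variables:
        for effect in variables:
            if cause == effect:
                continue
            ls = ls_by_edge.get((cause, effect), default_ls)
            links[(cause, effect)] = CausalLink(
                cause=cause, effect=effect, LS=ls,
                significant=(cause, effect) in significant,
            )
    return SiteNetwork(site="s", variables=variables, links=links,
                       exogenous=frozenset(exogenous))


class TestStandardize:
    def test_spec_ratios(self):
        net = make_network({("richness", "biomass"): 0.8,
                            ("biomass", "richness"): 0.4,
                            ("no3", "biomass"): 0.2})
        std = standardize_network(net)
        assert std.link("richness", "biomass").SLS == pytest.approx(1.0)
        assert std.link("biomass", "richness").SLS == pytest.approx(0.5)
        assert std.link("no3", "biomass").SLS == pytest.approx(0.25)

    def test_max_sls_is_one(self):
        std = standardize_network(make_network({("no3", "po4"): 0.77}))
        assert max(l.SLS for l in std.links.values()) == pytest.approx(1.0)

    def test_idempotent(self):
        std1 = standardize_network(make_network({("no3", "po4"): 0.5}))
        std2 = standardize_network(std1)
        for key in std1.links:
            assert std1.links[key].SLS == pytest.approx(std2.links[key].SLS)

    def test_all_zero_rejected(self):
        net = make_network({}, variables=("a", "b"), exogenous=())
        for l in net.links.values():
            l.LS = 0.0
        with pytest.raises(ValidationError):
            standardize_network(net)

    def test_scale_invariance_of_sls_and_loops(self):
        ls = {("richness", "biomass"): 0.8, ("biomass", "richness"): 0.3,
              ("biomass", "no3"): 0.5, ("no3", "richness"): 0.4}
        net1 = standardize_network(make_network(ls))
        net2 = standardize_network(
            make_network({k: 3.0 * v for k, v in ls.items()}, default_ls=0.3)
        )
        # scaling every LS by c > 0 leaves SLS and loop weights unchanged
        # (LS values are capped at 1 in practice; the algebra holds regardless)
        for key in net1.links:
            assert net1.links[key].SLS == pytest.approx(net2.links[key].SLS)
        t1, t2 = triangular_loops(net1), triangular_loops(net2)
        for name in t1:
            assert t1[name].loop_weight == pytest.approx(t2[name].loop_weight)


class TestLoops:
    def test_pairwise_sqrt_identity(self):
        net = standardize_network(
            make_network({("richness", "biomass"): 0.9, ("biomass", "richness"): 0.4,
                          ("no3", "po4"): 1.0})
        )
        loop = pairwise_loop(net, "richness", "biomass")
        assert loop.loop_weight == pytest.approx(np.sqrt(0.9 * 0.4))

    def test_annihilation_and_identity(self):
        net = standardize_network(
            make_network({("richness", "biomass"): 0.0, ("biomass", "richness"): 0.6,
                          ("no3", "po4"): 1.0})
        )
        assert pairwise_loop(net, "richness", "biomass").loop_weight == 0.0
        sym = standardize_network(
            make_network({("richness", "biomass"): 0.6, ("biomass", "richness"): 0.6,
                          ("no3", "po4"): 1.0})
        )
        assert pairwise_loop(sym, "richness", "biomass").loop_weight == pytest.approx(0.6)

    def test_triangular_cube_root_identity(self):
        net = standardize_network(
            make_network({("richness", "biomass"): 1.0, ("biomass", "no3"): 1.0,
                          ("no3", "richness"): 0.125})
        )
        assert triangular_loops(net)["I-N"].loop_weight == pytest.approx(0.5)

    def test_equal_members_identity(self):
        net = standardize_network(
            make_network({("richness", "biomass"): 0.8, ("biomass", "no3"): 0.8,
                          ("no3", "richness"): 0.8, ("po4", "no3"): 1.0})
        )
        assert triangular_loops(net)["I-N"].loop_weight == pytest.approx(0.8)

    def test_geometric_mean_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ls = {("richness", "biomass"): rng.uniform(0.05, 1),
                  ("biomass", "no3"): rng.uniform(0.05, 1),
                  ("no3", "richness"): rng.uniform(0.05, 1)}
            net = standardize_network(make_network(ls))
            for loop in triangular_loops(net).values():
                members = [l.SLS for l in loop.links]
                assert min(members) <= loop.loop_weight <= max(members) + 1e-12

    def test_temperature_never_in_loops(self):
        net = standardize_network(make_network({("no3", "po4"): 1.0}))
        for loop in triangular_loops(net).values():
            assert all("temperature" not in (l.cause, l.effect) for l in loop.links)
        for (a, b) in all_pairwise_loops(net):
            assert "temperature" not in (a, b)

    def test_unstandardized_network_rejected(self):
        with pytest.raises(ValidationError):
            triangular_loops(make_network({}))

    def test_missing_variable_rejected(self):
        net = standardize_network(
            make_network({("a", "b"): 1.0}, variables=("a", "b"), exogenous=())
        )
        with pytest.raises(ValidationError):
            triangular_loops(net)

    def test_loop_significance_requires_all_members(self):
        sig = {("richness", "biomass"), ("biomass", "no3")}
        net = standardize_network(
            make_network({("richness", "biomass"): 0.9, ("biomass", "no3"): 0.9,
                          ("no3", "richness"): 0.9}, significant=sig)
        )
        assert not triangular_loops(net)["I-N"].significant
        sig.add(("no3", "richness"))
        net = standardize_network(
            make_network({("richness", "biomass"): 0.9, ("biomass", "no3"): 0.9,
                          ("no3", "richness"): 0.9}, significant=sig)
        )
        assert triangular_loops(net)["I-N"].significant


class TestDirectionalBias:
    def test_subtraction_and_antisymmetry(self):
        net = standardize_network(
            make_network({("richness", "biomass"): 1.0, ("biomass", "richness"): 0.4})
        )
        assert directional_bias(net, "richness", "biomass") == pytest.approx(0.6)
        assert directional_bias(net, "biomass", "richness") == pytest.approx(-0.6)

    def test_symmetric_gives_zero(self):
        net = standardize_network(
            make_network({("richness", "biomass"): 0.5, ("biomass", "richness"): 0.5,
                          ("no3", "po4"): 1.0})
        )
        assert directional_bias(net, "richness", "biomass") == pytest.approx(0.0)


class TestRecovery:
    def test_perfect_detection(self):
        truth = GroundTruthNetwork(frozenset({("richness", "biomass")}))
        net = standardize_network(
            make_network({("richness", "biomass"): 1.0},
                         significant={("richness", "biomass")})
        )
        assert recovery_metrics(net, truth) == (1.0, 1.0)

    def test_no_predictions_convention(self):
        truth = GroundTruthNetwork(frozenset({("richness", "biomass")}))
        net = standardize_network(make_network({("richness", "biomass"): 1.0}))
        precision, recall = recovery_metrics(net, truth)
        assert precision == 1.0 and recall == 0.0

    def test_false_positive_with_empty_truth(self):
        truth = GroundTruthNetwork(frozenset())
        net = standardize_network(
            make_network({("richness", "biomass"): 1.0},
                         significant={("richness", "biomass")})
        )
        precision, recall = recovery_metrics(net, truth)
        assert precision == 0.0 and recall == 1.0

    def test_links_into_exogenous_excluded(self):
        truth = GroundTruthNetwork(frozenset({("richness", "biomass")}))
        net = standardize_network(
            make_network({("richness", "biomass"): 1.0},
                         significant={("richness", "biomass"),
                                      ("biomass", "temperature")})
        )
        precision, recall = recovery_metrics(net, truth)
        assert precision == 1.0 and recall == 1.0


def test_label_permutation_equivariance():
    ls = {("richness", "biomass"): 0.9, ("biomass", "richness"): 0.3,
          ("no3", "biomass"): 0.6}
    net = standardize_network(make_network(ls))
    swapped = {("biomass", "richness"): 0.9, ("richness", "biomass"): 0.3,
               ("no3", "richness"): 0.6}
    net2 = standardize_network(make_network(swapped))
    assert net.link("richness", "biomass").SLS == pytest.approx(
        net2.link("biomass", "richness").SLS
    )
    assert net.link("no3", "biomass").SLS == pytest.approx(
        net2.link("no3", "richness").SLS
    )
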