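"""Mechanism chains: logical-consistency CPT rules, report grading,
the evidence ceiling, shared links."""

import itertools

import numpy as np
import pytest

from esynth.causal import MECH, CausalLayerConfig, build_causal_layer
from esynth.inference import brute_force_posterior, posterior
from esynth.mechanism import (
    GRADE_LIKELIHOODS,
    LinkSpec,
    MechanismSpec,
    MechReport,
    attach_mech_report,
    build_mechanism_subnet,
    chain_cpts,
)
from esynth.network import NetworkError, validate_network


def m1_spec():
    return MechanismSpec(
        id="M1",
        p_given_m=0.7,
        links=(LinkSpec("mu11", 1.0), LinkSpec("mu12", 0.5), LinkSpec("mu13", 0.5)),
    )


def m2_spec():
    return MechanismSpec(
        id="M2",
        p_given_m=0.8,
        links=(LinkSpec("mu21", 0.01), LinkSpec("mu22", 0.5)),
    )


class TestChainCpts:
    def test_two_link_chain_rows(self):
        cpts = {c.child: c for c in chain_cpts(m2_spec())}
        mu21, mu22 = cpts["mu21"], cpts["mu22"]
        assert mu21.row((True,)) == (0.0, 1.0)  # mechanism entails its link
        assert mu21.row((False,)) == pytest.approx((0.99, 0.01))  # elicited background
        assert mu22.row((True, True)) == (0.0, 1.0)
        assert mu22.row((True, False)) == (0.0, 1.0)
        assert mu22.row((False, True)) == (1.0, 0.0)  # inconsistency: all links true => M2
        assert mu22.row((False, False)) == (0.5, 0.5)  # indifference

    def test_three_link_chain_rows(self):
        cpts = {c.child: c for c in chain_cpts(m1_spec())}
        assert cpts["mu11"].row((False,)) == (0.0, 1.0)  # established biochemistry
        # intermediate link: background everywhere under ~M1
        assert cpts["mu12"].row((False, True)) == (0.5, 0.5)
        assert cpts["mu12"].row((False, False)) == (0.5, 0.5)
        # final link: zero only on the all-true prefix
        assert cpts["mu13"].row((False, True, True)) == (1.0, 0.0)
        for prefix in [(True, False), (False, True), (False, False)]:
            assert cpts["mu13"].row((False,) + prefix) == (0.5, 0.5)
        # and 1 whenever M1 holds
        for prefix in itertools.product((True, False), repeat=2):
            assert cpts["mu13"].row((True,) + prefix) == (0.0, 1.0)

    def test_single_link_zero_background_is_perfect_proxy(self):
        spec = MechanismSpec(id="Mx", p_given_m=0.5, links=(LinkSpec("mu", 0.0),))
        (cpt,) = chain_cpts(spec)
        assert cpt.row((True,)) == (0.0, 1.0)
        assert cpt.row((False,)) == (1.0, 0.0)


class TestBuildSubnet:
    def test_case_study_subnet_validates(self):
        net = build_causal_layer(CausalLayerConfig())
        before = len(net.variables)
        net = build_mechanism_subnet(net, [m1_spec(), m2_spec()])
        assert len(net.variables) == before + 2 + 5  # two mechanisms, five links
        assert validate_network(net) == []

    def test_no_specs_is_identity(self):
        net = build_causal_layer(CausalLayerConfig())
        assert build_mechanism_subnet(net, []) is net

    def test_requires_mechanism_node(self):
        from esynth.network import CausalNetwork

        with pytest.raises(NetworkError, match="causal layer"):
            build_mechanism_subnet(CausalNetwork(), [m1_spec()])

    def test_chain_true_event_has_positive_probability_without_mechanism(self):
        # under ~M1 the all-links-true world is reachable only through
        # background paths that falsify the final-link rule; the joint
        # (all links true, ~M1) must be exactly zero, while each proper
        # prefix retains positive probability — by exhaustive enumeration
        net = build_causal_layer(CausalLayerConfig())
        net = build_mechanism_subnet(net, [m1_spec()])
        p_all = brute_force_posterior(
            net, "M1", {"mu11": True, "mu12": True, "mu13": True}
        )
        assert p_all == pytest.approx(1.0, abs=1e-12)  # full chain certifies M1
        p_prefix = brute_force_posterior(net, "M1", {"mu11": True, "mu12": True})
        assert p_prefix < 1.0

    def test_shared_link_any_parent_mechanism_forces_link(self):
        owner = MechanismSpec(id="Ma", p_given_m=0.6, links=(LinkSpec("mu_shared", 0.3),))
        sharer = MechanismSpec(
            id="Mb", p_given_m=0.5, links=(LinkSpec("mu_b", 0.5),), shared_links=("mu_shared",)
        )
        net = build_causal_layer(CausalLayerConfig())
        net = build_mechanism_subnet(net, [owner, sharer])
        assert validate_network(net) == []
        cpt = net.cpts["mu_shared"]
        assert set(cpt.parents) == {"Ma", "Mb"}
        # enumeration oracle on the full network
        assert posterior(net, "mu_shared", {"Mb": True}) == pytest.approx(1.0, abs=1e-12)
        assert posterior(net, "mu_shared", {"Ma": True, "Mb": False}) == pytest.approx(
            brute_force_posterior(net, "mu_shared", {"Ma": True, "Mb": False}), abs=1e-9
        )

    def test_missing_shared_link_rejected(self):
        bad = MechanismSpec(
            id="Mb", p_given_m=0.5, links=(LinkSpec("mu_b", 0.5),), shared_links=("ghost",)
        )
        net = build_causal_layer(CausalLayerConfig())
        with pytest.raises(NetworkError, match="missing link"):
            build_mechanism_subnet(net, [bad])


class TestMechReports:
    def test_grade_likelihood_pairs(self):
        net = build_causal_layer(CausalLayerConfig())
        net = build_mechanism_subnet(net, [m1_spec(), m2_spec()])
        net = attach_mech_report(net, MechReport(id="r1", link="mu12", grade="confident"))
        net = attach_mech_report(net, MechReport(id="r2", link="mu22", grade="cautious"))
        assert net.cpts["Rep[r1]"].row((True,)) == pytest.approx((0.09, 0.91))
        assert net.cpts["Rep[r1]"].row((False,)) == pytest.approx((0.91, 0.09))
        assert net.cpts["Rep[r2]"].row((True,)) == pytest.approx((0.25, 0.75))
        assert net.cpts["Rep[r2]"].row((False,)) == pytest.approx((0.75, 0.25))

    def test_uninformative_custom_pair_rejected(self):
        with pytest.raises(NetworkError, match="custom likelihoods"):
            MechReport(id="r", link="mu", grade="custom", likelihoods=(0.5, 0.5))

    def test_unknown_link_rejected(self):
        net = build_causal_layer(CausalLayerConfig())
        with pytest.raises(NetworkError, match="missing link"):
            attach_mech_report(net, MechReport(id="r", link="ghost"))

    def test_multiple_reports_per_link_allowed(self):
        net = build_causal_layer(CausalLayerConfig())
        net = build_mechanism_subnet(net, [m2_spec()])
        net = attach_mech_report(net, MechReport(id="a", link="mu21"))
        net = attach_mech_report(net, MechReport(id="b", link="mu21"))
        assert validate_network(net) == []

    def test_positive_confident_report_never_decreases_hypothesis(self):
        net = build_causal_layer(CausalLayerConfig(prior_c=0.01))
        net = build_mechanism_subnet(net, [m1_spec()])
        net = attach_mech_report(net, MechReport(id="r", link="mu12", grade="confident"))
        assert posterior(net, evidence={"Rep[r]": True}) >= posterior(net) - 1e-15


def random_mechanism_spec(rng: np.random.Generator, tag: int) -> MechanismSpec:
    n_links = int(rng.integers(1, 4))
    links = tuple(
        LinkSpec(f"mu{tag}_{k}", background=float(rng.choice([0.01, 0.3, 0.5, 1.0])))
        for k in range(n_links)
    )
    reports = tuple(
        MechReport(
            id=f"r{tag}_{k}",
            link=links[int(rng.integers(n_links))].id,
            grade=str(rng.choice(["confident", "cautious"])),
        )
        for k in range(int(rng.integers(1, 3)))
    )
    return MechanismSpec(
        id=f"Mech{tag}",
        p_given_m=float(rng.uniform(0.1, 0.95)),
        links=links,
        reports=reports,
    )


def test_mechanism_evidence_odds_ceiling_randomized():
    """Posterior odds from mechanism evidence alone never exceed
    prior odds divided by P(M | no causation).

    Mechanistic reports reach the hypothesis only through the existential
    node M; since P(reports | C) = P(reports | M) and
    P(reports | ~C) >= P(M|~C) P(reports | M), the Bayes factor is capped
    at 1 / P(M|~C).
    """
    rng = np.random.default_rng(42)
    for trial in range(200):
        prior = float(rng.uniform(0.001, 0.5))
        m_given_not_c = float(rng.uniform(0.2, 0.9))
        net = build_causal_layer(CausalLayerConfig(prior_c=prior, m_given_not_c=m_given_not_c))
        specs = [random_mechanism_spec(rng, j) for j in range(int(rng.integers(1, 3)))]
        net = build_mechanism_subnet(net, specs)  # attaches spec reports too
        evidence = {rep.report_node: True for spec in specs for rep in spec.reports}
        post = posterior(net, evidence=evidence)
        prior_odds = prior / (1 - prior)
        post_odds = post / (1 - post)
        assert post_odds <= prior_odds / m_given_not_c + 1e-9, (
            f"trial {trial}: ceiling violated (prior {prior}, P(M|~C) {m_given_not_c})"
        )
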