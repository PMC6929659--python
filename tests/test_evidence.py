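"""Report likelihood formulas, design targeting rules, hierarchical
modulator uncertainty, shared sponsorship-bias variables."""

import itertools

import pytest

from esynth.causal import DELTA, DR, PD, ROG, TIME, CausalLayerConfig, build_causal_layer
from esynth.evidence import (
    CptOverride,
    ModulatorBelief,
    ModulatorVector,
    StudyDesign,
    StudyRecord,
    allowed_targets,
    attach_study,
    marginalize_uncertain_modulator,
    negative_report_probability,
    positive_report_probability,
    report_cpt,
    shared_bias_variable,
)
from esynth.inference import brute_force_posterior, posterior
from esynth.network import NetworkError, validate_network

GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


class TestReportFormulas:
    @pytest.mark.parametrize(
        "mods, tracking, expected",
        [
            # perfect cohort study, no bias: certainty of a positive report
            (dict(A=1, SS=1, D=1, SB=0), ("A", "SS", "D"), 1.0),
            # sponsor-funded with middling tracking: 0.675, i.e. P(ES=0)=13/40
            (dict(A=0.5, SS=0.5, D=0.5, SB=1), ("A", "SS", "D"), 0.675),
            # uninformative study still reports positives half the time
            (dict(A=0, SS=0, D=0, SB=0), ("A", "SS", "D"), 0.5),
        ],
    )
    def test_positive_formula(self, mods, tracking, expected):
        m = ModulatorVector(**mods)
        assert positive_report_probability(m, tracking) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "mods, tracking, expected",
        [
            # sponsor-funded RCT: false-positive rate 0.09, so P(ES=0|no signal)=0.91
            (dict(A=0.5, SS=1, B=1, R=1, Pl=0.5, SB=1), ("A", "SS", "B", "R", "Pl"), 0.09),
            # perfect tracking: no false positives at all
            (dict(A=1, SS=1, SB=0), ("A", "SS"), 0.0),
            # worst study: coin-flip false positives
            (dict(A=0, SS=0, SB=0), ("A", "SS"), 0.5),
        ],
    )
    def test_negative_formula(self, mods, tracking, expected):
        m = ModulatorVector(**mods)
        assert negative_report_probability(m, tracking) == pytest.approx(expected, abs=1e-15)

    def test_duration_rejected_under_the_null(self):
        with pytest.raises(NetworkError, match="duration"):
            negative_report_probability(ModulatorVector(), ("A", "SS", "D"))

    def test_empty_tracking_rejected(self):
        with pytest.raises(NetworkError):
            positive_report_probability(ModulatorVector(), ())

    def test_attenuation_monotonicity_on_grid(self):
        # positive formula: non-decreasing in tracking, non-increasing in SB;
        # negative formula: non-increasing in both
        for a, ss, sb in itertools.product(GRID, GRID, GRID):
            m = ModulatorVector(A=a, SS=ss, SB=sb)
            for d in GRID:
                if d >= 0.25:
                    lower = ModulatorVector(A=a, SS=ss, D=d - 0.25, SB=sb)
                    higher = ModulatorVector(A=a, SS=ss, D=d, SB=sb)
                    assert positive_report_probability(higher, ("A", "SS", "D")) >= (
                        positive_report_probability(lower, ("A", "SS", "D"))
                    )
            if sb >= 0.25:
                less_biased = ModulatorVector(A=a, SS=ss, SB=sb - 0.25)
                assert positive_report_probability(m, ("A", "SS")) <= (
                    positive_report_probability(less_biased, ("A", "SS"))
                )
                assert negative_report_probability(m, ("A", "SS")) <= (
                    negative_report_probability(less_biased, ("A", "SS"))
                )
            if a >= 0.25:
                worse = ModulatorVector(A=a - 0.25, SS=ss, SB=sb)
                assert negative_report_probability(m, ("A", "SS")) <= (
                    negative_report_probability(worse, ("A", "SS"))
                )

    def test_corner_scenarios_shift_as_published_tendencies(self):
        # four corners: (tracking, SB) from (good, none) to (poor, biased);
        # "good" stays below 1 so the false-positive rate is not already 0
        good, poor = 0.75, 0.25
        scenarios = {
            "a": ModulatorVector(A=good, SS=good, D=good, SB=0.0),
            "b": ModulatorVector(A=good, SS=good, D=good, SB=1.0),
            "c": ModulatorVector(A=poor, SS=poor, D=poor, SB=0.0),
            "d": ModulatorVector(A=poor, SS=poor, D=poor, SB=1.0),
        }
        pos = {k: positive_report_probability(m, ("A", "SS", "D")) for k, m in scenarios.items()}
        neg = {k: negative_report_probability(m, ("A", "SS")) for k, m in scenarios.items()}
        # P(ES=1 | indicator) strictly decreases towards the worst corner
        assert pos["a"] > pos["b"] > pos["d"] and pos["a"] > pos["c"] > pos["d"]
        # false positives rise with worse tracking but fall with bias
        assert neg["c"] > neg["a"] and neg["d"] > neg["b"]
        assert neg["b"] < neg["a"] and neg["d"] < neg["c"]


class TestTargetingRules:
    def test_design_target_sets(self):
        assert allowed_targets(StudyDesign("case_control")) == {PD, DR, ROG}
        assert allowed_targets(StudyDesign("cohort")) == {PD, DR, ROG, TIME}
        assert DELTA in allowed_targets(StudyDesign("rct"))
        assert allowed_targets(StudyDesign("case_report")) == {TIME}
        assert allowed_targets(StudyDesign("case_report", anecdotal_delta=True)) == {TIME, DELTA}
        assert DR in allowed_targets(StudyDesign("rct", multi_dose=True))
        assert allowed_targets(StudyDesign("basic_science")) == set()

    def test_case_control_cannot_speak_to_difference_making(self):
        with pytest.raises(NetworkError, match="cannot speak"):
            StudyRecord(
                id="s",
                design=StudyDesign("case_control"),
                modulators=ModulatorVector(),
                targets=(DELTA,),
                outcome=1,
            )

    def test_at_most_one_statistical_indicator(self):
        with pytest.raises(NetworkError, match="exactly one statistical indicator"):
            StudyRecord(
                id="s",
                design=StudyDesign("cohort"),
                modulators=ModulatorVector(),
                targets=(PD, DR),
                outcome=1,
            )


def shaheen_study():
    return StudyRecord(
        id="shaheen",
        design=StudyDesign("cohort"),
        modulators=ModulatorVector(A=1, SS=1, D=1, SB=0),
        targets=(DR, TIME),
        outcome=1,
    )


class TestAttachStudy:
    def test_shaheen_cpt_rows(self):
        net = build_causal_layer(CausalLayerConfig())
        net = attach_study(net, shaheen_study())
        cpt = net.cpts["ES[shaheen]"]
        assert cpt.row((True, True)) == (0.0, 1.0)  # both indicators: certain positive
        for combo in [(True, False), (False, True), (False, False)]:
            assert cpt.row(combo) == (1.0, 0.0)  # no false positives at perfect tracking

    def test_override_pins_rows(self):
        study = StudyRecord(
            id="ludwig",
            design=StudyDesign("rct"),
            modulators=ModulatorVector(A=0.5, SS=1, D=0, B=1, R=1, Pl=0.5, SB=1),
            targets=(DELTA,),
            outcome=0,
            cpt_override=CptOverride(p_es0_given_true=0.325, p_es0_given_false=0.91),
        )
        cpt = report_cpt(study)
        assert cpt.row((True,)) == pytest.approx((0.325, 0.675))
        assert cpt.row((False,)) == pytest.approx((0.91, 0.09))

    def test_unknown_target_rejected(self):
        from esynth.network import CausalNetwork

        with pytest.raises(NetworkError, match="unknown indicator"):
            attach_study(CausalNetwork(), shaheen_study())


class TestHierarchicalModulators:
    def test_point_mass_beliefs_collapse_exactly(self):
        study = shaheen_study()
        beliefs = [ModulatorBelief("A", {1.0: 1.0}), ModulatorBelief("SS", {1.0: 1.0})]
        assert marginalize_uncertain_modulator(beliefs, study).table == report_cpt(study).table

    def test_two_point_belief_averages_rows(self):
        study = StudyRecord(
            id="s",
            design=StudyDesign("cohort"),
            modulators=ModulatorVector(A=0.0, SS=1, D=1, SB=0),
            targets=(DR, TIME),
            outcome=1,
        )
        mixed = marginalize_uncertain_modulator([ModulatorBelief("A", {0.0: 0.5, 1.0: 0.5})], study)
        low = report_cpt(study)
        high = report_cpt(study, modulators=study.modulators.with_value("A", 1.0))
        for combo in mixed.table:
            expected = tuple(0.5 * (a + b) for a, b in zip(low.row(combo), high.row(combo)))
            assert mixed.row(combo) == pytest.approx(expected, abs=1e-15)

    def test_belief_must_sum_to_one(self):
        with pytest.raises(NetworkError):
            ModulatorBelief("A", {0.0: 0.4, 1.0: 0.4})


class TestSharedSponsorshipBias:
    def studies(self, n=2):
        return [
            StudyRecord(
                id=f"s{i}",
                design=StudyDesign("cohort"),
                modulators=ModulatorVector(A=1, SS=1, D=1, SB=0),
                targets=(PD, TIME),
                outcome=0,
                sponsor_group="acme",
            )
            for i in range(n)
        ]

    def test_null_reports_raise_bias_suspicion(self):
        # a drug with high prior of harm; two null reports from one sponsor
        net = build_causal_layer(CausalLayerConfig(prior_c=0.9))
        belief = ModulatorBelief("SB", {0.0: 0.9, 1.0: 0.1})
        net = shared_bias_variable(net, "acme", belief, self.studies())
        assert validate_network(net) == []
        evidence = {"ES[s0]": False, "ES[s1]": False}
        post_sb = posterior(net, "SB[acme]", evidence, state=1.0)
        assert post_sb > 0.1  # bias suspicion rises
        # engine agrees with the exhaustive oracle on this small network
        assert post_sb == pytest.approx(
            brute_force_posterior(net, "SB[acme]", evidence, state=1.0), abs=1e-9
        )

    def test_point_mass_equivalent_to_folding(self):
        study = self.studies(1)[0]
        net1 = build_causal_layer(CausalLayerConfig())
        net1 = shared_bias_variable(net1, "acme", ModulatorBelief("SB", {1.0: 1.0}), [study])
        net2 = build_causal_layer(CausalLayerConfig())
        folded = StudyRecord(
            id=study.id,
            design=study.design,
            modulators=study.modulators.with_value("SB", 1.0),
            targets=study.targets,
            outcome=study.outcome,
        )
        net2 = attach_study(net2, folded)
        ev = {"ES[s0]": False}
        assert posterior(net1, evidence=ev) == pytest.approx(posterior(net2, evidence=ev), abs=1e-12)

    def test_empty_group_leaves_network_unchanged(self):
        net = build_causal_layer(CausalLayerConfig())
        out = shared_bias_variable(net, "acme", ModulatorBelief("SB", {0.0: 1.0}), [])
        assert out.variables.keys() == net.variables.keys()

    def test_mismatched_group_rejected(self):
        net = build_causal_layer(CausalLayerConfig())
        stray = self.studies(1)[0]
        with pytest.raises(NetworkError, match="sponsor group"):
            shared_bias_variable(net, "other", ModulatorBelief("SB", {0.0: 1.0}), [stray])
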