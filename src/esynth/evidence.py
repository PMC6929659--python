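"""Study reports: design-based indicator targeting and modulator-driven
report likelihoods.

A study enters the network as a single binary report leaf (effect size
observed, ES = 1, or not, ES = 0) whose parents are the causal indicators
the study can speak to.  The report's conditional probabilities are not
free parameters: they are computed from the study's quality profile — the
evidential modulators adjustment (A), sample size (SS), duration (D),
blinding (B), randomisation (R), placebo (Pl), each scored in [0, 1], and
sponsorship bias (SB).

Two formulas set the whole CPT.  When every targeted indicator holds, the
study tracks a real signal and

    P(ES = 1 | indicators true) = (1 - SB/10) * (0.5 + avg(tracking)/2),

rising from the coin-flip floor 0.5 towards 1 as quality improves.  When
the indicators do not all hold there is no signal to track and a positive
report is a false positive:

    P(ES = 1 | otherwise) = (1 - SB/10) * 0.5 * (1 - avg(tracking')),

falling from 0.5 towards 0 as quality improves.  Duration is excluded
from the second average: however long a study runs, it cannot detect a
signal nature does not send.  Sponsorship bias attenuates the probability
of a positive report under *both* indicator states — funder-aligned
studies tend to hide harms.

Observational designs track the statistical indicators with (A, SS, D);
randomised trials track the causal link itself and additionally use
(B, R, Pl).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Hashable, Mapping, Sequence

from . import causal
from .causal import DELTA, DR, PD, ROG, SIGMA, TIME
from .network import (
    BINARY_STATES,
    CausalNetwork,
    Cpt,
    DiscreteVariable,
    NetworkError,
    add_variable,
    attach_cpt,
)

__all__ = [
    "ModulatorVector",
    "StudyDesign",
    "StudyRecord",
    "ModulatorBelief",
    "CptOverride",
    "allowed_targets",
    "positive_report_probability",
    "negative_report_probability",
    "report_cpt",
    "attach_study",
    "marginalize_uncertain_modulator",
    "shared_bias_variable",
    "POSITIVE_TRACKING",
    "NEGATIVE_TRACKING",
]

STUDY_DESIGNS = ("rct", "cohort", "case_control", "case_series", "case_report", "basic_science")

#: Signal-tracking components averaged in the positive-indicator formula.
POSITIVE_TRACKING = {
    "rct": ("A", "SS", "D", "B", "R", "Pl"),
    "observational": ("A", "SS", "D"),
}
#: Components averaged in the false-positive formula (duration excluded).
NEGATIVE_TRACKING = {
    "rct": ("A", "SS", "B", "R", "Pl"),
    "observational": ("A", "SS"),
}

#: Divisor of the sponsorship-bias attenuation factor (1 - SB/divisor).
SB_DIVISOR = 10.0


@dataclass(frozen=True)
class ModulatorVector:
    """Per-study quality scores, each in [0, 1]."""

    A: float = 0.5  # adjustment / stratification for confounders
    SS: float = 0.5  # sample size score
    D: float = 0.5  # study duration score
    B: float = 0.0  # blinding
    R: float = 0.0  # randomisation
    Pl: float = 0.0  # placebo quality
    SB: float = 0.0  # sponsorship bias

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise NetworkError(f"{name} out of [0,1]: {v!r}")

    def component(self, name: str) -> float:
        return getattr(self, name)

    def with_value(self, name: str, value: float) -> "ModulatorVector":
        return replace(self, **{name: value})


@dataclass(frozen=True)
class CptOverride:
    """Explicitly pinned report conditionals, bypassing the formulas."""

    p_es0_given_true: float
    p_es0_given_false: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise NetworkError(f"{name} out of [0,1]: {v!r}")


@dataclass(frozen=True)
class StudyDesign:
    kind: str
    multi_dose: bool = False  # RCT with graded dose arms can speak to DR/RoG
    anecdotal_delta: bool = False  # case report scored as difference-making
    # (Karch-Lasagna / Naranjo style causality assessment)

    def __post_init__(self) -> None:
        if self.kind not in STUDY_DESIGNS:
            raise NetworkError(f"unknown study design {self.kind!r}; expected one of {STUDY_DESIGNS}")

    @property
    def is_rct(self) -> bool:
        return self.kind == "rct"


@dataclass(frozen=True)
class StudyRecord:
    """One evidence item: a study, its quality profile, and its outcome."""

    id: str
    design: StudyDesign
    modulators: ModulatorVector
    targets: tuple[str, ...]
    outcome: int  # observed ES, 0 or 1
    sponsor_group: str | None = None
    cpt_override: CptOverride | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.targets:
            raise NetworkError(f"study {self.id!r}: targets must be non-empty")
        if len(set(self.targets)) != len(self.targets):
            raise NetworkError(f"study {self.id!r}: duplicate targets")
        sigma_targets = [t for t in self.targets if t in SIGMA]
        if len(sigma_targets) > 1:
            raise NetworkError(
                f"study {self.id!r}: declare exactly one statistical indicator "
                f"(got {sigma_targets!r}); use the strongest supported"
            )
        if DELTA in self.targets and not (self.design.is_rct or self.design.anecdotal_delta):
            raise NetworkError(f"study {self.id!r}: design cannot speak to indicator {DELTA}")
        if self.outcome not in (0, 1):
            raise NetworkError(f"study {self.id!r}: outcome must be 0 or 1")
        allowed = allowed_targets(self.design)
        bad = set(self.targets) - allowed
        if bad:
            raise NetworkError(
                f"study {self.id!r}: design cannot speak to indicator(s) {sorted(bad)!r}"
            )

    @property
    def report_node(self) -> str:
        return f"ES[{self.id}]"


@dataclass(frozen=True)
class ModulatorBelief:
    """Discrete uncertainty over one modulator's value (hierarchical layer)."""

    component: str
    distribution: Mapping[float, float]  # value -> probability

    def __post_init__(self) -> None:
        if self.component not in ModulatorVector.__dataclass_fields__:
            raise NetworkError(f"unknown modulator component {self.component!r}")
        dist = {float(v): float(p) for v, p in self.distribution.items()}
        object.__setattr__(self, "distribution", dist)
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise NetworkError(f"belief over {self.component!r} does not sum to 1")
        for v in dist:
            if not 0.0 <= v <= 1.0:
                raise NetworkError(f"belief support value {v!r} out of [0,1]")

    @property
    def is_point_mass(self) -> bool:
        return any(abs(p - 1.0) <= 1e-12 for p in self.distribution.values())


def allowed_targets(design: StudyDesign) -> set[str]:
    """Indicators a study of this design may report on.

    RCTs speak to difference-making and time course (and to dose-response
    indicators when run with graded dose arms); cohort studies to one
    statistical indicator plus time course; case-control studies to one
    statistical indicator only; anecdotal designs to time course (and to
    difference-making only under an explicit causality-assessment flag).
    Basic-science studies feed the mechanism sub-network, not indicator
    reports.
    """
    kind = design.kind
    if kind == "rct":
        targets = {DELTA, TIME}
        if design.multi_dose:
            targets |= {PD, DR, ROG}
        return targets
    if kind == "cohort":
        return {PD, DR, ROG, TIME}
    if kind == "case_control":
        return {PD, DR, ROG}
    if kind in ("case_series", "case_report"):
        targets = {TIME}
        if design.anecdotal_delta:
            targets.add(DELTA)
        return targets
    return set()  # basic_science: mechanism evidence only


def _avg(m: ModulatorVector, components: Sequence[str]) -> float:
    if not components:
        raise NetworkError("tracking component set must be non-empty")
    return sum(m.component(c) for c in components) / len(components)


def positive_report_probability(m: ModulatorVector, tracking: Sequence[str]) -> float:
    """P(ES = 1 | all targeted indicators true) for quality profile ``m``."""
    p = (1.0 - m.SB / SB_DIVISOR) * (0.5 + _avg(m, tracking) / 2.0)
    return min(1.0, max(0.0, p))


def negative_report_probability(m: ModulatorVector, tracking: Sequence[str]) -> float:
    """P(ES = 1 | targeted indicators not all true): the false-positive rate.

    Duration must not appear in ``tracking``: a longer study cannot detect
    a signal that is not there.
    """
    if "D" in tracking:
        raise NetworkError("duration not a tracking component under the null")
    p = (1.0 - m.SB / SB_DIVISOR) * 0.5 * (1.0 - _avg(m, tracking))
    return min(1.0, max(0.0, p))


def _tracking_sets(design: StudyDesign) -> tuple[tuple[str, ...], tuple[str, ...]]:
    key = "rct" if design.is_rct else "observational"
    return POSITIVE_TRACKING[key], NEGATIVE_TRACKING[key]


def report_cpt(
    study: StudyRecord,
    *,
    modulators: ModulatorVector | None = None,
    extra_parents: tuple[str, ...] = (),
    extra_states: Mapping[str, Sequence[Hashable]] | None = None,
) -> Cpt:
    """Build the report-node CPT for a study.

    The all-indicators-true row uses the positive formula; every other
    parent combination uses the false-positive formula.  ``extra_parents``
    (used for an explicit shared sponsorship-bias node) prepend additional
    parents whose state substitutes the SB component.
    """
    m = modulators if modulators is not None else study.modulators
    pos_track, neg_track = _tracking_sets(study.design)
    parents = study.targets + tuple(extra_parents)
    spaces: list[Sequence[Hashable]] = [BINARY_STATES] * len(study.targets)
    for p in extra_parents:
        spaces.append(tuple((extra_states or {})[p]))
    table: dict[tuple, tuple[float, float]] = {}
    for combo in itertools.product(*spaces):
        ind_states = combo[: len(study.targets)]
        mv = m
        for p_name, p_state in zip(extra_parents, combo[len(study.targets):]):
            mv = mv.with_value("SB", float(p_state))
        if study.cpt_override is not None:
            p1 = (
                1.0 - study.cpt_override.p_es0_given_true
                if all(ind_states)
                else 1.0 - study.cpt_override.p_es0_given_false
            )
        elif all(ind_states):
            p1 = positive_report_probability(mv, pos_track)
        else:
            p1 = negative_report_probability(mv, neg_track)
        table[combo] = (1.0 - p1, p1)
    return Cpt(study.report_node, parents, table)


def attach_study(net: CausalNetwork, study: StudyRecord) -> CausalNetwork:
    """Add the study's report node (with its formula-derived CPT) to ``net``."""
    for t in study.targets:
        if t not in net.variables:
            raise NetworkError(f"study {study.id!r} targets unknown indicator {t!r}")
    net = add_variable(net, DiscreteVariable(study.report_node, BINARY_STATES), "report")
    return attach_cpt(net, report_cpt(study))


def marginalize_uncertain_modulator(
    beliefs: Sequence[ModulatorBelief],
    base: StudyRecord,
) -> Cpt:
    """Report CPT under hierarchical uncertainty about modulator values.

    Each row is the belief-weighted mixture of the deterministic-modulator
    rows over the product of the (independent) belief distributions.  With
    point-mass beliefs this collapses exactly to :func:`report_cpt`.
    """
    names = [b.component for b in beliefs]
    if len(set(names)) != len(names):
        raise NetworkError("multiple beliefs over the same modulator component")
    if base.cpt_override is not None:
        raise NetworkError(f"study {base.id!r} has a pinned CPT; nothing to marginalise")
    supports = [sorted(b.distribution.items()) for b in beliefs]
    mixture: dict[tuple, list[float]] = {}
    for values in itertools.product(*supports):
        weight = 1.0
        m = base.modulators
        for name, (value, prob) in zip(names, values):
            weight *= prob
            m = m.with_value(name, value)
        cpt = report_cpt(base, modulators=m)
        for combo, row in cpt.table.items():
            acc = mixture.setdefault(combo, [0.0] * len(row))
            for i, p in enumerate(row):
                acc[i] += weight * p
    return Cpt(base.report_node, tuple(base.targets), {k: tuple(v) for k, v in mixture.items()})


def shared_bias_variable(
    net: CausalNetwork,
    group: str,
    belief: ModulatorBelief,
    studies: Sequence[StudyRecord],
) -> CausalNetwork:
    """Attach studies of one sponsor group through an explicit SB node.

    A single discrete node carries the group's sponsorship-bias value
    (prior = the belief distribution); every report node in the group gets
    it as an extra parent, its CPT parameterised by the SB state.  The
    posterior over the node then aggregates what the reports jointly say
    about the sponsor's bias.
    """
    if belief.component != "SB":
        raise NetworkError("shared bias variable requires a belief over SB")
    if not studies:
        return net
    for s in studies:
        if s.sponsor_group != group:
            raise NetworkError(f"study {s.id!r} is not in sponsor group {group!r}")
    node = f"SB[{group}]"
    values = tuple(v for v, _ in sorted(belief.distribution.items()))
    probs = tuple(p for _, p in sorted(belief.distribution.items()))
    if len(values) == 1:
        # point mass: fold the value into each report CPT directly
        for s in studies:
            folded = replace(s, modulators=s.modulators.with_value("SB", values[0]))
            net = attach_study(net, folded)
        return net
    net = add_variable(net, DiscreteVariable(node, values), "modulator")
    net = attach_cpt(net, Cpt(node, (), {(): probs}))
    for s in studies:
        net = add_variable(net, DiscreteVariable(s.report_node, BINARY_STATES), "report")
        cpt = report_cpt(s, extra_parents=(node,), extra_states={node: values})
        net = attach_cpt(net, cpt)
    return net
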