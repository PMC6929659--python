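"""The causal scaffold: hypothesis, indicators, and their elicited CPTs.

Builds the fixed upper layer of the network — the causal hypothesis C
(drug causes adverse effect), difference-making Delta, the statistical
black-box block Sigma = {PD, DR, RoG} (probabilistic dependence,
dose-response, rate of growth), mechanism existence M and time course T —
with the entailment structure

    RoG => DR => PD,   M => T,   Delta => C,   C => M, C => T

hard-coded into the CPTs: entailed rows carry probability 1, and
P(Delta | not C) = 0 makes difference-making a perfect indicator.

The free Sigma rows (how likely each statistical pattern is under
causation and under no causation) are derived from a finite family of
candidate dose-response curve shapes with prior weights conditional on
the causal hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

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
    "HYPOTHESIS",
    "DELTA",
    "PD",
    "DR",
    "ROG",
    "MECH",
    "TIME",
    "INDICATORS",
    "SIGMA",
    "CurveSpec",
    "CurveSet",
    "SigmaCptBundle",
    "CausalLayerConfig",
    "default_curve_set",
    "derive_sigma_cpts",
    "build_causal_layer",
    "check_indicator_positivity",
]

# Canonical node names.
HYPOTHESIS = "C"
DELTA = "Delta"
PD = "PD"
DR = "DR"
ROG = "RoG"
MECH = "M"
TIME = "T"

INDICATORS = (DELTA, PD, DR, ROG, MECH, TIME)
SIGMA = (PD, DR, ROG)


@dataclass(frozen=True)
class CurveSpec:
    """One candidate dose-response curve shape.

    Flags say which statistical indicators the shape exhibits; entailment
    RoG => DR => PD must hold at the flag level.  Weights are unnormalised
    prior masses for the shape conditional on the causal hypothesis being
    true / false.
    """

    label: str
    exhibits_pd: bool
    exhibits_dr: bool
    exhibits_rog: bool
    weight_given_c: float
    weight_given_not_c: float

    def __post_init__(self) -> None:
        if self.exhibits_rog and not self.exhibits_dr:
            raise NetworkError(f"inconsistent curve flags for {self.label!r}: RoG without DR")
        if self.exhibits_dr and not self.exhibits_pd:
            raise NetworkError(f"inconsistent curve flags for {self.label!r}: DR without PD")
        if self.weight_given_c < 0 or self.weight_given_not_c < 0:
            raise NetworkError(f"negative weight for curve {self.label!r}")


@dataclass(frozen=True)
class CurveSet:
    """A finite family of candidate dose-response curves with prior weights."""

    curves: tuple[CurveSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        for attr in ("weight_given_c", "weight_given_not_c"):
            total = sum(getattr(c, attr) for c in self.curves)
            if total <= 0:
                raise NetworkError(f"degenerate curve set: total {attr} is not positive")

    def normalized(self, given_c: bool) -> list[tuple[CurveSpec, float]]:
        attr = "weight_given_c" if given_c else "weight_given_not_c"
        total = sum(getattr(c, attr) for c in self.curves)
        return [(c, getattr(c, attr) / total) for c in self.curves]


@dataclass(frozen=True)
class SigmaCptBundle:
    """The six free conditional probabilities of the Sigma block.

    The entailment rows P(PD|DR) = P(DR|RoG) = 1 are hard-coded when the
    bundle is composed into a network; only the non-entailed conditionals
    live here.
    """

    p_rog_given_c: float
    p_rog_given_not_c: float
    p_dr_given_c_not_rog: float
    p_dr_given_not_c_not_rog: float
    p_pd_given_c_not_dr: float
    p_pd_given_not_c_not_dr: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise NetworkError(f"{name} = {v!r} outside [0,1]")


@dataclass(frozen=True)
class CausalLayerConfig:
    """Parameters of the causal scaffold.

    prior_c
        Prior probability of the causal hypothesis.
    delta_given_c
        P(Delta | C).  Defaults to 1; values below 1 model holistic
        causation, where no surgical intervention on the causal link is
        possible.  P(Delta | not C) is always 0.
    m_given_not_c
        P(M | not C): the probability that some drug-to-effect mechanism
        exists even though the drug does not cause the effect.  Default
        0.5 — such inert mechanisms are common.
    t_given_neither
        P(T | no mechanism, no causation): correct temporal ordering by
        coincidence.  Default 0.5 (indifference).
    sigma_cpts
        The free Sigma-block conditionals; by default derived from
        :func:`default_curve_set`.
    """

    prior_c: float = 0.01
    delta_given_c: float = 1.0
    m_given_not_c: float = 0.5
    t_given_neither: float = 0.5
    sigma_cpts: SigmaCptBundle | None = None

    def __post_init__(self) -> None:
        for name in ("prior_c", "delta_given_c", "m_given_not_c", "t_given_neither"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise NetworkError(f"{name} = {v!r} outside [0,1]")

    def resolved_sigma(self) -> SigmaCptBundle:
        if self.sigma_cpts is not None:
            return self.sigma_cpts
        return derive_sigma_cpts(default_curve_set())


def default_curve_set() -> CurveSet:
    """Eight illustrative dose-response shapes with uniform prior weights.

    Shapes mirror the canonical qualitative families used in dose-finding:
    flat (no dependence), inverted-U (dependence without monotone growth),
    shallow linear / saturating / threshold (dose-response without a steep
    slope), and steep linear / sigmoid / supralinear (steep rate of
    growth).  Under "no causation" the weights tilt towards the flat and
    non-monotone shapes; under causation they are uniform over the eight.
    """
    spec = [
        # label, pd, dr, rog, w_c, w_not_c
        ("flat", False, False, False, 1.0, 6.0),
        ("inverted_u", True, False, False, 1.0, 2.0),
        ("shallow_linear", True, True, False, 1.0, 1.0),
        ("saturating", True, True, False, 1.0, 1.0),
        ("threshold", True, True, False, 1.0, 1.0),
        ("steep_linear", True, True, True, 1.0, 0.5),
        ("sigmoid", True, True, True, 1.0, 0.5),
        ("supralinear", True, True, True, 1.0, 0.5),
    ]
    return CurveSet(tuple(CurveSpec(*row) for row in spec))


def derive_sigma_cpts(curves: CurveSet) -> SigmaCptBundle:
    """Derive the free Sigma conditionals from a curve family.

    With normalised weights w(curve | C) and w(curve | not C):

        P(RoG | C)           = sum of w over curves exhibiting RoG
        P(DR  | C, not RoG)  = w(DR and not RoG) / w(not RoG)
        P(PD  | C, not DR)   = w(PD and not DR) / w(not DR)

    and analogously conditioning on the hypothesis being false.  Each
    quotient is the probability mass of curves exhibiting the stronger
    pattern among those that lack the still-stronger one.
    """
    out: dict[str, float] = {}
    for given_c, suffix in ((True, "c"), (False, "not_c")):
        weighted = curves.normalized(given_c)
        rog = sum(w for c, w in weighted if c.exhibits_rog)
        not_rog = sum(w for c, w in weighted if not c.exhibits_rog)
        dr_not_rog = sum(w for c, w in weighted if c.exhibits_dr and not c.exhibits_rog)
        not_dr = sum(w for c, w in weighted if not c.exhibits_dr)
        pd_not_dr = sum(w for c, w in weighted if c.exhibits_pd and not c.exhibits_dr)
        cond = "C" if given_c else "not C"
        if not_rog <= 0:
            raise NetworkError(f"degenerate curve set: no curve without RoG given {cond}")
        if not_dr <= 0:
            raise NetworkError(f"degenerate curve set: no curve without DR given {cond}")
        out[f"p_rog_given_{suffix}"] = rog
        out[f"p_dr_given_{suffix}_not_rog"] = dr_not_rog / not_rog
        out[f"p_pd_given_{suffix}_not_dr"] = pd_not_dr / not_dr
    return SigmaCptBundle(**out)


def _binary(name: str) -> DiscreteVariable:
    return DiscreteVariable(name, BINARY_STATES)


def build_causal_layer(cfg: CausalLayerConfig) -> CausalNetwork:
    """Build the seven-node causal scaffold with its elicited CPTs.

    Nodes and parents::

        C (root)                      prior cfg.prior_c
        Delta <- C                    P(Delta|C)=cfg.delta_given_c, P(Delta|~C)=0
        RoG   <- C                    from the Sigma bundle
        DR    <- C, RoG               P(DR|*,RoG)=1; else bundle
        PD    <- C, DR                P(PD|*,DR)=1; else bundle
        M     <- C                    P(M|C)=1, P(M|~C)=cfg.m_given_not_c
        T     <- M, C                 1 unless both false, then cfg.t_given_neither
    """
    sigma = cfg.resolved_sigma()
    net = CausalNetwork()
    net = add_variable(net, _binary(HYPOTHESIS), "hypothesis")
    for name in (DELTA, ROG, DR, PD, MECH, TIME):
        net = add_variable(net, _binary(name), "indicator")

    def row(p_true: float) -> tuple[float, float]:
        return (1.0 - p_true, p_true)

    net = attach_cpt(net, Cpt(HYPOTHESIS, (), {(): row(cfg.prior_c)}))
    net = attach_cpt(
        net,
        Cpt(DELTA, (HYPOTHESIS,), {(True,): row(cfg.delta_given_c), (False,): row(0.0)}),
    )
    net = attach_cpt(
        net,
        Cpt(ROG, (HYPOTHESIS,), {(True,): row(sigma.p_rog_given_c), (False,): row(sigma.p_rog_given_not_c)}),
    )
    net = attach_cpt(
        net,
        Cpt(
            DR,
            (HYPOTHESIS, ROG),
            {
                (True, True): row(1.0),
                (False, True): row(1.0),
                (True, False): row(sigma.p_dr_given_c_not_rog),
                (False, False): row(sigma.p_dr_given_not_c_not_rog),
            },
        ),
    )
    net = attach_cpt(
        net,
        Cpt(
            PD,
            (HYPOTHESIS, DR),
            {
                (True, True): row(1.0),
                (False, True): row(1.0),
                (True, False): row(sigma.p_pd_given_c_not_dr),
                (False, False): row(sigma.p_pd_given_not_c_not_dr),
            },
        ),
    )
    net = attach_cpt(
        net,
        Cpt(MECH, (HYPOTHESIS,), {(True,): row(1.0), (False,): row(cfg.m_given_not_c)}),
    )
    net = attach_cpt(
        net,
        Cpt(
            TIME,
            (MECH, HYPOTHESIS),
            {
                (True, True): row(1.0),
                (True, False): row(1.0),
                (False, True): row(1.0),
                (False, False): row(cfg.t_given_neither),
            },
        ),
    )
    return net


def check_indicator_positivity(net: CausalNetwork) -> list[str]:
    """Check P(Ind | C) >= P(Ind) >= P(Ind | not C) for every indicator.

    A positive indicator must be at least as likely under causation as
    marginally, and at least as likely marginally as under no causation.
    Returns a diagnostic string per violated indicator (non-strict check).
    """
    from .inference import posterior  # local import: avoid cycle

    tol = 1e-12
    violations: list[str] = []
    hyp = net.hypothesis
    prior = posterior(net, target=hyp)
    for ind in INDICATORS:
        if ind not in net.variables:
            continue
        p_given_c = posterior(net, target=ind, evidence={hyp: True})
        p_given_not_c = posterior(net, target=ind, evidence={hyp: False})
        p_marg = prior * p_given_c + (1.0 - prior) * p_given_not_c
        if p_given_c < p_marg - tol or p_marg < p_given_not_c - tol:
            violations.append(
                f"{ind}: P({ind}|C)={p_given_c:.6f}, P({ind})={p_marg:.6f}, "
                f"P({ind}|~C)={p_given_not_c:.6f} violates ordering"
            )
    return violations
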