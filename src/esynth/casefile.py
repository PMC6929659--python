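"""Declarative case files, the bundled worked example, forward sampling,
and a synthetic-case generator.

A *case* is everything needed to assess one drug–adverse-effect
hypothesis: the priors to scan, the causal-layer parameters, optional
dose-response curve weights, the studies, and the mechanism hypotheses
with their basic-science reports.  Cases are written as YAML (JSON is a
subset) and loaded into a validated :class:`CaseSpec`;
:func:`run_case` builds the full network and runs the sequential
posterior trajectory.

The bundled fixture (``data/paracetamol_asthma.yaml``) encodes the
paracetamol–childhood-asthma assessment: two candidate mechanisms (NAPQI/
TRPA1-mediated airway inflammation; glutathione depletion and oxidative
stress) with six positive basic-science reports, a null-result RCT
feeding the difference-making indicator, and a cohort study feeding
dose-response and time course.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Hashable, Mapping, Sequence

import numpy as np
import yaml

from .causal import (
    DELTA,
    DR,
    HYPOTHESIS,
    PD,
    ROG,
    TIME,
    CausalLayerConfig,
    CurveSet,
    CurveSpec,
    SigmaCptBundle,
    build_causal_layer,
    derive_sigma_cpts,
)
from .evidence import (
    CptOverride,
    ModulatorBelief,
    ModulatorVector,
    StudyDesign,
    StudyRecord,
    attach_study,
    marginalize_uncertain_modulator,
    shared_bias_variable,
)
from .inference import PosteriorTrajectory, trajectory
from .mechanism import LinkSpec, MechanismSpec, MechReport, build_mechanism_subnet
from .network import CausalNetwork, NetworkError, attach_cpt, validate_network

__all__ = [
    "CaseSpec",
    "BeliefSpec",
    "CaseResult",
    "SyntheticCase",
    "SyntheticConfig",
    "load_case_spec",
    "dump_case_spec",
    "fixture_path",
    "load_fixture",
    "build_case_network",
    "run_case",
    "forward_sample",
    "generate_synthetic_case",
]

_INDICATOR_ALIASES = {
    "delta": DELTA,
    "pd": PD,
    "dr": DR,
    "rog": ROG,
    "t": TIME,
    "time": TIME,
}


@dataclass(frozen=True)
class BeliefSpec:
    """Hierarchical uncertainty about a modulator, scoped to one study or
    to a sponsor group (the latter creates an explicit shared SB node)."""

    belief: ModulatorBelief
    study: str | None = None
    sponsor_group: str | None = None

    def __post_init__(self) -> None:
        if (self.study is None) == (self.sponsor_group is None):
            raise NetworkError("belief must name exactly one of study or sponsor_group")
        if self.sponsor_group is not None and self.belief.component != "SB":
            raise NetworkError("sponsor-group beliefs must concern SB")


@dataclass(frozen=True)
class CaseSpec:
    """A complete, validated evidence specification."""

    priors: tuple[float, ...]
    causal: CausalLayerConfig = field(default_factory=CausalLayerConfig)
    curves: CurveSet | None = None
    studies: tuple[StudyRecord, ...] = ()
    mechanisms: tuple[MechanismSpec, ...] = ()
    beliefs: tuple[BeliefSpec, ...] = ()
    evidence_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "priors", tuple(float(p) for p in self.priors))
        object.__setattr__(self, "studies", tuple(self.studies))
        object.__setattr__(self, "mechanisms", tuple(self.mechanisms))
        object.__setattr__(self, "beliefs", tuple(self.beliefs))
        if self.evidence_order is not None:
            object.__setattr__(self, "evidence_order", tuple(self.evidence_order))
        if not self.priors:
            raise NetworkError("at least one prior required")
        for p in self.priors:
            if not 0.0 < p < 1.0:
                raise NetworkError(f"prior {p!r} outside (0,1)")
        ids = [s.id for s in self.studies] + [m.id for m in self.mechanisms]
        ids += [r.id for m in self.mechanisms for r in m.reports]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate ids across studies/mechanisms/reports: {dup!r}")
        known = set(ids)
        for item in self.evidence_order or ():
            if item not in known:
                raise NetworkError(f"evidence_order references unknown item {item!r}")
        study_ids = {s.id for s in self.studies}
        groups = {s.sponsor_group for s in self.studies if s.sponsor_group}
        for b in self.beliefs:
            if b.study is not None and b.study not in study_ids:
                raise NetworkError(f"belief references unknown study {b.study!r}")
            if b.sponsor_group is not None and b.sponsor_group not in groups:
                raise NetworkError(f"belief references unknown sponsor group {b.sponsor_group!r}")


# --------------------------------------------------------------------------
# YAML (de)serialisation
# --------------------------------------------------------------------------

def _parse_target(raw: str) -> str:
    key = str(raw).strip().lower()
    if key in _INDICATOR_ALIASES:
        return _INDICATOR_ALIASES[key]
    raise NetworkError(f"unknown indicator target {raw!r}; expected one of {sorted(_INDICATOR_ALIASES)}")


def _study_from_dict(raw: Mapping[str, Any]) -> StudyRecord:
    design_raw = raw.get("design")
    if isinstance(design_raw, str):
        design = StudyDesign(design_raw)
    else:
        design = StudyDesign(
            design_raw["kind"],
            multi_dose=bool(design_raw.get("multi_dose", False)),
            anecdotal_delta=bool(design_raw.get("anecdotal_delta", False)),
        )
    mods = {k: float(v) for k, v in (raw.get("modulators") or {}).items()}
    override = None
    if raw.get("cpt_override") is not None:
        o = raw["cpt_override"]
        override = CptOverride(float(o["p_es0_given_true"]), float(o["p_es0_given_false"]))
    return StudyRecord(
        id=str(raw["id"]),
        design=design,
        modulators=ModulatorVector(**mods),
        targets=tuple(_parse_target(t) for t in raw.get("targets", ())),
        outcome=int(raw["outcome"]),
        sponsor_group=raw.get("sponsor_group"),
        cpt_override=override,
    )


def _mechanism_from_dict(raw: Mapping[str, Any]) -> MechanismSpec:
    links = tuple(LinkSpec(str(l["id"]), float(l.get("background", 0.5))) for l in raw.get("links", ()))
    reports = []
    for r in raw.get("reports", ()):
        likelihoods = None
        if r.get("likelihoods") is not None:
            likelihoods = (float(r["likelihoods"][0]), float(r["likelihoods"][1]))
        reports.append(
            MechReport(
                id=str(r["id"]),
                link=str(r["link"]),
                grade=str(r.get("grade", "confident")),
                outcome=int(r.get("outcome", 1)),
                likelihoods=likelihoods,
            )
        )
    return MechanismSpec(
        id=str(raw["id"]),
        p_given_m=float(raw["p_given_m"]),
        links=links,
        reports=tuple(reports),
        shared_links=tuple(str(x) for x in raw.get("shared_links", ())),
    )


def _spec_from_dict(doc: Mapping[str, Any]) -> CaseSpec:
    causal_raw = dict(doc.get("causal") or {})
    sigma = None
    if causal_raw.get("sigma_cpts") is not None:
        sigma = SigmaCptBundle(**{k: float(v) for k, v in causal_raw.pop("sigma_cpts").items()})
    curves = None
    if doc.get("curves") is not None:
        curves = CurveSet(
            tuple(
                CurveSpec(
                    label=str(c["label"]),
                    exhibits_pd=bool(c["pd"]),
                    exhibits_dr=bool(c["dr"]),
                    exhibits_rog=bool(c["rog"]),
                    weight_given_c=float(c["w_c"]),
                    weight_given_not_c=float(c["w_not_c"]),
                )
                for c in doc["curves"]
            )
        )
        if sigma is None:
            sigma = derive_sigma_cpts(curves)
    priors = doc.get("priors") or ()
    causal_cfg = CausalLayerConfig(
        prior_c=float(causal_raw.get("prior_c", priors[0] if priors else 0.01)),
        delta_given_c=float(causal_raw.get("delta_given_c", 1.0)),
        m_given_not_c=float(causal_raw.get("m_given_not_c", 0.5)),
        t_given_neither=float(causal_raw.get("t_given_neither", 0.5)),
        sigma_cpts=sigma,
    )
    beliefs = []
    for b in doc.get("beliefs", ()):
        beliefs.append(
            BeliefSpec(
                belief=ModulatorBelief(str(b["component"]), {float(k): float(v) for k, v in b["distribution"].items()}),
                study=b.get("study"),
                sponsor_group=b.get("sponsor_group"),
            )
        )
    return CaseSpec(
        priors=tuple(float(p) for p in priors),
        causal=causal_cfg,
        curves=curves,
        studies=tuple(_study_from_dict(s) for s in doc.get("studies", ())),
        mechanisms=tuple(_mechanism_from_dict(m) for m in doc.get("mechanisms", ())),
        beliefs=tuple(beliefs),
        evidence_order=tuple(doc["evidence_order"]) if doc.get("evidence_order") else None,
    )


def load_case_spec(path: str | Path) -> CaseSpec:
    """Load and validate a case specification from a YAML/JSON file."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise NetworkError(f"{path}: expected a mapping at top level")
    try:
        return _spec_from_dict(doc)
    except (KeyError, TypeError) as exc:
        raise NetworkError(f"{path}: malformed case spec ({exc})") from exc


def _spec_to_dict(spec: CaseSpec) -> dict[str, Any]:
    doc: dict[str, Any] = {"priors": list(spec.priors)}
    causal: dict[str, Any] = {
        "prior_c": spec.causal.prior_c,
        "delta_given_c": spec.causal.delta_given_c,
        "m_given_not_c": spec.causal.m_given_not_c,
        "t_given_neither": spec.causal.t_given_neither,
    }
    if spec.causal.sigma_cpts is not None and spec.curves is None:
        causal["sigma_cpts"] = {
            k: getattr(spec.causal.sigma_cpts, k) for k in spec.causal.sigma_cpts.__dataclass_fields__
        }
    doc["causal"] = causal
    if spec.curves is not None:
        doc["curves"] = [
            {
                "label": c.label,
                "pd": c.exhibits_pd,
                "dr": c.exhibits_dr,
                "rog": c.exhibits_rog,
                "w_c": c.weight_given_c,
                "w_not_c": c.weight_given_not_c,
            }
            for c in spec.curves.curves
        ]
    reverse = {v: k for k, v in _INDICATOR_ALIASES.items() if k not in ("time",)}
    doc["studies"] = []
    for s in spec.studies:
        entry: dict[str, Any] = {
            "id": s.id,
            "design": {
                "kind": s.design.kind,
                "multi_dose": s.design.multi_dose,
                "anecdotal_delta": s.design.anecdotal_delta,
            },
            "targets": [reverse[t] for t in s.targets],
            "modulators": {k: getattr(s.modulators, k) for k in s.modulators.__dataclass_fields__},
            "outcome": s.outcome,
        }
        if s.sponsor_group:
            entry["sponsor_group"] = s.sponsor_group
        if s.cpt_override is not None:
            entry["cpt_override"] = {
                "p_es0_given_true": s.cpt_override.p_es0_given_true,
                "p_es0_given_false": s.cpt_override.p_es0_given_false,
            }
        doc["studies"].append(entry)
    doc["mechanisms"] = []
    for m in spec.mechanisms:
        entry = {
            "id": m.id,
            "p_given_m": m.p_given_m,
            "links": [{"id": l.id, "background": l.background} for l in m.links],
            "reports": [],
        }
        if m.shared_links:
            entry["shared_links"] = list(m.shared_links)
        for r in m.reports:
            rep: dict[str, Any] = {"id": r.id, "link": r.link, "grade": r.grade, "outcome": r.outcome}
            if r.likelihoods is not None:
                rep["likelihoods"] = list(r.likelihoods)
            entry["reports"].append(rep)
        doc["mechanisms"].append(entry)
    if spec.beliefs:
        doc["beliefs"] = []
        for b in spec.beliefs:
            entry = {"component": b.belief.component, "distribution": dict(b.belief.distribution)}
            if b.study is not None:
                entry["study"] = b.study
            if b.sponsor_group is not None:
                entry["sponsor_group"] = b.sponsor_group
            doc["beliefs"].append(entry)
    if spec.evidence_order is not None:
        doc["evidence_order"] = list(spec.evidence_order)
    return doc


def dump_case_spec(spec: CaseSpec, path: str | Path) -> None:
    """Write a case specification to YAML (inverse of :func:`load_case_spec`)."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def fixture_path() -> Path:
    """Path of the bundled paracetamol–asthma case file."""
    return Path(importlib.resources.files("esynth") / "data" / "paracetamol_asthma.yaml")


def load_fixture() -> CaseSpec:
    return load_case_spec(fixture_path())


# --------------------------------------------------------------------------
# Network assembly and execution
# --------------------------------------------------------------------------

def build_case_network(spec: CaseSpec) -> CausalNetwork:
    """Assemble the full network: causal scaffold, mechanisms, reports."""
    cfg = spec.causal
    if spec.curves is not None and cfg.sigma_cpts is None:
        cfg = CausalLayerConfig(
            prior_c=cfg.prior_c,
            delta_given_c=cfg.delta_given_c,
            m_given_not_c=cfg.m_given_not_c,
            t_given_neither=cfg.t_given_neither,
            sigma_cpts=derive_sigma_cpts(spec.curves),
        )
    net = build_causal_layer(cfg)
    net = build_mechanism_subnet(net, spec.mechanisms)

    study_beliefs: dict[str, list[ModulatorBelief]] = {}
    group_beliefs: dict[str, ModulatorBelief] = {}
    for b in spec.beliefs:
        if b.study is not None:
            study_beliefs.setdefault(b.study, []).append(b.belief)
        else:
            assert b.sponsor_group is not None
            group_beliefs[b.sponsor_group] = b.belief

    grouped: set[str] = set()
    for group, belief in group_beliefs.items():
        members = [s for s in spec.studies if s.sponsor_group == group]
        net = shared_bias_variable(net, group, belief, members)
        grouped.update(s.id for s in members)
    for study in spec.studies:
        if study.id in grouped:
            continue
        net = attach_study(net, study)
        if study.id in study_beliefs:
            net = attach_cpt(net, marginalize_uncertain_modulator(study_beliefs[study.id], study))
    return net


def _evidence_items(spec: CaseSpec) -> list[tuple[str, str, Hashable]]:
    """(item id, report node, observed state) in trajectory order."""
    by_id: dict[str, tuple[str, Hashable]] = {}
    default_order: list[str] = []
    for m in spec.mechanisms:
        for r in m.reports:
            by_id[r.id] = (r.report_node, bool(r.outcome))
            default_order.append(r.id)
    for s in spec.studies:
        by_id[s.id] = (s.report_node, bool(s.outcome))
        default_order.append(s.id)
    order = list(spec.evidence_order) if spec.evidence_order is not None else default_order
    return [(item, *by_id[item]) for item in order]


@dataclass(frozen=True)
class CaseResult:
    """Outcome of running a case: the network and the posterior trajectory."""

    spec: CaseSpec
    network: CausalNetwork
    trajectory: PosteriorTrajectory

    @property
    def final_posteriors(self) -> tuple[float, ...]:
        return self.trajectory.final_posteriors


def run_case(spec: CaseSpec) -> CaseResult:
    """Build the network and run the sequential posterior trajectory.

    Evidence is incorporated in ``spec.evidence_order`` (default: mechanism
    reports in listing order, then studies), one posterior per prior.
    """
    net = build_case_network(spec)
    diagnostics = validate_network(net)
    if diagnostics:
        raise NetworkError(f"case network invalid: {diagnostics!r}")
    items = _evidence_items(spec)
    traj = trajectory(net, [(node, state) for _, node, state in items], spec.priors)
    renamed = tuple(
        row if row.item_id == "prior" else row.__class__(items[i - 1][0], row.posteriors, row.lr_contributions)
        for i, row in enumerate(traj.rows)
    )
    traj = PosteriorTrajectory(traj.priors, renamed)
    return CaseResult(spec, net, traj)


# --------------------------------------------------------------------------
# Sampling and synthetic cases
# --------------------------------------------------------------------------

def forward_sample(net: CausalNetwork, seed: int, n: int) -> list[dict[str, Hashable]]:
    """Draw ``n`` ancestral samples of every variable."""
    diagnostics = validate_network(net)
    if diagnostics:
        raise NetworkError(f"cannot sample an invalid network: {diagnostics!r}")
    rng = np.random.default_rng(seed)
    order = net.topological_order()
    cols: dict[str, np.ndarray] = {}
    for name in order:
        cpt = net.cpts[name]
        states = net.variables[name].states
        k = len(states)
        u = rng.random(n)
        if not cpt.parents:
            cum = np.cumsum(cpt.row(()))
            cols[name] = np.searchsorted(cum, u, side="right").clip(0, k - 1)
            continue
        out = np.empty(n, dtype=np.int64)
        parent_spaces = [net.variables[p].states for p in cpt.parents]
        parent_cols = [cols[p] for p in cpt.parents]
        for combo in itertools.product(*(range(len(s)) for s in parent_spaces)):
            mask = np.ones(n, dtype=bool)
            for pc, ix in zip(parent_cols, combo):
                mask &= pc == ix
            if not mask.any():
                continue
            labels = tuple(parent_spaces[i][ix] for i, ix in enumerate(combo))
            cum = np.cumsum(cpt.row(labels))
            out[mask] = np.searchsorted(cum, u[mask], side="right").clip(0, k - 1)
        cols[name] = out
    names = list(net.variables)
    return [
        {name: net.variables[name].states[int(cols[name][i])] for name in names}
        for i in range(n)
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape of a randomly generated case.

    Defaults give a small mixed-evidence case (two studies, one
    mechanism with up to two links and one report per link) at an
    even prior — the regime used for calibration checks, where the
    updater is scored against its own sampling distribution.
    """

    n_studies: int = 2
    n_mechanisms: int = 1
    max_links: int = 2
    prior: float = 0.5
    modulator_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)

    def __post_init__(self) -> None:
        if self.n_studies < 0 or self.n_mechanisms < 0 or self.max_links < 1:
            raise NetworkError("synthetic config counts must be non-negative (max_links >= 1)")


@dataclass(frozen=True)
class SyntheticCase:
    """A sampled case: generating spec, latent ground truth, observed reports."""

    seed: int
    spec: CaseSpec
    ground_truth: Mapping[str, Hashable]

    @property
    def hypothesis_true(self) -> bool:
        return bool(self.ground_truth[HYPOTHESIS])


def generate_synthetic_case(seed: int, config: SyntheticConfig = SyntheticConfig()) -> SyntheticCase:
    """Sample a case from the generative model itself.

    Draws a random study/mechanism layout, forward-samples one world
    (hypothesis, indicators, mechanisms, report outcomes) from the network
    it induces, and returns the case with the sampled report outcomes as
    the observed evidence.  Same seed, same case.
    """
    rng = np.random.default_rng(seed)
    grid = config.modulator_grid

    def pick(options):
        return options[rng.integers(len(options))]

    studies = []
    for i in range(config.n_studies):
        kind = pick(("rct", "cohort", "case_control"))
        design = StudyDesign(kind)
        if kind == "rct":
            targets: tuple[str, ...] = (DELTA, TIME)
        elif kind == "cohort":
            targets = (pick((PD, DR, ROG)), TIME)
        else:
            targets = (pick((PD, DR, ROG)),)
        mods = ModulatorVector(
            A=pick(grid), SS=pick(grid), D=pick(grid),
            B=pick(grid) if kind == "rct" else 0.0,
            R=pick(grid) if kind == "rct" else 0.0,
            Pl=pick(grid) if kind == "rct" else 0.0,
            SB=float(pick((0.0, 1.0))),
        )
        studies.append(
            StudyRecord(id=f"study{i}", design=design, modulators=mods, targets=targets, outcome=0)
        )
    mechanisms = []
    for j in range(config.n_mechanisms):
        n_links = int(rng.integers(1, config.max_links + 1))
        links = tuple(
            LinkSpec(f"mu{j}_{k}", background=float(pick((0.01, 0.5, 1.0)))) for k in range(n_links)
        )
        reports = tuple(
            MechReport(id=f"mrep{j}_{k}", link=links[k].id, grade=pick(("confident", "cautious")), outcome=1)
            for k in range(n_links)
        )
        mechanisms.append(
            MechanismSpec(
                id=f"Mech{j}",
                p_given_m=float(rng.uniform(0.3, 0.9)),
                links=links,
                reports=reports,
            )
        )
    draft = CaseSpec(
        priors=(config.prior,),
        causal=CausalLayerConfig(prior_c=config.prior),
        studies=tuple(studies),
        mechanisms=tuple(mechanisms),
    )
    net = build_case_network(draft)
    world = forward_sample(net, seed=int(rng.integers(2**31)), n=1)[0]

    observed_studies = tuple(
        StudyRecord(
            id=s.id,
            design=s.design,
            modulators=s.modulators,
            targets=s.targets,
            outcome=int(bool(world[s.report_node])),
            sponsor_group=s.sponsor_group,
            cpt_override=s.cpt_override,
        )
        for s in draft.studies
    )
    observed_mechs = tuple(
        MechanismSpec(
            id=m.id,
            p_given_m=m.p_given_m,
            links=m.links,
            reports=tuple(
                MechReport(id=r.id, link=r.link, grade=r.grade, outcome=int(bool(world[r.report_node])),
                           likelihoods=r.likelihoods)
                for r in m.reports
            ),
            shared_links=m.shared_links,
        )
        for m in draft.mechanisms
    )
    final = CaseSpec(
        priors=draft.priors,
        causal=draft.causal,
        studies=observed_studies,
        mechanisms=observed_mechs,
    )
    return SyntheticCase(seed=seed, spec=final, ground_truth=dict(world))
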