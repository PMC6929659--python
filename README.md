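# esynth

Bayesian-network synthesis of heterogeneous pharmacovigilance evidence:
given randomised trials, observational studies and basic-science
mechanism reports of varying quality, what is the probability that a drug
causes a suspected adverse effect?

## Who this is for

Drug-safety assessors and methodologists who need to aggregate evidence
that standard statistical meta-analysis cannot combine — a null-result
RCT, a dose-response cohort signal, and in-vitro reports on steps of a
candidate biological mechanism — into a single, auditable posterior
probability of causation.

## The model

The causal hypothesis **C** ("drug D causes adverse effect E in
population U") is the root of a discrete Bayesian network. Evidence never
touches C directly; it flows through six *causal indicators*, observable
consequences of causation:

- **Δ** (difference-making): intervening on the drug changes the effect.
  A perfect indicator — Δ ⇒ C, encoded as P(Δ | ¬C) = 0 — though C does
  not entail Δ (holistic causation), so P(Δ | C) ≤ 1 is configurable.
- **Σ = {PD, DR, RoG}** (probabilistic dependence, dose-response, rate
  of growth): symmetric statistical patterns ordered by entailment
  RoG ⇒ DR ⇒ PD, with P(PD | DR) = P(DR | RoG) = 1 hard-coded. The free
  conditionals, e.g. P(PD | C, ¬DR), are derived from a finite family of
  candidate dose-response curve shapes with prior weights conditional on
  C, via probability quotients such as

  P(PD | C, ¬DR) = P(curves exhibiting PD, C, ¬DR) / P(curves exhibiting C, ¬DR).

- **M** (mechanism exists): C ⇒ M, so P(M | C) = 1; P(M | ¬C) = 0.5 by
  default since inert mechanisms are common. M fans out into concrete
  mechanism hypotheses M_i with chains of sub-mechanism links μ_i,k;
  chain CPTs encode that M_i entails each link and that all links jointly
  entail M_i (the final link is impossible under ¬M_i when every earlier
  link holds). Basic-science reports attach to links with graded Bayes
  factors: confident ≈ 10 (0.91/0.09), cautious = 3 (0.75/0.25).
- **T** (time course): M ⇒ T and C ⇒ T; P(T | ¬M, ¬C) = 0.5.

Studies enter as binary report leaves ES ∈ {0, 1} whose CPTs are computed
from quality scores ("evidential modulators") — adjustment A, sample size
SS, duration D, blinding B, randomisation R, placebo Pl, each in [0, 1],
and sponsorship bias SB:

    P(ES=1 | indicators true)  = (1 − SB/10) · (0.5 + avg(tracking)/2)
    P(ES=1 | otherwise)        = (1 − SB/10) · 0.5 · (1 − avg(tracking′))

where duration is excluded from the second average (a long study cannot
detect a signal nature does not send) and sponsorship bias attenuates
positive reports under both states (funder-aligned studies tend to hide
harms). Study design limits which indicators a report may feed: RCTs
speak to Δ and T, cohorts to one Σ indicator plus T, case-control studies
to one Σ indicator only.

Posteriors are computed by exact variable elimination; an independent
brute-force enumeration oracle cross-checks every inference path in the
test suite.

## Worked example

The bundled case file encodes the paracetamol–childhood-asthma
assessment: two candidate mechanisms (M1: paracetamol → NAPQI → TRPA1 →
airway inflammation; M2: glutathione depletion → oxidative-stress
hyperresponsiveness) with six positive basic-science reports, a
null-result sponsor-funded RCT feeding Δ, and a dose-response cohort
study feeding DR and T.

```
$ esynth trajectory src/esynth/data/paracetamol_asthma.yaml
item                prior=0.01      prior=0.005     prior=0.001
prior               0.0100          0.0050          0.0010
rep_mu21_a          0.0175          0.0088          0.0018
rep_mu21_b          0.0193          0.0097          0.0020
rep_mu12            0.0195          0.0098          0.0020
rep_mu22_cautious   0.0197          0.0099          0.0020
rep_mu22_confident  0.0197          0.0099          0.0020
rep_mu13            0.0198          0.0099          0.0020
ludwig              0.0072          0.0036          0.0007
shaheen             0.0148          0.0074          0.0015
```

Each row is P(C | evidence up to and including that item), one column per
prior. The six mechanistic reports roughly double the posterior odds —
and can never do more than that: mechanism evidence reaches C only
through M, capping the Bayes factor at 1 / P(M | ¬C) = 2. The null-result
RCT (`ludwig`, ES = 0) pulls the posterior down by a likelihood ratio of
(13/40)/(91/100) ≈ 0.36; the positive cohort signal (`shaheen`) partially
recovers it. Other CLI commands: `esynth run` (CSV/JSON export),
`esynth validate`, and `esynth simulate --seed N` (sample a synthetic
case from the generative model and score the posterior against the
sampled ground truth).

## Layout

- `src/esynth/network.py` — discrete variables, CPTs, DAG validation, chain-rule joint
- `src/esynth/causal.py` — causal scaffold, curve-derived Σ CPTs, indicator positivity
- `src/esynth/evidence.py` — study targeting rules, modulator formulas, hierarchical modulator uncertainty, shared sponsorship-bias nodes
- `src/esynth/mechanism.py` — mechanism chains, logical-consistency CPTs, graded reports
- `src/esynth/inference.py` — variable elimination, enumeration oracle, trajectories, sensitivity
- `src/esynth/casefile.py` — YAML case files, the bundled fixture, forward sampling, synthetic cases
- `src/esynth/cli.py` — the `esynth` command
- `docs/methods.md` — modelling assumptions, defaults and limitations
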