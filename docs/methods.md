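# Methods

## Model structure

The package assesses a single causal hypothesis C — drug causes adverse
effect — against its negation. C is the unique root of a discrete
Bayesian network; all other variables are binary with states ordered
(false, true), except explicit shared sponsorship-bias nodes, whose
states are the support of the user's belief over the bias value.

The fixed causal layer has seven nodes. Parent sets follow the printed
conditionals of the elicitation: the statistical block is oriented
C → RoG → DR → PD with C also a parent of DR and PD, because the free
conditionals are stated as P(DR | C, ¬RoG) and P(PD | C, ¬DR), which
require exactly these parent sets. Entailments are hard rows:
P(PD | DR) = P(DR | RoG) = P(T | M) = P(M | C) = P(T | C) = 1 and
P(Δ | ¬C) = 0. Three residual probabilities are tunable, with defaults:

| parameter | meaning | default |
|---|---|---|
| `delta_given_c` | P(Δ \| C); < 1 models holistic causation | 1.0 |
| `m_given_not_c` | P(M \| ¬C); inert mechanisms are common | 0.5 |
| `t_given_neither` | P(T \| ¬M, ¬C); temporal order by coincidence | 0.5 |

Only "positive" causation (the drug fostering the effect) is modelled;
the hypothesis space is the hard-coded pair {C, ¬C}.

## Sigma CPTs from curve families

The free Σ conditionals come from a finite set of candidate dose-response
curve shapes, each flagged for which of PD/DR/RoG it exhibits (flags must
respect RoG ⇒ DR ⇒ PD) and weighted conditionally on C. With normalised
weights w(·|C):

    P(RoG | C)        = Σ_{rog} w(c|C)
    P(DR | C, ¬RoG)   = Σ_{dr ∧ ¬rog} w(c|C) / Σ_{¬rog} w(c|C)
    P(PD | C, ¬DR)    = Σ_{pd ∧ ¬dr} w(c|C) / Σ_{¬dr} w(c|C)

Degenerate denominators (no curve lacking DR, or lacking RoG, under
either hypothesis state) are rejected. The derivation is invariant under
rescaling the weights.

The default curve library names eight qualitative shapes (flat,
inverted-U, shallow linear, saturating, threshold, steep linear, sigmoid,
supralinear). The exact functional forms behind such illustrative
families are not fixed by any data, so the default flags and weights are
an editorial choice: flags follow the qualitative shape (flat exhibits
nothing; inverted-U exhibits PD only; the three non-steep monotone shapes
exhibit PD and DR; the three steep shapes all of PD, DR, RoG), weights
are uniform under C and tilted towards flat/non-monotone shapes under ¬C.
Any analysis that depends on Σ conditionals should supply its own curve
weights or an explicit Σ bundle in the case file; the bundled worked
example is insensitive to this choice because its anchor quantities do
not involve Σ reports.

## Report likelihoods

A study's report node CPT is fully determined by its quality profile.
With tracking components averaged to `avg`:

    P(ES=1 | all targeted indicators true) = (1 − SB/10)(0.5 + avg/2)
    P(ES=1 | any targeted indicator false) = (1 − SB/10) · 0.5 · (1 − avg′)

RCTs track with (A, SS, D, B, R, Pl) and fall back to (A, SS, B, R, Pl)
under the null; observational designs use (A, SS, D) and (A, SS).
Duration never appears in the null-state average — study length cannot
manufacture a signal — and the constructor rejects it there. The
sponsorship-bias attenuation divisor is 10 (an SB = 1 study keeps 90 % of
its positive-report probability), kept as a named constant.

Multi-indicator reports (e.g. a cohort study feeding DR and T) apply the
positive formula only to the all-true parent row; every other row takes
the false-positive formula. The worked example prints exactly these two
cases and no graded intermediate, and this is the most conservative
consistent completion.

The bundled null-result RCT (`ludwig`) carries a pinned CPT
(P(ES=0|Δ) = 13/40, P(ES=0|¬Δ) = 91/100) via the case file's
`cpt_override` field rather than the formula path: the published worked
computation for this study evaluates to those values while its stated
modulator vector would give 0.25 via the positive formula, and the pinned
values are the ones the downstream posterior table is computed from. User
studies default to the formula path.

## Modulator uncertainty

Modulators with known values are folded into report CPTs before
inference and create no nodes. Uncertainty about a modulator value is a
discrete belief over candidate values; the report CPT becomes the
belief-weighted mixture of the deterministic CPTs (a hierarchical model
collapsed by marginalisation), which is exactly the deterministic CPT
when beliefs are point masses. A belief about sponsorship bias shared by
several studies of one sponsor group instead becomes an explicit node —
prior equal to the belief, one edge to each of the group's reports — so
the posterior over the sponsor's bias itself updates as reports accrue.

## Mechanism sub-networks

Each mechanism hypothesis M_i (parent M, P(M_i | ¬M) = 0) carries an
ordered chain of links; link k has parents (M_i, links 1..k−1). Rows:
1 wherever M_i is true; 0 for the *final* link when M_i is false and all
earlier links are true (the full chain would entail M_i); otherwise the
link's background probability — 1 for established biochemistry, 0.5 for
indifference, or any elicited value. The zero row is applied only to the
final link because that is the single logically forced row; intermediate
all-true prefixes under ¬M_i keep their background, matching the
elicited tables of the worked example.

A link shared between mechanisms gets every sharing mechanism as an
additional parent and is true with probability 1 when any of them holds,
with the owning chain's rules applying otherwise. This is the minimal
rule consistent with entailment; the bundled case has no shared links.

Evidential modulators are deliberately not applied to mechanism reports;
their strength is expressed through the Bayes-factor grades alone
(confident 0.91/0.09, cautious 0.75/0.25, or a custom pair with the
positive likelihood strictly larger).

A structural consequence worth noting: because mechanism reports reach C
only through M, their joint Bayes factor is bounded by 1 / P(M | ¬C) —
with the default 0.5, mechanistic evidence alone can at most double the
prior odds. The test suite asserts this ceiling on randomised mechanism
configurations.

## Inference

Exact variable elimination with a greedy min-fill ordering over the
moralised graph; factors are dense numpy arrays. The networks involved
are small (the full bundled case is 22 nodes), so no log-space or
approximate machinery is used. Probabilities are 64-bit floats; CPT rows
must sum to 1 within 1e-12; inference cross-checks are asserted at 1e-9.
Comparisons with the published posterior table round half-up to 4 decimal
places, the table's printed precision.

An independent oracle, `brute_force_posterior`, enumerates the full
joint (vectorised, capped at 2^22 configurations) and shares no code with
the elimination path. Every inference result in the test suite is backed
by oracle agreement on randomised networks.

Sequential trajectories recompute the exact posterior for every evidence
prefix and every configured prior; the per-item likelihood-ratio
contribution is the ratio of successive posterior odds. The final row
therefore equals the batch posterior by construction of the model, and
the suite asserts it to 1e-12 together with evidence-order invariance.

Evidence in case files may be attached only to report nodes; latent
indicator and mechanism nodes are never directly observed. The engine
itself accepts conditioning on any node, which the diagnostic
`check_indicator_positivity` uses to verify the elicitation-level
ordering P(Ind | C) ≥ P(Ind) ≥ P(Ind | ¬C) for every indicator. The
check is non-strict: the elicited tables make several of these
inequalities equalities (e.g. Δ under `delta_given_c` = 1), so a strict
test would flag well-formed layers.

## Synthetic cases and what they show

`generate_synthetic_case` samples a random study/mechanism layout (by
default two studies and one mechanism of up to two links, modulators on
a five-point grid, SB ∈ {0, 1}, prior 0.5), then forward-samples one
world — hypothesis, indicators, mechanism links, and report outcomes —
from the network that layout induces, and returns the case with the
sampled reports as observations. Because the cases are drawn from the
model's own generative distribution, the posterior must discriminate the
sampled hypothesis states and be calibrated within Monte Carlo error;
the suite checks both on 1000 seeded cases. This is a self-consistency
check of the updater, not evidence about real pharmacovigilance data:
real studies are not sampled from these CPTs, modulator scores are
judgements rather than measurements, and the generator draws study
layouts independently of the hypothesis state.

The even prior used by the generator is a design choice for these
checks: it spreads posteriors across bins, which a pharmacovigilance-
scale prior (0.01 and below) would not.

## Problem sizes and determinism

All bundled computations are exact and deterministic; randomness appears
only in sampling utilities and randomised property tests, which take
explicit seeds. Default test problem sizes — 500 randomised
oracle-equality networks of up to ~10 nodes (the oracle itself accepts up
to 2^22 configurations), 200 randomised mechanism configurations, 1000
synthetic calibration cases — keep the whole suite under a minute on one
CPU while exercising every code path.

## Known limitations

- External-validity ("relevance") modulation of reports is not modelled.
- Effect sizes are binary; odds ratios, confidence intervals and
  continuous effect-size reports are out of scope.
- CPTs are elicited, not learned from data; no dose-finding or
  quality-scoring pipeline is included.
- The default curve library's flags/weights are illustrative (see above).
- Strength of causation is not represented: the hypothesis is a
  proposition, not a magnitude.
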