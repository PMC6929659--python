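# Paracetamol -> childhood asthma/wheezing: the bundled worked example.
#
# Two candidate mechanisms with six positive basic-science reports, a
# null-result RCT feeding the difference-making indicator (report CPT
# pinned to the published worked values 13/40 and 91/100), and a cohort
# study feeding dose-response + time course (report CPT from the
# modulator formulas, which give 1 and 0 here).
#
# Evidence beyond the cohort study (further observational studies and
# ecological time-trend data) would require Sigma conditionals and
# per-study parameters that were never fully published, and is
# therefore not encoded here.

priors: [0.01, 0.005, 0.001]

causal:
  prior_c: 0.01
  delta_given_c: 1.0     # difference-making taken as certain under causation
  m_given_not_c: 0.5     # inert mechanisms are common
  t_given_neither: 0.5   # temporal ordering by coincidence

mechanisms:
  - id: M1               # paracetamol -> NAPQI -> TRPA1 -> airway inflammation
    p_given_m: 0.7
    links:
      - {id: mu11, background: 1.0}   # metabolisation to NAPQI: established
      - {id: mu12, background: 0.5}   # NAPQI stimulates TRPA1
      - {id: mu13, background: 0.5}   # TRPA1 -> neurogenic airway inflammation
    reports:
      - {id: rep_mu12, link: mu12, grade: confident, outcome: 1}
      - {id: rep_mu13, link: mu13, grade: confident, outcome: 1}
  - id: M2               # paracetamol -> glutathione depletion -> oxidative stress
    p_given_m: 0.8
    links:
      - {id: mu21, background: 0.01}  # glutathione depletion at therapeutic dose
      - {id: mu22, background: 0.5}   # low glutathione -> airway hyperresponsiveness
    reports:
      - {id: rep_mu21_a, link: mu21, grade: confident, outcome: 1}
      - {id: rep_mu21_b, link: mu21, grade: confident, outcome: 1}
      - {id: rep_mu22_cautious, link: mu22, grade: cautious, outcome: 1}
      - {id: rep_mu22_confident, link: mu22, grade: confident, outcome: 1}

studies:
  - id: ludwig           # null-result practitioner RCT, sponsor-funded
    design: rct
    targets: [delta]
    modulators: {A: 0.5, SS: 1.0, D: 0.0, B: 1.0, R: 1.0, Pl: 0.5, SB: 1.0}
    outcome: 0
    cpt_override:        # published worked values; see package docs
      p_es0_given_true: 0.325
      p_es0_given_false: 0.91
  - id: shaheen          # Avon cohort: dose-response + time course
    design: cohort
    targets: [dr, t]
    modulators: {A: 1.0, SS: 1.0, D: 1.0, B: 0.0, R: 0.0, Pl: 0.0, SB: 0.0}
    outcome: 1

evidence_order:
  - rep_mu21_a
  - rep_mu21_b
  - rep_mu12
  - rep_mu22_cautious
  - rep_mu22_confident
  - rep_mu13
  - ludwig
  - shaheen
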