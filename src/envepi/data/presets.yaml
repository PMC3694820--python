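# Named generative presets for the synthetic-data module.
#
# Explicit presets pin the noise-free expression of every genotype in both
# environments and realize the canonical two-locus interaction geometries
# of the vector/polygon method.  Benefit polarity: expression up is
# beneficial in Env_0, expression down is beneficial in Env_1.
#
# The thermodynamic "inversion" preset is the three-mutation
# lock + destabilizer scenario: one allosteric-lock mutation (S97P-like,
# modeled as allosteric-only, ddG_fold = 0) plus two destabilizing
# mutations with round illustrative ddG values.

parallelogram:
  # no epistasis, no GxE: both mutations beneficial in both environments,
  # log-additive (opposing polygon sides parallel, all vectors quadrant I)
  model: explicit
  mutations: [A, B]
  expression:
    Env_0: {"": 1.0, "A": 4.0, "B": 2.0, "A;B": 8.0}
    Env_1: {"": 1.0, "A": 0.25, "B": 0.5, "A;B": 0.125}

gxe_only:
  # log-additive (parallelogram) but mutation A trades off between
  # environments: both A sides in quadrant IV, no GxG
  model: explicit
  mutations: [A, B]
  expression:
    Env_0: {"": 1.0, "A": 4.0, "B": 2.0, "A;B": 8.0}
    Env_1: {"": 1.0, "A": 4.0, "B": 0.5, "A;B": 2.0}

gxg_only:
  # environment-independent sign epistasis: B neutral alone (quadrant III)
  # and beneficial in both environments with A (quadrant I); no vector in
  # II/IV, hence no GxGxE
  model: explicit
  mutations: [A, B]
  expression:
    Env_0: {"": 1.0, "A": 2.0, "B": 1.0, "A;B": 8.0}
    Env_1: {"": 1.0, "A": 0.5, "B": 1.0, "A;B": 0.125}

gxgxe:
  # B is neutral alone (III) but GxE-trade-off with A present (IV):
  # a split opposing pair with a member in IV
  model: explicit
  mutations: [A, B]
  expression:
    Env_0: {"": 1.0, "A": 2.0, "B": 1.0, "A;B": 4.0}
    Env_1: {"": 1.0, "A": 2.0, "B": 1.0, "A;B": 4.0}

figS1_counterexample:
  # GxE and GxG together without GxGxE: A is sign-epistatic but
  # environment-independent (III -> I), B is GxE but background-independent
  # (IV in both backgrounds)
  model: explicit
  mutations: [A, B]
  expression:
    Env_0: {"": 1.0, "A": 1.0, "B": 4.0, "A;B": 8.0}
    Env_1: {"": 1.0, "A": 1.0, "B": 4.0, "A;B": 2.0}

inversion:
  # lock + two destabilizers with IPTG stabilization: the wild type is
  # induced by IPTG, the triple mutant is repressed by it
  model: thermodynamic
  mutations:
    - {name: L1, ddG_fold: 0.0, allosteric_lock: true}
    - {name: D1, ddG_fold: 2.0}
    - {name: D2, ddG_fold: 2.0}
  dG_fold_wt: -4.0
  dG_iptg: 3.0
  RT: 0.593
  R_max: 200.0
  E_min: 1.0
  E_max: 1000.0
  leak_release: 0.001
  noise_cv: 0.1
  n_replicates: 3
  seed: 0
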