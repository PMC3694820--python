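# Methods

## Data model and normalization

A map holds one measurement per (genotype, environment): either raw
replicates or a (mean, sd, n) summary. Expression units are arbitrary —
every decision in the package is a ratio or a within-environment
comparison — so normalization (dividing all values by the reference
genotype's mean in the same environment) is an explicit, idempotent
operation that changes plots but no classification. Summary records are
first-class because published supplementary tables usually report
summaries rather than replicates; the pooled two-sample t statistic is a
function of (mean, sd, n) alone, so the two record kinds are fully
interchangeable for significance testing.

Genotypes are bit vectors over a variant's *ordered* mutation list; the
text form is semicolon-separated mutation names with the empty string as
wild type (a bitstring dialect is accepted via the format config).

## Significance and benefit signs

Each mutation effect (one mutation, one background, one environment) is
tested with a two-sided two-sample t-test between the carrier and the
background genotype. Defaults and reasons:

* **Pooled-variance Student t** rather than Welch: with n = 3 per group
  the Welch degrees of freedom are extremely unstable; Welch is available
  via config.
* **Raw expression scale** rather than log: a config switch enables log
  scale (replicates are logged directly; summary records use the
  delta-method approximation sd/mean for the log-scale spread).
* **Bonferroni family** = every effect test within one variant's dataset,
  both environments included (24 tests for a complete three-mutation
  variant). The family is a genuine convention choice; this is the most
  conservative reading of a single classification panel, and the family
  size used is echoed in all output metadata.
* **Degenerate spread**: if both sides have zero spread the p-value is 1
  for equal means and 0 otherwise. This makes noise-free synthetic data
  behave as "every nonzero difference is significant", which is exactly
  what the analytic sign oracles in the test suite assume.
* **α = 0.05** family-wise, flags assigned by the strict inequality
  p < α/m.

Benefit polarity encodes the selective objective: under inversion,
expression up is beneficial in `Env_0` and down is beneficial in `Env_1`.
A mutation's benefit sign is *beneficial* only when its effect is both
significant and in the favored direction; everything else — including
exactly neutral and non-significant effects — is *deleterious*, because
neutral mutations are not fixed by positive selection. Sign is therefore
invariant under any positive rescaling of one environment's values.

An opt-in cross-dataset pooling rule exists for effects that are shared
verbatim between variants (same mutation, background and environment): if
a majority of datasets call the effect significant with a consistent
direction, the remaining datasets may inherit the call. It is disabled by
default and refuses to act when significant datasets disagree on
direction.

## M/S/R classification

Within a motif (pair + background), the four benefit signs determine the
category per environment: R when both mutations are deleterious alone and
beneficial together; S when exactly one mutation's sign depends on the
other (the changer is named); M otherwise. The categories are mutually
exclusive and exhaustive given one convention: a both-signs-change pattern
in any orientation other than deleterious-alone/beneficial-together (for
example the mirror case, beneficial alone and deleterious together) is
*labelled R with an orientation flag* (`beneficial_together = False`) and
a warning, rather than being given a fourth category. The canonical R
definition covers only the valley-crossing direction and the mirror
pattern has no established name; flagging keeps the taxonomy closed
without inventing one.

Cross-environment concordance compares the M/S/R letter only — an S motif
counts as concordant even if a different mutation changes sign in each
environment. Only this reading reproduces the embedded reference panel's
own concordance count, and the panel itself contains rows where the same
S(x) label appears in both environments.

### A note on the embedded reference panel

The 18-motif reference panel is stored exactly as published. One of its
six-row blocks is internally inconsistent as a set of benefit signs: in
the first variant's no-inducer column, the three magnitude calls involving
the second mutation force its sign to be equal around a four-background
cycle while the one sign call forces an inequality on the same cycle — an
odd cycle, satisfiable by no assignment. Because each pairwise comparison
appears with the same test result in both motifs that use it, *no*
dataset processed by a deterministic classifier can reproduce all six
categories of that block simultaneously. The synthetic stand-in tables in
`envepi.examples` therefore reproduce 35 of the 36 category cells and
document which cell deviates; the fixture itself is still asserted and
reported verbatim.

## Vectors, quadrants and polygons

Vector coordinates are (normalized `Env_0` expression, normalized inverse
`Env_1` expression), so the reference sits at (1, 1) and progress toward
inversion points to the upper right. Quadrants are assigned from the two
statistical benefit signs, not from raw geometry, so that mutations
neutral on an axis land on that axis's deleterious side; in particular a
zero-length vector is quadrant III. A raw-geometry mode exists for
plotting only. The x-axis carries the `Env_0` sign and the y-axis the
`Env_1` sign, with quadrants numbered counterclockwise (II = `Env_1`-only
beneficial); since both II and IV are G×E by definition, every detection
is invariant to which of the two off-diagonal quadrants is which.

Polygon closure — both mutational paths from the double-absent to the
double-present genotype reaching the same point — is an algebraic identity
in log coordinates (the displacements telescope), checked defensively to
1e-9; observed deviations are at machine precision.

Detections: G×E iff a vector is in quadrant II or IV; G×G iff an opposing
pair of polygon sides occupies different quadrants; G×G×E iff some split
opposing pair additionally has a member in II or IV. G×G×E implies G×G by
construction, and the shipped counterexample preset demonstrates that
G×E ∧ G×G does not imply G×G×E.

The polygon census counts opposing pairs under three rooting conventions,
because the published counting is not fully explicit about which
third-site backgrounds define the polygons: `present` (default; one
polygon per pair with the remaining mutation present, where the narrated
examples live), `absent`, and `both` (all six motif polygons). All three
are reported side by side; the census fraction is the share of opposing
pairs that point in the same quadrant, i.e. that lack the sign-changing
higher-order signature.

## Higher-order (G×G×G) comparison

A third mutation that changes a pair's category in a fixed environment is
a G×G×G interaction; differing G×G×G status between the environments is
G×G×G×E. By default the comparison includes the sign-changer identity
(S(A) → S(B) counts as a change): which mutation is conditional is part of
the motif's structure, and a change of changer is a real third-order
effect even when the letter stays S. A relaxed letter-only mode is
available and reports emit both.

## Trajectories

All L! orderings are enumerated deterministically (lexicographic in
mutation positions). A step is selectable when its effect is beneficial;
the variable-environment policy allows a free environment choice at every
step, with no switching cost or dwell time — deliberately the *weakest*
constraint under which environmental change can open trajectories, and
labelled as such in reports. Constant-environment accessibility is
therefore always a subset of variable accessibility. A sensitivity mode
(`require_benefit=False`) admits steps that are merely not significantly
deleterious. Reversion steps (walking a trajectory backwards) are judged
from the forward effect inverted: a reversion is selectable only when the
forward effect is significantly in the disfavored direction.

Expression profiles report normalized expression (`Env_0`) or normalized
inverse expression (`Env_1`) at the L + 1 trajectory nodes, matching the
vector-plot axes.

## The generative model

`SyntheticModelParams` formalizes the proposed inversion mechanism with
the minimal standard thermodynamic ingredients — the mechanism is stated
verbally in the literature without equations, so all functional forms here
are model assumptions, recorded as such:

* two-state folding with Boltzmann occupancy
  P_fold = 1/(1 + exp(ΔG/RT)), RT = 0.593 kcal/mol (25 °C);
* additive per-mutation ΔΔG_fold (kcal/mol, positive destabilizes) on a
  stable wild-type baseline (ΔG_wt = −4 kcal/mol by default, a typical
  small-protein stability margin);
* inducer binding stabilizes every genotype by ΔG_IPTG (default
  3 kcal/mol) — the binding site is assumed intact in all variants;
* wild-type induction is carried by an allosteric release factor
  (`leak_release`, default 1e-3): with inducer bound and no lock
  mutation, only that fraction of folded repressor remains DNA-bound;
* a lock mutation blocks the release (P_active = P_fold regardless of
  inducer). The default inversion preset models the lock as *allosteric
  only* (ΔΔG_fold = 0): giving the lock its own destabilizing ΔΔG would
  make its no-inducer effect strictly positive, whereas its observed role
  in the wild-type background is specific to the inducer environment —
  the allosteric-only choice makes the lock exactly neutral without
  inducer, which is the cleanest expression of that role in a noise-free
  model;
* expression E = E_min + (E_max − E_min)/(1 + R_max·P_active), defaults
  E_min = 1, E_max = 1000, R_max = 200 (a ~200-fold repression range);
* lognormal replicate noise with constant CV (default 0.1, a realistic
  reporter-assay spread) and n = 3 replicates, from a single seeded
  generator consumed in canonical genotype/environment order, so a seed
  fully determines the dataset.

The destabilizer preset values (+2 kcal/mol each against the −4 baseline)
put the double-destabilized genotype exactly at the folding midpoint
without inducer while leaving it comfortably folded with inducer — the
threshold signature: expression without inducer rises monotonically along
every mutational ordering, with later steps moving further, while
expression with inducer stays repressed once the lock is present.

What the model emulates: threshold behavior of accumulated
destabilization, inducer-dependent stabilization, an allosteric lock,
multiplicative replicate noise, and the resulting opening of trajectories
only under environmental change. What it does not emulate: sign epistasis
between the destabilizers themselves (a pure stability model moves
expression the same way in both backgrounds), mutation-specific allosteric
modulation, operator-affinity changes, growth-rate feedback, and any
background-dependent ΔΔG. Consequently the canonical two-locus interaction
geometries are provided as *explicit* landscapes (noise-free expression
pinned per genotype and environment) rather than forced out of the
thermodynamic model; passing tests on these presets validates the
detection logic, not the claim that stability alone can generate every
geometry.

The stand-in tables for the three published variants (`envepi.examples`)
are likewise explicit constructions: their sign structure follows the
published categories and narrated vector geometry, their sd is 2 % of the
mean (comfortably inside the Bonferroni threshold for every intended
contrast at n = 3), and one embedded conditional fold change of 20 is the
single published magnitude they encode. They are labelled synthetic
everywhere and exist to exercise the summary-statistics path end to end,
not to reconstruct the original measurements; in particular, polygon
census fractions computed from them characterize the construction, not
the original data.

## Numerical and degenerate-input conventions

* t-test requires n ≥ 2 on both sides; zero spread handled as above.
* Exactly equal means are "no change" (direction `none`), hence
  deleterious after the neutral-folding rule; no epsilon is applied to
  means, so ties must be exact (as they are in noise-free synthetic
  data).
* Polygon closure tolerance 1e-9 in log units (observed: ≤ 2.3e-16).
* Fold changes are ratios of means and strictly positive by the data
  model's positivity invariant.
* Normalization requires the reference genotype in both environments and
  fails loudly otherwise; missing genotypes are always reported by name.

## Problem sizes

The default test and acceptance runs use complete two-locus landscapes
(16 records) for the property scans — 1000 random landscapes for the
oracle-agreement acceptance check, 200–300 for the invariant suites — and
the complete three-mutation maps (16 records each) for the panel,
trajectory and census computations. These sizes make every check exact
and exhaustive at the motif level while keeping the whole suite fast.

## Known limitations

* The plane method is inherently two-environment; no three-environment
  generalization of the quadrant scheme is attempted.
* No quantitative epistasis coefficients (interaction terms, variance
  decomposition, Walsh/Fourier analysis): the classification is
  categorical by design.
* Bonferroni only; no FDR or permutation alternatives in this version.
* Accessibility is purely sign-based: no fixation probabilities, clonal
  interference or waiting times.
* The variable-environment policy's free per-step environment choice is
  an upper bound on what structured environmental fluctuation could
  achieve.
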