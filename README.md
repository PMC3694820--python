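# envepi

Environment-dependent epistasis analysis for small combinatorial
genotype–phenotype maps measured in two environments.

`envepi` is built for the kind of experiment where a handful of defining
mutations (typically three) are reconstructed in every combination and a
quantitative phenotype — reporter expression, in the motivating system — is
measured with and without an environmental signal (no IPTG, `Env_0`, versus
1 mM IPTG, `Env_1`). Its motivating use case is the evolution of an
*inverse* lac repressor: a LacI variant that represses in the presence of
IPTG instead of being induced by it. Under that objective, higher
expression is beneficial in `Env_0` and lower expression is beneficial in
`Env_1`, and the package answers questions such as: does a mutation's
benefit sign depend on the genetic background, on the environment, or on
both at once — and which mutational orderings are open to stepwise positive
selection?

## What it computes

**Epistasis categories (M/S/R).** For a pair of mutations in a fixed
background, the four benefit signs s₁ = sign(m₁|bg), s₁′ = sign(m₁|bg+m₂),
s₂ = sign(m₂|bg), s₂′ = sign(m₂|bg+m₁) determine, per environment:
*magnitude* epistasis (M, no sign changes), *sign* epistasis (S, exactly
one mutation flips; the flipping mutation is named), or *reciprocal sign*
epistasis (R, both deleterious alone yet beneficial together — the
necessary condition for multiple fitness peaks). Signs come from
two-sample t-tests (pooled-variance by default, computable from mean/sd/n
summaries) with a panel-wide Bonferroni correction at α = 0.05; neutral
effects are grouped with deleterious ones, since neutral mutations are not
fixed by positive selection. A three-mutation variant yields the standard
6-row panel (3 pairs × 2 third-site backgrounds), and an 18-motif reference
panel for three inverse LacI variants ships as an embedded fixture.

**Mutational vectors and polygons.** Each mutation in each background is a
vector in the plane (x = expression in `Env_0`, y = 1/expression in
`Env_1`), both normalized to the wild type, so progress toward inversion
points up and to the right. Quadrants are assigned from the statistical
benefit signs (I = beneficial in both, II = `Env_1` only, III = neither,
IV = `Env_0` only); quadrant II/IV vectors are sign-changing G×E
interactions. The two paths ab→Ab→AB and ab→aB→AB close a polygon whose
opposing sides are the same mutation in two backgrounds: opposing sides in
different quadrants indicate G×G, and if one of the split pair lies in
II/IV the interaction is G×G×E. G×E together with G×G does *not* imply
G×G×E — the package ships a constructed counterexample preset. Category
changes induced by a third mutation are reported as G×G×G, and their
environment dependence as G×G×G×E.

**Trajectory accessibility.** All L! orderings from wild type to the full
mutant are enumerated; a step is selectable when its effect is beneficial
(significant, favored direction). Accessibility is evaluated in each
constant environment and under a variable-environment policy (free
environment choice at each step), with per-step environment witnesses.

**Synthetic data.** A thermodynamic stability/allostery model generates
complete maps from first principles: per-mutation folding ΔΔG, a Boltzmann
folded fraction P_fold = 1/(1 + exp(ΔG/RT)), inducer binding that
stabilizes (ΔG_IPTG), an allosteric-lock flag that keeps the repressor
DNA-bound under inducer, and a repression curve
E = E_min + (E_max − E_min)/(1 + R_max·P_active), with seeded lognormal
replicate noise. Explicit-landscape presets cover the textbook interaction
geometries (parallelogram, G×E only, G×G only, G×G×E, and the
G×E∧G×G⇏G×G×E counterexample).

## Worked example

Simulate the noise-free inversion scenario (lock mutation `L1` plus
destabilizers `D1`, `D2`) and classify it:

```sh
$ envepi simulate --preset inversion --seed 1 --noise-cv 0 -o inv.tsv
$ envepi classify --input inv.tsv
inferred
X	X	○	M	M
X	○	X	M	M
•	X	X	M	M
X	•	X	M	M
○	X	X	M	M
X	X	•	M	M

concordant across environments: 6/6
```

Each row is one motif: `X X ○` means the first two mutations are the pair
under test with the third site wild type (`•` = third mutation present);
the last two columns are the `Env_0` and `Env_1` categories. The pure
stability/lock model produces no sign epistasis — every effect keeps its
sign across backgrounds — so all six motifs are magnitude epistasis in
both environments.

Accessibility is a different story:

```sh
$ envepi trajectories --input inv.tsv
...
"policies": {"constant_Env_0": 0, "constant_Env_1": 0, "variable": 6}
```

No ordering is selectable in either constant environment (the lock step is
neutral without inducer; the destabilizing steps are deleterious with it),
but all six orderings open up when the environment may change between
steps — e.g. the witness for `L1→D1→D2` is `Env_1, Env_0, Env_0`: fix the
lock under inducer, then the destabilizers without it. This is the core
phenomenon the package quantifies: genetic constraint that exists in every
constant environment can vanish in a variable one.

The embedded reference panel and its cross-environment concordance:

```sh
$ envepi fixture
...
concordant across environments: 9/18
```

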