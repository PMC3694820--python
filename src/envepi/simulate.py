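"""Synthetic genotype x environment expression data.

Two generative modes feed the pipeline with fully controlled landscapes:

**Thermodynamic model** (:class:`SyntheticModelParams`): a minimal
two-state folding formalization of the proposed inversion mechanism.
Each mutation carries a folding free-energy change ``ddG_fold``
(kcal/mol, positive = destabilizing) and optionally an *allosteric lock*
flag: a lock mutation blocks the inducer-triggered release from the DNA,
so a locked repressor stays active under IPTG.  The repressor's folding
free energy is

    dG = dG_fold_wt + sum(ddG_fold of present mutations) - dG_iptg * [IPTG]

(IPTG binding stabilizes every genotype; the wild type's induction comes
from allosteric release, not from destabilization).  The folded fraction
follows the Boltzmann sigmoid ``P_fold = 1 / (1 + exp(dG / RT))``; the
active-repressor probability is ``P_fold``, reduced by the small
``leak_release`` factor when IPTG is present and no lock mutation is
carried (functional allostery releases the DNA).  Expression follows a
standard repression curve

    E = E_min + (E_max - E_min) / (1 + R_max * P_active).

Accumulating destabilizing mutations therefore has threshold behavior:
little effect while ``dG`` is far below zero, then a steep expression
increase as the stability margin is spent — but only in the environment
where IPTG's stabilizing contribution is missing.

**Explicit landscapes** (:class:`ExplicitLandscape`): noise-free
expression given directly per (genotype, environment).  Pure stability
effects move expression the same way in both environments, so the
textbook two-locus interaction geometries (parallelogram, G x E only,
G x G only, ...) are shipped as explicit tables instead.

Both modes add seeded lognormal replicate noise with a fixed coefficient
of variation (multiplicative noise with positive support, the standard
model for reporter expression data), defaulting to triplicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .gpmap import (
    ENV_0,
    ENV_1,
    ENVIRONMENTS,
    Environment,
    ExpressionRecord,
    Genotype,
    GenotypePhenotypeMap,
    Variant,
)

__all__ = [
    "MutationSpec",
    "SyntheticModelParams",
    "ExplicitLandscape",
    "SyntheticDataset",
    "noise_free_expression",
    "generate_dataset",
    "scenario_library",
    "preset",
    "random_two_locus_landscape",
]


@dataclass(frozen=True)
class MutationSpec:
    name: str
    ddG_fold: float = 0.0  # kcal/mol; positive destabilizes
    allosteric_lock: bool = False


@dataclass(frozen=True)
class SyntheticModelParams:
    """Parameters of the stability/allostery model (energies in kcal/mol)."""

    mutations: tuple[MutationSpec, ...]
    dG_fold_wt: float = -4.0  # negative = stable
    dG_iptg: float = 3.0  # stabilization from inducer binding
    RT: float = 0.593  # thermal energy at 25 C
    R_max: float = 200.0  # repression factor of the active repressor
    E_min: float = 1.0  # fully repressed expression (arbitrary units)
    E_max: float = 1000.0  # unrepressed expression
    leak_release: float = 1e-3  # residual DNA occupancy of induced, unlocked LacI
    noise_cv: float = 0.1  # lognormal coefficient of variation
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.E_max > self.E_min > 0:
            raise ValueError("need E_max > E_min > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.RT <= 0:
            raise ValueError("RT must be positive")
        if not 0 <= self.leak_release <= 1:
            raise ValueError("leak_release must be in [0, 1]")

    def variant(self, name: str = "synthetic") -> Variant:
        return Variant.from_names(name, [m.name for m in self.mutations])


def noise_free_expression(
    params: SyntheticModelParams, genotype: Genotype, environment: Environment
) -> float:
    """Deterministic expression level under the thermodynamic model."""
    iptg = environment.iptg_mM > 0
    dG = params.dG_fold_wt + sum(
        m.ddG_fold for m, b in zip(params.mutations, genotype.bits) if b
    )
    if iptg:
        dG -= params.dG_iptg
    p_fold = 1.0 / (1.0 + math.exp(dG / params.RT))
    locked = any(
        m.allosteric_lock for m, b in zip(params.mutations, genotype.bits) if b
    )
    if iptg and not locked:
        p_active = p_fold * params.leak_release
    else:
        p_active = p_fold
    return params.E_min + (params.E_max - params.E_min) / (
        1.0 + params.R_max * p_active
    )


@dataclass(frozen=True)
class ExplicitLandscape:
    """Noise-free expression specified directly per genotype/environment.

    ``expression`` maps environment label -> {genotype label -> value},
    with genotype labels as semicolon-joined mutation names ('' = wild
    type).
    """

    mutation_names: tuple[str, ...]
    expression: dict
    noise_cv: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def variant(self, name: str = "synthetic") -> Variant:
        return Variant.from_names(name, list(self.mutation_names))

    def value(self, variant: Variant, genotype: Genotype, env: Environment) -> float:
        label = genotype.label(variant)
        try:
            return float(self.expression[env.label][label])
        except KeyError:
            raise KeyError(
                f"explicit landscape lacks a value for genotype "
                f"{label or '<wild type>'} in {env.label}"
            ) from None


Params = Union[SyntheticModelParams, ExplicitLandscape]


@dataclass
class SyntheticDataset:
    """A generated map together with its noise-free ground truth."""

    params: Params
    gpmap: GenotypePhenotypeMap
    ground_truth: dict  # (bits, env label) -> noise-free expression

    def true_expression(self, genotype: Genotype, env: Environment) -> float:
        return self.ground_truth[(genotype.bits, env.label)]


def _lognormal_replicates(
    rng: np.random.Generator, mean: float, cv: float, n: int
) -> tuple[float, ...]:
    """n lognormal draws with the given mean and coefficient of variation."""
    if cv == 0.0:
        return (mean,) * n
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return tuple(float(v) for v in rng.lognormal(mu, math.sqrt(sigma2), size=n))


def generate_dataset(
    params: Params,
    variant: Optional[Variant] = None,
    name: str = "synthetic",
) -> SyntheticDataset:
    """Complete 2^L x 2-environment dataset with seeded replicate noise.

    The same parameters (including seed) always produce the identical
    dataset; ``noise_cv = 0`` reproduces the ground truth exactly.
    """
    if variant is None:
        variant = params.variant(name)
    rng = np.random.default_rng(params.seed)
    gpmap = GenotypePhenotypeMap(variant)
    truth = {}
    for genotype in variant.all_genotypes():
        for env in ENVIRONMENTS:
            if isinstance(params, SyntheticModelParams):
                value = noise_free_expression(params, genotype, env)
            else:
                value = params.value(variant, genotype, env)
            truth[(genotype.bits, env.label)] = value
            reps = _lognormal_replicates(
                rng, value, params.noise_cv, params.n_replicates
            )
            gpmap.add(ExpressionRecord(genotype, env, replicates=reps))
    return SyntheticDataset(params, gpmap, truth)


#: expression grid for random landscapes: powers of two give crisp benefit
#: signs and frequent exact ties (neutral effects)
_RANDOM_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


def random_two_locus_landscape(
    rng: np.random.Generator, mutation_names: Sequence[str] = ("A", "B")
) -> ExplicitLandscape:
    """A random noise-free two-locus landscape for property testing.

    Each genotype's expression in each environment is drawn independently
    from a small power-of-two grid, so every benefit-sign combination
    (including exact neutrality) is exercised with substantial
    probability.
    """
    names = tuple(mutation_names)
    labels = ["", names[0], names[1], f"{names[0]};{names[1]}"]
    expression = {
        env.label: {
            lab: float(rng.choice(_RANDOM_GRID)) for lab in labels
        }
        for env in ENVIRONMENTS
    }
    return ExplicitLandscape(
        mutation_names=names, expression=expression, noise_cv=0.0
    )


def _parse_preset(entry: dict) -> Params:
    kind = entry.get("model")
    if kind == "thermodynamic":
        muts = tuple(
            MutationSpec(
                name=m["name"],
                ddG_fold=float(m.get("ddG_fold", 0.0)),
                allosteric_lock=bool(m.get("allosteric_lock", False)),
            )
            for m in entry["mutations"]
        )
        kwargs = {
            k: entry[k]
            for k in (
                "dG_fold_wt",
                "dG_iptg",
                "RT",
                "R_max",
                "E_min",
                "E_max",
                "leak_release",
                "noise_cv",
                "n_replicates",
                "seed",
            )
            if k in entry
        }
        return SyntheticModelParams(mutations=muts, **kwargs)
    if kind == "explicit":
        return ExplicitLandscape(
            mutation_names=tuple(entry["mutations"]),
            expression={
                env: {str(k): float(v) for k, v in table.items()}
                for env, table in entry["expression"].items()
            },
            noise_cv=float(entry.get("noise_cv", 0.0)),
            n_replicates=int(entry.get("n_replicates", 3)),
            seed=int(entry.get("seed", 0)),
        )
    raise ValueError(f"unknown preset model kind {kind!r}")


def scenario_library() -> dict:
    """Named parameter presets covering the canonical interaction motifs.

    Keys: ``parallelogram`` (no epistasis, no G x E), ``gxe_only``,
    ``gxg_only``, ``gxgxe``, ``figS1_counterexample`` (G x E and G x G
    present yet no G x G x E), and ``inversion`` (the three-mutation
    lock + destabilizer scenario with IPTG stabilization).
    """
    with resources.files("envepi.data").joinpath("presets.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {name: _parse_preset(entry) for name, entry in raw.items()}


def preset(name: str, **overrides) -> Params:
    """One preset, optionally with field overrides (e.g. seed, noise_cv)."""
    lib = scenario_library()
    try:
        p = lib[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(lib)}"
        ) from None
    return replace(p, **overrides) if overrides else p
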