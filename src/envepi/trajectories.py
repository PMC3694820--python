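"""Mutational trajectories and their accessibility to positive selection.

A trajectory is an ordering in which the variant's mutations are fixed
one at a time, from the wild type to the full mutant (L! orderings for L
mutations).  A step is *selectable* in an environment when the mutation's
effect there is beneficial — statistically significant and in the favored
direction; neutral steps are never positively selected and block a
trajectory.

Accessibility policies:

``constant`` (per environment)
    every step must be beneficial in that fixed environment;
``variable``
    every step must be beneficial in at least one environment, modelling
    free environmental change between fixation events (no switching cost
    or dwell time — the weakest constraint under which environmental
    variability can open trajectories).  The returned witness lists one
    environment per step that makes the trajectory selectable.

Any trajectory accessible in a constant environment is accessible under
the variable policy.  With ``require_benefit=False`` steps merely need to
avoid being significantly deleterious (sensitivity analysis only).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Union

from .effects import (
    BENEFICIAL,
    EffectsTable,
    SignificancePolicy,
    compute_effects,
)
from .gpmap import (
    ENV_0,
    ENV_1,
    ENVIRONMENTS,
    Environment,
    Genotype,
    GenotypePhenotypeMap,
    Variant,
)

__all__ = [
    "Trajectory",
    "enumerate_trajectories",
    "accessibility",
    "accessibility_report",
    "expression_profile",
]


@dataclass(frozen=True)
class Trajectory:
    """One mutation ordering with its intermediate genotypes."""

    ordering: tuple[str, ...]
    genotypes: tuple[Genotype, ...]  # length L + 1, wild type first

    @property
    def steps(self) -> list[tuple[Genotype, str, Genotype]]:
        return [
            (self.genotypes[i], self.ordering[i], self.genotypes[i + 1])
            for i in range(len(self.ordering))
        ]

    def reversed(self) -> "Trajectory":
        """The same path walked from the full mutant back to wild type.

        Note the 'mutations' of the reverse walk are reversions; it is
        only used to probe direction dependence on landscapes where both
        directions are measurable.
        """
        return Trajectory(
            tuple(reversed(self.ordering)), tuple(reversed(self.genotypes))
        )


def enumerate_trajectories(variant: Variant) -> list[Trajectory]:
    """All L! orderings, in lexicographic order of mutation positions."""
    out = []
    for perm in permutations(range(variant.n_mutations)):
        genotypes = [variant.wildtype()]
        for idx in perm:
            genotypes.append(genotypes[-1].with_mutation(idx))
        out.append(
            Trajectory(
                tuple(variant.mutation_names[i] for i in perm),
                tuple(genotypes),
            )
        )
    return out


def _step_beneficial(
    effects: EffectsTable,
    mutation: str,
    before: Genotype,
    after: Genotype,
    env: Environment,
    require_benefit: bool,
) -> bool:
    variant = effects.gpmap.variant
    idx = variant.index_of(mutation)
    if before.has(idx):
        # reversion step: judged from the forward effect, inverted.  The
        # reversion is beneficial iff the forward effect is significantly
        # in the disfavored direction; reverting a neutral stays neutral.
        eff = effects.get(mutation, after, env)
        favored = eff.significant and eff.sign != BENEFICIAL and eff.raw_direction != "none"
        if require_benefit:
            return favored
        return favored or not eff.significant
    eff = effects.get(mutation, before, env)
    if require_benefit:
        return eff.sign == BENEFICIAL
    # sensitivity mode: allow anything not significantly deleterious
    return eff.sign == BENEFICIAL or not eff.significant


def accessibility(
    gpmap: GenotypePhenotypeMap,
    trajectory: Trajectory,
    policy: str = "variable",
    environment: Optional[Environment] = None,
    effects: Optional[EffectsTable] = None,
    significance: SignificancePolicy = SignificancePolicy(),
    require_benefit: bool = True,
) -> tuple[bool, Optional[list[str]]]:
    """Is a trajectory open to stepwise positive selection?

    Returns ``(accessible, witness)``: for the variable policy the witness
    is one environment label per step under which every step is
    beneficial; for constant policies it is the fixed environment
    repeated.  Inaccessible trajectories return ``(False, None)``.
    """
    if policy not in ("constant", "variable"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "constant" and environment is None:
        raise ValueError("constant policy needs an environment")
    if effects is None:
        effects = compute_effects(gpmap, policy=significance)
    witness: list[str] = []
    for before, mutation, after in trajectory.steps:
        if policy == "constant":
            envs = [environment]
        else:
            envs = list(ENVIRONMENTS)
        chosen = None
        for env in envs:
            if _step_beneficial(effects, mutation, before, after, env, require_benefit):
                chosen = env.label
                break
        if chosen is None:
            return False, None
        witness.append(chosen)
    return True, witness


def accessibility_report(
    gpmap: GenotypePhenotypeMap,
    effects: Optional[EffectsTable] = None,
    significance: SignificancePolicy = SignificancePolicy(),
    require_benefit: bool = True,
) -> dict:
    """Accessible-trajectory counts under each policy, with witnesses."""
    if effects is None:
        effects = compute_effects(gpmap, policy=significance)
    trajectories = enumerate_trajectories(gpmap.variant)
    out = {
        "n_trajectories": len(trajectories),
        "policies": {},
        "witnesses": {},
    }
    for label, kwargs in (
        ("constant_Env_0", {"policy": "constant", "environment": ENV_0}),
        ("constant_Env_1", {"policy": "constant", "environment": ENV_1}),
        ("variable", {"policy": "variable"}),
    ):
        accessible = []
        witnesses = {}
        for traj in trajectories:
            ok, wit = accessibility(
                gpmap,
                traj,
                effects=effects,
                require_benefit=require_benefit,
                **kwargs,
            )
            if ok:
                accessible.append(traj.ordering)
                witnesses["->".join(traj.ordering)] = wit
        out["policies"][label] = len(accessible)
        out["witnesses"][label] = witnesses
    return out


def expression_profile(
    gpmap: GenotypePhenotypeMap,
    trajectory: Trajectory,
    environment: Environment,
) -> list[float]:
    """Normalized expression at each trajectory node (L + 1 values).

    Env_0 profiles report expression relative to the reference; Env_1
    profiles report inverse expression, matching the vertical axis of the
    vector plots, so progress toward inversion is an increase in either.
    """
    ref = gpmap.reference
    ref_mean = gpmap.mean(ref, environment)
    out = []
    for genotype in trajectory.genotypes:
        value = gpmap.mean(genotype, environment)
        if environment.label == ENV_1.label:
            out.append(ref_mean / value)
        else:
            out.append(value / ref_mean)
    return out
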