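"""Directional mutation effects: sign, magnitude and significance.

The selective objective is regulatory inversion: higher expression is
favored without inducer (``Env_0``) and lower expression is favored with
inducer (``Env_1``).  :class:`BenefitPolarity` encodes this and is
configurable for other objectives.

A mutation's effect in a given background and environment is summarized
as a :class:`DirectionalEffect`: the expression fold change, a two-sample
t-test p-value, a Bonferroni-corrected significance flag, and the benefit
sign.  Neutral (non-significant) effects are grouped under *deleterious*,
because neutral mutations are not fixed by positive selection.

The Bonferroni family is, by default, every mutation-effect test within
one variant's dataset across both environments (the most conservative
reading of a single classification panel); the family size is recorded on
the resulting table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .gpmap import (
    ENV_0,
    ENV_1,
    ENVIRONMENTS,
    Environment,
    ExpressionRecord,
    Genotype,
    GenotypePhenotypeMap,
    MutationLabel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BenefitPolarity",
    "INVERSION_POLARITY",
    "SignificancePolicy",
    "DirectionalEffect",
    "EffectsTable",
    "t_test_effect",
    "correct_multiplicity",
    "compute_effects",
    "effect",
    "pooled_significance_override",
]

BENEFICIAL = "beneficial"
DELETERIOUS = "deleterious"


@dataclass(frozen=True)
class BenefitPolarity:
    """Which expression direction counts as beneficial per environment.

    ``directions`` maps environment label to +1 (higher expression is
    beneficial) or -1 (lower expression is beneficial).
    """

    directions: dict  # env label -> +1 | -1

    def __post_init__(self) -> None:
        for env, d in self.directions.items():
            if d not in (+1, -1):
                raise ValueError(f"polarity for {env} must be +1 or -1, got {d}")

    def beneficial_direction(self, environment: Environment) -> int:
        return self.directions[environment.label]


#: The inversion objective: expression up is good without IPTG, down with it.
INVERSION_POLARITY = BenefitPolarity({ENV_0.label: +1, ENV_1.label: -1})


@dataclass(frozen=True)
class SignificancePolicy:
    """How significance is assessed.

    flavor
        ``"pooled"`` (Student t, pooled variance; stable at n = 3) or
        ``"welch"``.
    log_scale
        Test log-transformed expression.  Replicates are logged directly;
        summary records use the lognormal delta-method approximation
        (mean -> log mean - s^2/2 correction omitted, sd -> sd/mean).
    alpha
        Family-wise error rate for the Bonferroni correction.
    """

    flavor: str = "pooled"
    log_scale: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.flavor not in ("pooled", "welch"):
            raise ValueError(f"unknown t-test flavor {self.flavor!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _summary_stats(
    rec: ExpressionRecord, log_scale: bool
) -> tuple[float, float, int]:
    if rec.replicates is not None:
        vals = np.log(rec.replicates) if log_scale else np.asarray(rec.replicates)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return float(np.mean(vals)), sd, len(vals)
    mean, sd, n = rec.summary
    if log_scale:
        return math.log(mean), sd / mean, n
    return mean, sd, n


def t_test_effect(
    rec_a: ExpressionRecord,
    rec_b: ExpressionRecord,
    policy: SignificancePolicy = SignificancePolicy(),
) -> float:
    """Two-sided two-sample t-test p-value between two expression records.

    Computable from summary statistics alone; replicate-mode records with
    matching mean/sd/n give the identical statistic.  Degenerate case:
    when both sides have zero spread the p-value is 1.0 for equal means
    and 0.0 otherwise (any difference is then beyond doubt).
    """
    if rec_a.environment.label != rec_b.environment.label:
        raise ValueError(
            "records must share an environment "
            f"({rec_a.environment.label} vs {rec_b.environment.label})"
        )
    m_a, s_a, n_a = _summary_stats(rec_a, policy.log_scale)
    m_b, s_b, n_b = _summary_stats(rec_b, policy.log_scale)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"significance testing needs n >= 2 on both sides (got {n_a}, {n_b})"
        )
    if s_a == 0.0 and s_b == 0.0:
        return 1.0 if m_a == m_b else 0.0
    res = stats.ttest_ind_from_stats(
        m_a, s_a, n_a, m_b, s_b, n_b, equal_var=(policy.flavor == "pooled")
    )
    return float(res.pvalue)


def correct_multiplicity(
    p_values: Sequence[float], alpha: float = 0.05
) -> list[bool]:
    """Bonferroni significance flags: flag i is True iff p_i < alpha / m."""
    m = len(p_values)
    if m == 0:
        raise ValueError("empty p-value family")
    threshold = alpha / m
    return [p < threshold for p in p_values]


@dataclass(frozen=True)
class DirectionalEffect:
    """Sign + magnitude + significance of one mutation in one background."""

    mutation: str
    background: Genotype
    environment: Environment
    fold_change: float  # expression(bg + mutation) / expression(bg)
    p_value: float
    significant: bool
    raw_direction: str  # "up" | "down" | "none"
    sign: str  # BENEFICIAL | DELETERIOUS

    @property
    def beneficial(self) -> bool:
        return self.sign == BENEFICIAL


@dataclass
class EffectsTable:
    """All directional effects for one map, with a shared Bonferroni family."""

    gpmap: GenotypePhenotypeMap
    polarity: BenefitPolarity
    policy: SignificancePolicy
    family_size: int
    _effects: dict = field(default_factory=dict)

    def key(
        self, mutation: str, background: Genotype, environment: Environment
    ) -> tuple:
        return (mutation, background.bits, environment.label)

    def add(self, eff: DirectionalEffect) -> None:
        self._effects[self.key(eff.mutation, eff.background, eff.environment)] = eff

    def get(
        self, mutation: str, background: Genotype, environment: Environment
    ) -> DirectionalEffect:
        try:
            return self._effects[self.key(mutation, background, environment)]
        except KeyError:
            raise KeyError(
                f"no effect for {mutation} in background "
                f"{background.label(self.gpmap.variant) or '<wild type>'} "
                f"({environment.label})"
            ) from None

    def __iter__(self):
        return iter(self._effects.values())

    def __len__(self) -> int:
        return len(self._effects)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "mutation": e.mutation,
                    "background": e.background.label(self.gpmap.variant),
                    "environment": e.environment.label,
                    "fold_change": e.fold_change,
                    "p_raw": e.p_value,
                    "significant": e.significant,
                    "sign": e.sign,
                }
                for e in self
            ]
        )


def _raw_direction(fold_change: float) -> str:
    if fold_change > 1.0:
        return "up"
    if fold_change < 1.0:
        return "down"
    return "none"


def _sign(
    direction: str, significant: bool, polarity: BenefitPolarity, env: Environment
) -> str:
    if not significant or direction == "none":
        return DELETERIOUS  # neutral folds into deleterious
    wanted = "up" if polarity.beneficial_direction(env) > 0 else "down"
    return BENEFICIAL if direction == wanted else DELETERIOUS


def compute_effects(
    gpmap: GenotypePhenotypeMap,
    polarity: BenefitPolarity = INVERSION_POLARITY,
    policy: SignificancePolicy = SignificancePolicy(),
) -> EffectsTable:
    """Compute every mutation effect in every background and environment.

    All (mutation, background, environment) pairs with both genotypes
    measured contribute one t-test to a single Bonferroni family.
    """
    variant = gpmap.variant
    entries = []  # (mutation, background, env, fold, p)
    for i, mut in enumerate(variant.mutations):
        for background in variant.all_genotypes():
            if background.has(i):
                continue
            carrier = background.with_mutation(i)
            for env in ENVIRONMENTS:
                if not (gpmap.has(background, env) and gpmap.has(carrier, env)):
                    continue
                rec_bg = gpmap.get(background, env)
                rec_mut = gpmap.get(carrier, env)
                fold = rec_mut.mean / rec_bg.mean
                p = t_test_effect(rec_mut, rec_bg, policy)
                entries.append((mut.name, background, env, fold, p))
    if not entries:
        raise ValueError("no computable effects: map too sparse")
    flags = correct_multiplicity([e[4] for e in entries], alpha=policy.alpha)
    table = EffectsTable(gpmap, polarity, policy, family_size=len(entries))
    for (name, background, env, fold, p), sig in zip(entries, flags):
        direction = _raw_direction(fold)
        table.add(
            DirectionalEffect(
                mutation=name,
                background=background,
                environment=env,
                fold_change=fold,
                p_value=p,
                significant=sig,
                raw_direction=direction,
                sign=_sign(direction, sig, polarity, env),
            )
        )
    return table


def effect(
    gpmap: GenotypePhenotypeMap,
    mutation: "str | MutationLabel",
    background: Genotype,
    environment: Environment,
    polarity: BenefitPolarity = INVERSION_POLARITY,
    policy: SignificancePolicy = SignificancePolicy(),
    effects: Optional[EffectsTable] = None,
) -> DirectionalEffect:
    """Directional effect of one mutation (convenience lookup).

    Builds the full family-corrected table unless one is passed in, so the
    significance threshold is always the panel-wide Bonferroni one.
    """
    name = mutation.name if isinstance(mutation, MutationLabel) else mutation
    if effects is None:
        effects = compute_effects(gpmap, polarity, policy)
    return effects.get(name, background, environment)


def pooled_significance_override(
    tables: Sequence[EffectsTable],
    mutation: str,
    background_label: str,
    environment: Environment,
) -> bool:
    """Cross-dataset significance pooling for one shared effect.

    When the identical mutation/background/environment effect is measured
    in several variants' datasets and a majority of them call it
    significant with a consistent direction, the effect may be flagged
    significant in all of them.  Mirrors a one-off published rule for a
    shared mutation; opt-in, never applied silently.

    Returns True (and mutates the tables: significance and sign updated)
    if the override was applied.
    """
    if len(tables) < 2:
        return False  # nothing to pool
    found = []
    for table in tables:
        variant = table.gpmap.variant
        try:
            bg = variant.genotype(
                [t for t in background_label.split(";") if t]
            )
            found.append((table, table.get(mutation, bg, environment)))
        except KeyError:
            continue
    if len(found) < 2:
        return False
    sig = [(t, e) for t, e in found if e.significant]
    if len(sig) * 2 <= len(found):
        return False  # no majority
    directions = {e.raw_direction for _, e in sig}
    if len(directions) != 1:
        logger.warning(
            "cross-dataset override refused for %s: significant datasets "
            "disagree on direction (%s)",
            mutation,
            sorted(directions),
        )
        return False
    direction = directions.pop()
    for table, eff in found:
        if eff.significant:
            continue
        new = DirectionalEffect(
            mutation=eff.mutation,
            background=eff.background,
            environment=eff.environment,
            fold_change=eff.fold_change,
            p_value=eff.p_value,
            significant=True,
            raw_direction=direction,
            sign=_sign(direction, True, table.polarity, eff.environment),
        )
        table.add(new)
    return True
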