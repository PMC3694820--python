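"""Magnitude / sign / reciprocal-sign epistasis classification.

For a mutation pair (m1, m2) in a background where both are absent, the
four benefit signs

    s1  = sign(m1 | bg)        s1' = sign(m1 | bg + m2)
    s2  = sign(m2 | bg)        s2' = sign(m2 | bg + m1)

determine the category per environment:

* **R** (reciprocal sign): both mutations deleterious alone and both
  beneficial together (s1 = s2 = deleterious, s1' = s2' = beneficial) -
  the valley-crossing pattern, a necessary condition for multiple peaks.
* **S** (sign): exactly one mutation's sign depends on the other; the
  changing mutation is named.
* **M** (magnitude): neither sign is background-dependent.

A both-signs-change pattern that is not the canonical R orientation
(e.g. beneficial alone, deleterious together) is still labelled R but
carries ``beneficial_together = False`` and emits a warning, rather than
inventing a fourth category.

For a three-mutation variant this yields the familiar 6-motif panel:
3 pairs x 2 third-site backgrounds, each with two environment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Union

from .effects import (
    BENEFICIAL,
    DELETERIOUS,
    EffectsTable,
    INVERSION_POLARITY,
    SignificancePolicy,
    compute_effects,
)
from .gpmap import (
    ENVIRONMENTS,
    Environment,
    Genotype,
    GenotypePhenotypeMap,
    MutationLabel,
    Table1Fixture,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EpistasisCall",
    "ClassificationTable",
    "classify_pair",
    "classify_all",
    "environment_concordance",
]

# background-state glyphs used in the formatted panel output
_GLYPH_PAIR = "X"
_GLYPH_ABSENT = "○"  # open circle: wild type at the third site
_GLYPH_PRESENT = "•"  # bullet: third mutation present


@dataclass(frozen=True)
class EpistasisCall:
    """Category of one mutation pair in one background and environment."""

    pair: tuple[str, str]
    background: Genotype
    environment: Environment
    category: str  # "M" | "S" | "R"
    sign_changer: Optional[str]
    signs: dict  # {(mutation, "alone"|"with_other"): sign}
    #: Only meaningful for R: True for the canonical deleterious-alone /
    #: beneficial-together orientation.
    beneficial_together: Optional[bool] = None

    def __post_init__(self) -> None:
        if (self.category == "S") != (self.sign_changer is not None):
            raise ValueError("sign_changer must be set iff category is S")

    @property
    def label(self) -> str:
        """Category with the sign changer spelled out, e.g. ``S(T258A)``."""
        if self.category == "S":
            return f"S({self.sign_changer})"
        return self.category


def _name(mutation: Union[str, MutationLabel]) -> str:
    return mutation.name if isinstance(mutation, MutationLabel) else mutation


def classify_pair(
    gpmap: GenotypePhenotypeMap,
    m1: Union[str, MutationLabel],
    m2: Union[str, MutationLabel],
    background: Genotype,
    environment: Environment,
    effects: Optional[EffectsTable] = None,
    policy: SignificancePolicy = SignificancePolicy(),
) -> EpistasisCall:
    """Classify the epistatic interaction of one pair in one environment."""
    n1, n2 = _name(m1), _name(m2)
    variant = gpmap.variant
    i1, i2 = variant.index_of(n1), variant.index_of(n2)
    if background.has(i1) or background.has(i2):
        raise ValueError(
            f"background must not carry {n1} or {n2} "
            f"(got {background.label(variant) or '<wild type>'})"
        )
    if effects is None:
        effects = compute_effects(gpmap, policy=policy)
    bg_m1 = background.with_mutation(i1)
    bg_m2 = background.with_mutation(i2)

    s1 = effects.get(n1, background, environment).sign
    s1p = effects.get(n1, bg_m2, environment).sign
    s2 = effects.get(n2, background, environment).sign
    s2p = effects.get(n2, bg_m1, environment).sign

    changes1 = s1 != s1p
    changes2 = s2 != s2p
    signs = {
        (n1, "alone"): s1,
        (n1, "with_other"): s1p,
        (n2, "alone"): s2,
        (n2, "with_other"): s2p,
    }

    if changes1 and changes2:
        canonical = s1 == DELETERIOUS and s2 == DELETERIOUS
        if not canonical:
            logger.warning(
                "pair (%s, %s) in background %s / %s: both signs change but "
                "not in the deleterious-alone/beneficial-together "
                "orientation; labelled R with beneficial_together=False",
                n1,
                n2,
                background.label(variant) or "<wild type>",
                environment.label,
            )
        return EpistasisCall(
            (n1, n2), background, environment, "R", None, signs,
            beneficial_together=canonical,
        )
    if changes1 or changes2:
        changer = n1 if changes1 else n2
        return EpistasisCall((n1, n2), background, environment, "S", changer, signs)
    return EpistasisCall((n1, n2), background, environment, "M", None, signs)


@dataclass(frozen=True)
class MotifCalls:
    """One panel row: a pair + third-site background, both environments."""

    pair: tuple[str, str]
    background_mut: Optional[str]  # None for two-mutation variants
    background_present: bool
    calls: dict  # env label -> EpistasisCall


@dataclass
class ClassificationTable:
    """All epistasis calls for one variant, panel-style.

    For an L-mutation variant there are C(L,2) pairs; for each pair every
    genotype of the remaining sites serves as a background, giving the
    6 motif rows of the published panel when L = 3.
    """

    variant_name: str
    motifs: list[MotifCalls]

    def __len__(self) -> int:
        return len(self.motifs)

    def get_category(
        self,
        mut_a: str,
        mut_b: str,
        background_present: bool,
        env_label: str,
    ) -> tuple[str, Optional[str]]:
        """Category label + sign changer, fixture-compatible interface."""
        pair = {mut_a, mut_b}
        for motif in self.motifs:
            if set(motif.pair) == pair and motif.background_present == background_present:
                call = motif.calls[env_label]
                return call.category, call.sign_changer
        raise KeyError(
            f"no motif for pair ({mut_a}, {mut_b}) with background "
            f"{'present' if background_present else 'absent'}"
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for motif in self.motifs:
            row = {
                "variant": self.variant_name,
                "mut_a": motif.pair[0],
                "mut_b": motif.pair[1],
                "background_mut": motif.background_mut or "",
                "background_state": "present" if motif.background_present else "absent",
            }
            for env in ENVIRONMENTS:
                row[env.label] = motif.calls[env.label].label
            rows.append(row)
        return pd.DataFrame(rows)

    def format_panel(self, variant=None) -> str:
        """Panel-style text table with X / open-circle / bullet notation."""
        lines = [self.variant_name]
        muts = None
        if variant is not None:
            muts = list(variant.mutation_names)
        for motif in self.motifs:
            if muts is not None:
                glyphs = []
                for name in muts:
                    if name in motif.pair:
                        glyphs.append(_GLYPH_PAIR)
                    elif name == motif.background_mut:
                        glyphs.append(
                            _GLYPH_PRESENT if motif.background_present else _GLYPH_ABSENT
                        )
                    else:  # pragma: no cover - >3 mutations
                        glyphs.append("-")
                prefix = "\t".join(glyphs)
            else:
                state = "present" if motif.background_present else "absent"
                prefix = f"{motif.pair[0]} x {motif.pair[1]} | {motif.background_mut} {state}"
            cats = "\t".join(motif.calls[e.label].label for e in ENVIRONMENTS)
            lines.append(f"{prefix}\t{cats}")
        return "\n".join(lines)


#: Printed panel row order for a 3-mutation variant, as (pair indices,
#: background state): mirrors the published table layout.
_PANEL_ORDER_3 = [
    ((0, 1), False),
    ((0, 2), False),
    ((1, 2), True),
    ((0, 2), True),
    ((1, 2), False),
    ((0, 1), True),
]


def classify_all(
    gpmap: GenotypePhenotypeMap,
    effects: Optional[EffectsTable] = None,
    policy: SignificancePolicy = SignificancePolicy(),
) -> ClassificationTable:
    """Classify every pair in every third-site background and environment."""
    missing = gpmap.missing()
    if missing:
        labels = sorted(
            f"{g.label(gpmap.variant) or '<wild type>'}/{e.label}"
            for g, e in missing
        )
        raise ValueError(f"map is incomplete; missing measurements: {labels}")
    if effects is None:
        effects = compute_effects(gpmap, policy=policy)
    variant = gpmap.variant
    L = variant.n_mutations

    if L == 3:
        ordering = _PANEL_ORDER_3
    else:
        ordering = None

    motifs: list[MotifCalls] = []

    def motif_for(i: int, j: int, background: Genotype) -> MotifCalls:
        others = [k for k in range(L) if k not in (i, j)]
        if len(others) == 1:
            bg_mut = variant.mutation_names[others[0]]
            bg_present = background.has(others[0])
        elif not others:
            bg_mut, bg_present = None, False
        else:
            bg_mut = ";".join(
                variant.mutation_names[k] for k in others if background.has(k)
            ) or None
            bg_present = any(background.has(k) for k in others)
        calls = {
            env.label: classify_pair(
                gpmap,
                variant.mutation_names[i],
                variant.mutation_names[j],
                background,
                env,
                effects=effects,
            )
            for env in ENVIRONMENTS
        }
        return MotifCalls(
            (variant.mutation_names[i], variant.mutation_names[j]),
            bg_mut,
            bg_present,
            calls,
        )

    if ordering is not None:
        for (i, j), present in ordering:
            k = next(x for x in range(L) if x not in (i, j))
            background = variant.wildtype()
            if present:
                background = background.with_mutation(k)
            motifs.append(motif_for(i, j, background))
    else:
        for i, j in combinations(range(L), 2):
            for background in variant.all_genotypes():
                if background.has(i) or background.has(j):
                    continue
                motifs.append(motif_for(i, j, background))

    return ClassificationTable(variant.name, motifs)


def environment_concordance(
    table: Union[ClassificationTable, Table1Fixture, Sequence],
) -> tuple[int, int, list]:
    """Count motifs whose category label is the same in both environments.

    Only the M/S/R letter is compared (an S motif counts as concordant even
    if a different mutation changes sign in each environment — though no
    such motif occurs in the published panel).  Returns
    ``(n_same, n_total, discordant)`` where each discordant entry is
    ``(descriptor, category_env0, category_env1)``.
    """
    if isinstance(table, ClassificationTable):
        items = [
            (
                f"{m.pair[0]}x{m.pair[1]}|"
                f"{m.background_mut or ''}:"
                f"{'present' if m.background_present else 'absent'}",
                m.calls[ENVIRONMENTS[0].label].category,
                m.calls[ENVIRONMENTS[1].label].category,
            )
            for m in table.motifs
        ]
    elif isinstance(table, Table1Fixture):
        items = [
            (
                f"{r.variant}:{r.mut_a}x{r.mut_b}|{r.background_mut}:"
                f"{'present' if r.background_present else 'absent'}",
                r.category_env0,
                r.category_env1,
            )
            for r in table.rows
        ]
    else:
        items = [(str(i), c0, c1) for i, (c0, c1) in enumerate(table)]
    discordant = [(d, c0, c1) for d, c0, c1 in items if c0 != c1]
    n_total = len(items)
    return n_total - len(discordant), n_total, discordant
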