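"""Purely genetic third-order interactions and their environment dependence.

A G x G x G interaction is present when adding a third (modifier)
mutation changes the category of a pair's two-way epistatic motif in a
fixed environment; when that third-order status itself differs between
the two environments the interaction is G x G x G x E.

By default the comparison includes the identity of the sign changer
(``S(A)`` versus ``S(B)`` counts as a change): a shift in *which*
mutation is conditional is a real third-order effect even when both
motifs carry the letter S.  Set ``compare_changer=False`` to compare the
M/S/R letter only; reports emit both modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Union

from .classify import ClassificationTable
from .gpmap import ENVIRONMENTS, Environment, Table1Fixture

__all__ = ["TripleInteraction", "detect_gxgxg", "detect_gxgxgxe", "all_triples"]


def _category_label(cat: str, changer) -> str:
    return f"S({changer})" if cat == "S" else cat


@dataclass(frozen=True)
class TripleInteraction:
    pair: tuple[str, str]
    modifier: str
    environment_label: str
    category_without: str  # full label, e.g. "S(L349P)" or "M"
    category_with: str
    gxgxg: bool


def detect_gxgxg(
    table: Union[ClassificationTable, Table1Fixture],
    m1: str,
    m2: str,
    m3: str,
    environment: Environment,
    compare_changer: bool = True,
    variant_name: str | None = None,
) -> TripleInteraction:
    """Does adding ``m3`` change the epistasis category of (m1, m2)?"""

    def lookup(present: bool) -> str:
        if isinstance(table, Table1Fixture):
            if variant_name is None:
                raise ValueError("variant_name required with a fixture table")
            cat, changer = table.get_category(
                variant_name, m1, m2, present, environment.label
            )
        else:
            cat, changer = table.get_category(m1, m2, present, environment.label)
        return _category_label(cat, changer) if compare_changer else cat

    without_m3 = lookup(False)
    with_m3 = lookup(True)
    return TripleInteraction(
        pair=(m1, m2),
        modifier=m3,
        environment_label=environment.label,
        category_without=without_m3,
        category_with=with_m3,
        gxgxg=(without_m3 != with_m3),
    )


def detect_gxgxgxe(
    table: Union[ClassificationTable, Table1Fixture],
    m1: str,
    m2: str,
    m3: str,
    compare_changer: bool = True,
    variant_name: str | None = None,
) -> bool:
    """True iff the G x G x G status differs between the two environments."""
    statuses = [
        detect_gxgxg(
            table, m1, m2, m3, env, compare_changer, variant_name
        ).gxgxg
        for env in ENVIRONMENTS
    ]
    return statuses[0] != statuses[1]


def all_triples(
    table: ClassificationTable,
    mutation_names: tuple[str, ...],
    compare_changer: bool = True,
):
    """Report every (pair, modifier) triple of a variant as a DataFrame.

    A 3-mutation variant has exactly 3 triples per environment.
    """
    import pandas as pd

    rows = []
    for i, j in combinations(range(len(mutation_names)), 2):
        others = [k for k in range(len(mutation_names)) if k not in (i, j)]
        for k in others:
            m1, m2, m3 = mutation_names[i], mutation_names[j], mutation_names[k]
            per_env = {
                env.label: detect_gxgxg(table, m1, m2, m3, env, compare_changer)
                for env in ENVIRONMENTS
            }
            gxgxgxe = (
                per_env[ENVIRONMENTS[0].label].gxgxg
                != per_env[ENVIRONMENTS[1].label].gxgxg
            )
            for env in ENVIRONMENTS:
                t = per_env[env.label]
                rows.append(
                    {
                        "mut_a": m1,
                        "mut_b": m2,
                        "modifier": m3,
                        "environment": env.label,
                        "category_without_modifier": t.category_without,
                        "category_with_modifier": t.category_with,
                        "gxgxg": t.gxgxg,
                        "gxgxgxe": gxgxgxe,
                    }
                )
    return pd.DataFrame(rows)
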