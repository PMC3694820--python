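"""The mutational-vector / polygon method for G x E interactions.

Every mutation in a given background is a vector in the plane

    x = expression in Env_0 (normalized to the reference),
    y = 1 / expression in Env_1 (normalized),

so that movement to the upper right is movement toward the inversion
objective.  The vector's *quadrant* is assigned from the two statistical
benefit signs, not from the raw geometry, so that mutations neutral on an
axis land on the deleterious side of that axis:

    I   beneficial in both environments
    II  beneficial in Env_1 only
    III deleterious (or neutral) in both
    IV  beneficial in Env_0 only

Quadrants II and IV are sign-changing G x E interactions.  The two
mutational paths ab -> Ab -> AB and ab -> aB -> AB form a four-sided
polygon whose opposing sides are the same mutation in the two backgrounds;
opposing sides in different quadrants indicate sign epistasis (G x G), and
if additionally one of them lies in II or IV the interaction is
environment-dependent (G x G x E).  G x E together with G x G does *not*
imply G x G x E (see the counterexample preset in
:mod:`envepi.simulate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
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
    Genotype,
    GenotypePhenotypeMap,
    MutationLabel,
)

__all__ = [
    "MutationVector",
    "PolygonMotif",
    "PolygonCensus",
    "mutation_vector",
    "detect_gxe",
    "build_polygon",
    "detect_gxg",
    "detect_gxgxe",
    "polygon_census",
]

QUADRANTS = ("I", "II", "III", "IV")

#: tolerance for the polygon-closure identity in log coordinates
CLOSURE_TOL = 1e-9


def _quadrant(x_beneficial: bool, y_beneficial: bool) -> str:
    if x_beneficial and y_beneficial:
        return "I"
    if y_beneficial:
        return "II"
    if x_beneficial:
        return "IV"
    return "III"


@dataclass(frozen=True)
class MutationVector:
    """One mutation's displacement in the two-environment effect plane."""

    mutation: str
    background: Genotype
    start: tuple[float, float]
    end: tuple[float, float]
    dx_sign: str  # benefit sign on the Env_0 axis
    dy_sign: str  # benefit sign on the Env_1 axis
    quadrant: str

    @property
    def log_displacement(self) -> tuple[float, float]:
        return (
            math.log(self.end[0]) - math.log(self.start[0]),
            math.log(self.end[1]) - math.log(self.start[1]),
        )

    @property
    def zero_length(self) -> bool:
        return self.start == self.end


def _coords(
    gpmap: GenotypePhenotypeMap, genotype: Genotype, ref: Genotype
) -> tuple[float, float]:
    x = gpmap.mean(genotype, ENV_0) / gpmap.mean(ref, ENV_0)
    # inverse expression on the vertical axis, normalized so the reference
    # sits at (1, 1)
    y = gpmap.mean(ref, ENV_1) / gpmap.mean(genotype, ENV_1)
    return x, y


def mutation_vector(
    gpmap: GenotypePhenotypeMap,
    mutation: Union[str, MutationLabel],
    background: Genotype,
    effects: Optional[EffectsTable] = None,
    policy: SignificancePolicy = SignificancePolicy(),
) -> MutationVector:
    """Vector of one mutation in one background, with quadrant."""
    name = mutation.name if isinstance(mutation, MutationLabel) else mutation
    variant = gpmap.variant
    idx = variant.index_of(name)
    if background.has(idx):
        raise ValueError(f"background already carries {name}")
    if effects is None:
        effects = compute_effects(gpmap, policy=policy)
    carrier = background.with_mutation(idx)
    ref = gpmap.reference
    start = _coords(gpmap, background, ref)
    end = _coords(gpmap, carrier, ref)
    e0 = effects.get(name, background, ENV_0)
    e1 = effects.get(name, background, ENV_1)
    dx_ben = e0.sign == BENEFICIAL
    dy_ben = e1.sign == BENEFICIAL
    return MutationVector(
        mutation=name,
        background=background,
        start=start,
        end=end,
        dx_sign=e0.sign,
        dy_sign=e1.sign,
        quadrant=_quadrant(dx_ben, dy_ben),
    )


def detect_gxe(vector: MutationVector) -> bool:
    """Sign-changing genotype x environment interaction (quadrant II or IV)."""
    return vector.quadrant in ("II", "IV")


@dataclass(frozen=True)
class PolygonMotif:
    """The ab -> AB quadrilateral for one pair in one background."""

    pair: tuple[str, str]
    background: Genotype
    #: vectors keyed by (mutation, other_present)
    vectors: dict

    def vector(self, mutation: str, other_present: bool) -> MutationVector:
        return self.vectors[(mutation, other_present)]

    @property
    def opposing_pairs(self) -> list[tuple[MutationVector, MutationVector]]:
        m1, m2 = self.pair
        return [
            (self.vector(m1, False), self.vector(m1, True)),
            (self.vector(m2, False), self.vector(m2, True)),
        ]

    @property
    def closure_error(self) -> float:
        """Max |log-coordinate mismatch| between the two paths ab -> AB."""
        m1, m2 = self.pair
        a = self.vector(m1, False).log_displacement
        b = self.vector(m2, True).log_displacement
        c = self.vector(m2, False).log_displacement
        d = self.vector(m1, True).log_displacement
        return max(
            abs((a[0] + b[0]) - (c[0] + d[0])),
            abs((a[1] + b[1]) - (c[1] + d[1])),
        )

    @property
    def has_gxe(self) -> bool:
        return any(detect_gxe(v) for v in self.vectors.values())

    @property
    def has_gxg(self) -> bool:
        return detect_gxg(self)

    @property
    def has_gxgxe(self) -> bool:
        return detect_gxgxe(self)


def build_polygon(
    gpmap: GenotypePhenotypeMap,
    m1: Union[str, MutationLabel],
    m2: Union[str, MutationLabel],
    background: Genotype,
    effects: Optional[EffectsTable] = None,
    policy: SignificancePolicy = SignificancePolicy(),
) -> PolygonMotif:
    """Build the four-vector polygon for a pair in a background."""
    n1 = m1.name if isinstance(m1, MutationLabel) else m1
    n2 = m2.name if isinstance(m2, MutationLabel) else m2
    variant = gpmap.variant
    i1, i2 = variant.index_of(n1), variant.index_of(n2)
    if background.has(i1) or background.has(i2):
        raise ValueError("background must not carry either pair mutation")
    if effects is None:
        effects = compute_effects(gpmap, policy=policy)
    vectors = {
        (n1, False): mutation_vector(gpmap, n1, background, effects),
        (n1, True): mutation_vector(
            gpmap, n1, background.with_mutation(i2), effects
        ),
        (n2, False): mutation_vector(gpmap, n2, background, effects),
        (n2, True): mutation_vector(
            gpmap, n2, background.with_mutation(i1), effects
        ),
    }
    motif = PolygonMotif((n1, n2), background, vectors)
    if motif.closure_error > CLOSURE_TOL:  # pragma: no cover - defensive
        raise AssertionError(
            f"polygon closure violated ({motif.closure_error:.3e}) for "
            f"pair ({n1}, {n2})"
        )
    return motif


def detect_gxg(polygon: PolygonMotif) -> bool:
    """Sign epistasis: some opposing pair lies in different quadrants."""
    return any(a.quadrant != b.quadrant for a, b in polygon.opposing_pairs)


def detect_gxgxe(polygon: PolygonMotif) -> bool:
    """Environment-dependent sign epistasis.

    True iff some opposing pair is split between quadrants *and* at least
    one vector of that split pair lies in quadrant II or IV.
    """
    for a, b in polygon.opposing_pairs:
        if a.quadrant != b.quadrant and (detect_gxe(a) or detect_gxe(b)):
            return True
    return False


@dataclass
class PolygonCensus:
    """Counts of split / G x G x E opposing vector pairs for one map.

    ``rooting`` selects which third-site backgrounds define the polygons:
    ``"absent"`` (pair analyzed with the remaining site wild type),
    ``"present"`` (remaining mutation present), or ``"both"``.
    """

    variant_name: str
    rooting: str
    polygons: list[PolygonMotif]

    @property
    def n_polygons(self) -> int:
        return len(self.polygons)

    @property
    def opposing_pairs(self) -> list[tuple[MutationVector, MutationVector]]:
        return [p for poly in self.polygons for p in poly.opposing_pairs]

    @property
    def n_opposing_pairs(self) -> int:
        return len(self.opposing_pairs)

    @property
    def n_split(self) -> int:
        return sum(1 for a, b in self.opposing_pairs if a.quadrant != b.quadrant)

    @property
    def n_gxgxe(self) -> int:
        return sum(
            1
            for a, b in self.opposing_pairs
            if a.quadrant != b.quadrant and (detect_gxe(a) or detect_gxe(b))
        )

    @property
    def fraction_lacking_gxgxe_signature(self) -> float:
        """Fraction of opposing pairs that point in the same quadrant."""
        n = self.n_opposing_pairs
        return (n - self.n_split) / n if n else float("nan")

    def summary(self) -> dict:
        return {
            "variant": self.variant_name,
            "rooting": self.rooting,
            "n_polygons": self.n_polygons,
            "n_opposing_pairs": self.n_opposing_pairs,
            "n_split": self.n_split,
            "n_gxgxe": self.n_gxgxe,
            "fraction_lacking_gxgxe_signature": self.fraction_lacking_gxgxe_signature,
        }


def polygon_census(
    gpmap: GenotypePhenotypeMap,
    rooting: str = "present",
    effects: Optional[EffectsTable] = None,
    policy: SignificancePolicy = SignificancePolicy(),
) -> PolygonCensus:
    """Census of opposing vector pairs over a complete map.

    For a 3-mutation variant the default rooting gives 3 polygons (one per
    pair, with the remaining mutation present, where the published
    examples are narrated) and hence 6 opposing pairs; ``rooting="both"``
    counts all 6 motif polygons.
    """
    if rooting not in ("absent", "present", "both"):
        raise ValueError(f"unknown rooting {rooting!r}")
    missing = gpmap.missing()
    if missing:
        raise ValueError(f"map is incomplete ({len(missing)} missing records)")
    if effects is None:
        effects = compute_effects(gpmap, policy=policy)
    variant = gpmap.variant
    L = variant.n_mutations
    polygons = []
    for i, j in combinations(range(L), 2):
        others = [k for k in range(L) if k not in (i, j)]
        backgrounds = [variant.wildtype()]
        for k in others:
            if rooting == "absent":
                continue
            new = []
            for bg in backgrounds:
                if rooting == "both":
                    new.append(bg)
                new.append(bg.with_mutation(k))
            backgrounds = new
        for bg in backgrounds:
            polygons.append(
                build_polygon(
                    gpmap,
                    variant.mutation_names[i],
                    variant.mutation_names[j],
                    bg,
                    effects,
                )
            )
    return PolygonCensus(variant.name, rooting, polygons)
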