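"""Core data model for multi-environment genotype-phenotype maps.

A :class:`GenotypePhenotypeMap` holds expression measurements for every
combination of a small set of defining mutations (a :class:`Variant`),
measured in two environments (here: growth without IPTG, ``Env_0``, and
with 1 mM IPTG, ``Env_1``).  Measurements are either raw replicate values
or summary statistics (mean, sd, n); both are first-class because
published supplementary tables typically report summaries only.

Expression units are arbitrary: every downstream decision is a ratio or a
within-environment comparison, so maps may be analyzed raw or normalized
to the wild-type level (:meth:`GenotypePhenotypeMap.normalize`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import product
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "Environment",
    "ENV_0",
    "ENV_1",
    "ENVIRONMENTS",
    "MutationLabel",
    "Variant",
    "Genotype",
    "ExpressionRecord",
    "GenotypePhenotypeMap",
    "Table1Row",
    "Table1Fixture",
    "load_table1_fixture",
]


@dataclass(frozen=True)
class Environment:
    """A growth condition; exactly two are used per analysis."""

    label: str
    iptg_mM: float = 0.0


#: No inducer present.
ENV_0 = Environment("Env_0", 0.0)
#: 1 mM IPTG present.
ENV_1 = Environment("Env_1", 1.0)
#: Canonical environment order used everywhere.
ENVIRONMENTS = (ENV_0, ENV_1)

_ENV_BY_LABEL = {e.label: e for e in ENVIRONMENTS}


def environment_from_label(label: str) -> Environment:
    try:
        return _ENV_BY_LABEL[label]
    except KeyError:
        raise ValueError(
            f"unknown environment label {label!r}; expected one of "
            f"{sorted(_ENV_BY_LABEL)}"
        ) from None


@dataclass(frozen=True)
class MutationLabel:
    """A single point mutation, e.g. ``S97P``. ``color`` is a plot hint."""

    name: str
    color: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("mutation name must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class Variant:
    """A named variant defined by an ordered list of mutations.

    The order fixes genotype bit positions: bit *i* of a genotype is 1 iff
    the *i*-th mutation of ``mutations`` is present.
    """

    name: str
    mutations: tuple[MutationLabel, ...]

    def __post_init__(self) -> None:
        if len(self.mutations) < 2:
            raise ValueError("a variant needs at least two mutations")
        names = [m.name for m in self.mutations]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate mutation names in variant {self.name!r}")

    @classmethod
    def from_names(cls, name: str, mutation_names: Sequence[str]) -> "Variant":
        return cls(name, tuple(MutationLabel(n) for n in mutation_names))

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def mutation_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.mutations)

    def index_of(self, mutation: "str | MutationLabel") -> int:
        name = mutation.name if isinstance(mutation, MutationLabel) else mutation
        try:
            return self.mutation_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown mutation {name!r} for variant {self.name!r} "
                f"(defined: {list(self.mutation_names)})"
            ) from None

    def genotype(self, mutation_names: Iterable[str] = ()) -> "Genotype":
        """Genotype carrying exactly the given mutations (empty = wild type)."""
        bits = [0] * self.n_mutations
        for n in mutation_names:
            bits[self.index_of(n)] = 1
        return Genotype(tuple(bits))

    def wildtype(self) -> "Genotype":
        return Genotype((0,) * self.n_mutations)

    def full_mutant(self) -> "Genotype":
        return Genotype((1,) * self.n_mutations)

    def all_genotypes(self) -> list["Genotype"]:
        return [Genotype(bits) for bits in product((0, 1), repeat=self.n_mutations)]


@dataclass(frozen=True)
class Genotype:
    """Binary presence vector over a variant's ordered mutation list."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"genotype bits must be 0/1, got {self.bits}")

    @property
    def n_mutations_present(self) -> int:
        return sum(self.bits)

    def has(self, index: int) -> bool:
        return bool(self.bits[index])

    def with_mutation(self, index: int) -> "Genotype":
        if self.bits[index]:
            raise ValueError(f"mutation at position {index} already present")
        bits = list(self.bits)
        bits[index] = 1
        return Genotype(tuple(bits))

    def label(self, variant: Variant) -> str:
        """Human-readable label: semicolon-joined names, '' for wild type."""
        return ";".join(
            n for n, b in zip(variant.mutation_names, self.bits) if b
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "".join(str(b) for b in self.bits)


@dataclass(frozen=True)
class ExpressionRecord:
    """One genotype measured in one environment.

    Either ``replicates`` (raw values) or the (``mean``, ``sd``, ``n``)
    summary triple is stored; the summary properties work for both.
    """

    genotype: Genotype
    environment: Environment
    replicates: Optional[tuple[float, ...]] = None
    summary: Optional[tuple[float, float, int]] = None  # (mean, sd, n)

    def __post_init__(self) -> None:
        if (self.replicates is None) == (self.summary is None):
            raise ValueError("provide exactly one of replicates or summary")
        if self.replicates is not None:
            if len(self.replicates) < 1:
                raise ValueError("at least one replicate required")
            if any(v <= 0 for v in self.replicates):
                raise ValueError(
                    f"expression values must be strictly positive, got "
                    f"{self.replicates}"
                )
        else:
            mean, sd, n = self.summary
            if mean <= 0:
                raise ValueError(f"mean expression must be positive, got {mean}")
            if sd < 0:
                raise ValueError(f"sd must be non-negative, got {sd}")
            if n < 1:
                raise ValueError(f"n must be >= 1, got {n}")

    @property
    def mean(self) -> float:
        if self.replicates is not None:
            return sum(self.replicates) / len(self.replicates)
        return self.summary[0]

    @property
    def sd(self) -> float:
        if self.replicates is not None:
            n = len(self.replicates)
            if n == 1:
                return 0.0
            m = self.mean
            return math.sqrt(sum((v - m) ** 2 for v in self.replicates) / (n - 1))
        return self.summary[1]

    @property
    def n(self) -> int:
        if self.replicates is not None:
            return len(self.replicates)
        return self.summary[2]

    def scaled(self, factor: float) -> "ExpressionRecord":
        """Record with every expression value multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        if self.replicates is not None:
            return replace(
                self, replicates=tuple(v * factor for v in self.replicates)
            )
        mean, sd, n = self.summary
        return replace(self, summary=(mean * factor, sd * factor, n))


class GenotypePhenotypeMap:
    """Expression measurements indexed by (genotype, environment)."""

    def __init__(
        self,
        variant: Variant,
        records: Iterable[ExpressionRecord] = (),
        reference: Optional[Genotype] = None,
    ) -> None:
        self.variant = variant
        self.reference = reference if reference is not None else variant.wildtype()
        self._records: dict[tuple[tuple[int, ...], str], ExpressionRecord] = {}
        for rec in records:
            self.add(rec)

    # -- container protocol -------------------------------------------------
    def add(self, record: ExpressionRecord) -> None:
        if len(record.genotype.bits) != self.variant.n_mutations:
            raise ValueError(
                f"genotype length {len(record.genotype.bits)} does not match "
                f"variant {self.variant.name!r} with "
                f"{self.variant.n_mutations} mutations"
            )
        key = (record.genotype.bits, record.environment.label)
        if key in self._records:
            raise ValueError(
                "duplicate record for genotype "
                f"{record.genotype.label(self.variant) or '<wild type>'} in "
                f"{record.environment.label}"
            )
        self._records[key] = record

    def get(self, genotype: Genotype, environment: Environment) -> ExpressionRecord:
        key = (genotype.bits, environment.label)
        try:
            return self._records[key]
        except KeyError:
            raise KeyError(
                "no measurement for genotype "
                f"{genotype.label(self.variant) or '<wild type>'} in "
                f"{environment.label}"
            ) from None

    def has(self, genotype: Genotype, environment: Environment) -> bool:
        return (genotype.bits, environment.label) in self._records

    def __iter__(self) -> Iterator[ExpressionRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    # -- completeness -------------------------------------------------------
    def missing(self) -> list[tuple[Genotype, Environment]]:
        out = []
        for g in self.variant.all_genotypes():
            for env in ENVIRONMENTS:
                if not self.has(g, env):
                    out.append((g, env))
        return out

    @property
    def complete(self) -> bool:
        return not self.missing()

    # -- normalization ------------------------------------------------------
    def normalize(self) -> "GenotypePhenotypeMap":
        """Divide every value by the reference mean in the same environment.

        The reference genotype maps to mean 1.0 in both environments;
        replicate structure and relative spread are preserved.  Idempotent.
        """
        ref_means = {}
        for env in ENVIRONMENTS:
            try:
                ref_means[env.label] = self.get(self.reference, env).mean
            except KeyError:
                raise ValueError(
                    "reference genotype "
                    f"{self.reference.label(self.variant) or '<wild type>'} "
                    f"not measured in {env.label}; cannot normalize"
                ) from None
        out = GenotypePhenotypeMap(self.variant, reference=self.reference)
        for rec in self:
            out.add(rec.scaled(1.0 / ref_means[rec.environment.label]))
        return out

    def mean(self, genotype: Genotype, environment: Environment) -> float:
        return self.get(genotype, environment).mean


# ---------------------------------------------------------------------------
# Embedded classification fixture (three LacI inverse variants)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Row:
    """One epistasis motif: a mutation pair in a fixed third-site background,
    with its category in each environment."""

    variant: str
    mut_a: str
    mut_b: str
    background_mut: str
    background_present: bool
    category_env0: str
    sign_changer_env0: Optional[str]
    category_env1: str
    sign_changer_env1: Optional[str]

    def category(self, env_label: str) -> str:
        return self.category_env0 if env_label == ENV_0.label else self.category_env1

    def sign_changer(self, env_label: str) -> Optional[str]:
        return (
            self.sign_changer_env0
            if env_label == ENV_0.label
            else self.sign_changer_env1
        )


@dataclass(frozen=True)
class Table1Fixture:
    """The published 18-motif classification of the three inverse LacI
    variants (6 motifs per variant, two environment columns each)."""

    rows: tuple[Table1Row, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.rows)

    def for_variant(self, variant: str) -> tuple[Table1Row, ...]:
        return tuple(r for r in self.rows if r.variant == variant)

    def get_category(
        self,
        variant: str,
        mut_a: str,
        mut_b: str,
        background_present: bool,
        env_label: str,
    ) -> tuple[str, Optional[str]]:
        pair = {mut_a, mut_b}
        for r in self.rows:
            if (
                r.variant == variant
                and {r.mut_a, r.mut_b} == pair
                and r.background_present == background_present
            ):
                return r.category(env_label), r.sign_changer(env_label)
        raise KeyError(
            f"no fixture motif for {variant} pair ({mut_a}, {mut_b}) with "
            f"background {'present' if background_present else 'absent'}"
        )


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged 18-row classification fixture.

    The CSV ships in long format (one row per motif x environment); rows are
    pivoted back to one entry per motif with both environment categories.
    """
    with resources.files("envepi.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    rows = []
    key_cols = ["variant", "mut_a", "mut_b", "background_mut", "background_state"]
    for (variant, a, b, bg, state), grp in df.groupby(key_cols, sort=False):
        by_env = {r["env"]: r for _, r in grp.iterrows()}
        if set(by_env) != {ENV_0.label, ENV_1.label}:
            raise ValueError(
                f"fixture motif {variant}/{a}/{b} lacks one environment"
            )

        def _cat(env: str) -> tuple[str, Optional[str]]:
            cat = by_env[env]["category"]
            changer = by_env[env]["sign_changer"] or None
            if cat not in ("M", "S", "R"):
                raise ValueError(f"bad category {cat!r} in fixture")
            if (cat == "S") != (changer is not None):
                raise ValueError(
                    f"sign_changer must be present iff category is S "
                    f"({variant}/{a}/{b}/{env})"
                )
            return cat, changer

        c0, ch0 = _cat(ENV_0.label)
        c1, ch1 = _cat(ENV_1.label)
        rows.append(
            Table1Row(
                variant=variant,
                mut_a=a,
                mut_b=b,
                background_mut=bg,
                background_present=(state == "present"),
                category_env0=c0,
                sign_changer_env0=ch0,
                category_env1=c1,
                sign_changer_env1=ch1,
            )
        )
    return Table1Fixture(tuple(rows))


#: The three published inverse variants, in the order their mutations define
#: genotype bit positions.
LACI_VARIANTS = {
    "LacI_inv1": Variant.from_names("LacI_inv1", ["S97P", "R207L", "T258A"]),
    "LacI_inv2": Variant.from_names("LacI_inv2", ["S97P", "L307H", "L349P"]),
    "LacI_inv3": Variant.from_names("LacI_inv3", ["S97P", "G315D", "P339H"]),
}
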