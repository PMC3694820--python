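"""Reading and writing genotype-phenotype map tables.

The on-disk dialect is a TSV/CSV with a header and one row per
(genotype, environment):

* a genotype column, either semicolon-separated mutation names
  (``"S97P;T258A"``, empty string = wild type) or a bitstring (``"101"``);
* an environment column (``Env_0`` / ``Env_1``);
* then either one column per replicate value, or ``mean``/``sd``/``n``
  summary columns.

Replicate-mode and summary-mode rows may coexist in one file.  Column
names are remappable via :class:`FormatConfig` (YAML configs are accepted
by the CLI); the defaults match what :func:`write_gpmap` emits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .gpmap import (
    ENVIRONMENTS,
    ExpressionRecord,
    Genotype,
    GenotypePhenotypeMap,
    Variant,
    environment_from_label,
)

__all__ = ["FormatConfig", "read_gpmap", "write_gpmap"]


@dataclass
class FormatConfig:
    """Column mapping for gpmap tables."""

    genotype_col: str = "genotype"
    env_col: str = "environment"
    #: explicit replicate column names; None = every column starting with "rep"
    replicate_cols: Optional[Sequence[str]] = None
    mean_col: str = "mean"
    sd_col: str = "sd"
    n_col: str = "n"
    #: "names" (semicolon-separated tokens) or "bits" (e.g. "101")
    genotype_style: str = "names"
    #: field separator; None = infer from file extension (.csv -> ",")
    sep: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "FormatConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown format config keys: {sorted(unknown)}")
        return cls(**d)


def _infer_sep(path: Path, config: FormatConfig) -> str:
    if config.sep is not None:
        return config.sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_genotype(token: str, variant: Variant, style: str) -> Genotype:
    token = (token or "").strip()
    if style == "bits":
        if token and (set(token) - {"0", "1"} or len(token) != variant.n_mutations):
            raise ValueError(
                f"bad genotype bitstring {token!r} for variant {variant.name!r}"
            )
        bits = tuple(int(c) for c in token) if token else (0,) * variant.n_mutations
        return Genotype(bits)
    names = [t.strip() for t in token.split(";") if t.strip()] if token else []
    return variant.genotype(names)


def _infer_variant(df: pd.DataFrame, config: FormatConfig) -> Variant:
    """Build a variant from mutation tokens in order of first appearance."""
    seen: list[str] = []
    for token in df[config.genotype_col].fillna(""):
        for name in str(token).split(";"):
            name = name.strip()
            if name and name not in seen:
                seen.append(name)
    if len(seen) < 2:
        raise ValueError(
            "cannot infer a variant: fewer than two distinct mutation tokens "
            "in the genotype column; pass a Variant explicitly"
        )
    return Variant.from_names("inferred", seen)


def read_gpmap(
    path: Union[str, Path],
    variant: Optional[Variant] = None,
    config: Optional[FormatConfig] = None,
) -> GenotypePhenotypeMap:
    """Read a gpmap table, validating values and reporting duplicates.

    If ``variant`` is omitted it is inferred from the genotype tokens
    (bit positions in order of first appearance); supply it explicitly to
    fix the bit convention.
    """
    path = Path(path)
    config = config or FormatConfig()
    df = pd.read_csv(
        path,
        sep=_infer_sep(path, config),
        dtype={config.genotype_col: str},
        float_precision="round_trip",
    )
    df[config.genotype_col] = df[config.genotype_col].fillna("")
    for col in (config.genotype_col, config.env_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if variant is None:
        if config.genotype_style == "bits":
            raise ValueError("bitstring genotypes require an explicit Variant")
        variant = _infer_variant(df, config)

    rep_cols: list[str]
    if config.replicate_cols is not None:
        rep_cols = list(config.replicate_cols)
    else:
        rep_cols = [c for c in df.columns if c.startswith("rep")]
    has_summary = config.mean_col in df.columns

    gpmap = GenotypePhenotypeMap(variant)
    for idx, row in df.iterrows():
        genotype = _parse_genotype(row[config.genotype_col], variant, config.genotype_style)
        env = environment_from_label(str(row[config.env_col]).strip())
        reps = []
        for c in rep_cols:
            v = row.get(c)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                reps.append(float(v))
        if reps:
            rec = ExpressionRecord(genotype, env, replicates=tuple(reps))
        elif has_summary and not math.isnan(float(row[config.mean_col])):
            rec = ExpressionRecord(
                genotype,
                env,
                summary=(
                    float(row[config.mean_col]),
                    float(row[config.sd_col]),
                    int(row[config.n_col]),
                ),
            )
        else:
            raise ValueError(
                f"row {idx} of {path} has neither replicate values nor a "
                "mean/sd/n summary"
            )
        gpmap.add(rec)  # raises on duplicates, naming the genotype
    return gpmap


def write_gpmap(
    gpmap: GenotypePhenotypeMap,
    path: Union[str, Path],
    config: Optional[FormatConfig] = None,
) -> None:
    """Write a map in canonical order (genotypes by bit pattern, then env).

    Round-trips bit-exactly through :func:`read_gpmap` with the same config.
    """
    path = Path(path)
    config = config or FormatConfig()
    max_reps = max(
        (len(r.replicates) for r in gpmap if r.replicates is not None), default=0
    )
    rows = []
    for genotype in gpmap.variant.all_genotypes():
        for env in ENVIRONMENTS:
            if not gpmap.has(genotype, env):
                continue
            rec = gpmap.get(genotype, env)
            if config.genotype_style == "bits":
                gtok = str(genotype)
            else:
                gtok = genotype.label(gpmap.variant)
            row: dict = {config.genotype_col: gtok, config.env_col: env.label}
            if rec.replicates is not None:
                for i, v in enumerate(rec.replicates, start=1):
                    row[f"rep{i}"] = v
            else:
                mean, sd, n = rec.summary
                row[config.mean_col] = mean
                row[config.sd_col] = sd
                row[config.n_col] = n
            rows.append(row)
    cols = [config.genotype_col, config.env_col]
    cols += [f"rep{i}" for i in range(1, max_reps + 1)]
    if any(r.summary is not None for r in gpmap):
        cols += [config.mean_col, config.sd_col, config.n_col]
    df = pd.DataFrame(rows, columns=cols)
    # %.17g round-trips IEEE doubles bit-exactly
    df.to_csv(path, sep=_infer_sep(path, config), index=False, float_format="%.17g")
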