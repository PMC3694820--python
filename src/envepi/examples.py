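"""SYNTHETIC stand-in expression tables for the three inverse variants.

The raw per-genotype expression measurements behind the published
classification panel live in a supplementary table that is not shipped
here.  This module provides *synthetic* summary-statistics maps (mean,
sd = 2 % of mean, n = 3) whose benefit-sign structure was constructed by
hand from printed facts only: the panel's M/S/R categories, the narrated
vector geometry (the shared lock mutation pointing along the Env_1 axis
in the wild-type background and the other mutations rotating toward the
Env_0 axis once it is present), and the stated ~20-fold expression
increase of R207L in Env_1 when T258A is present in the P97 background.

They exercise the full summary-statistics pipeline path end to end.  Two
caveats make them stand-ins rather than reconstructions:

* The printed LacI_inv1 / Env_0 column is not realizable by any single
  consistent sign assignment (the magnitude calls of rows 1, 5 and 6
  together contradict the sign call of row 3 for R207L, which forms an
  odd constraint cycle).  These maps follow the explicitly narrated row-3
  sign change, so row 6 of LacI_inv1 classifies as S(R207L) in Env_0
  instead of the printed M: 35 of the 36 published category cells are
  reproduced.
* Absolute values and fold changes other than the 20-fold one are free
  choices; census fractions computed from these maps characterize the
  stand-in, not the original measurements.
"""

from __future__ import annotations

from .gpmap import (
    ENV_0,
    ENV_1,
    ExpressionRecord,
    GenotypePhenotypeMap,
    LACI_VARIANTS,
)

__all__ = ["synthetic_expression_tables", "SD_CV"]

#: relative spread of the synthetic summaries (well inside the Bonferroni
#: threshold for every intended-significant contrast at n = 3)
SD_CV = 0.02

# mean expression per genotype label, per environment; '' = wild type.
# Env_1 values are relative to the induced wild-type level (hence the
# strong decrease for lock-carrying genotypes); Env_0 values are relative
# to the repressed wild-type level.
_MEANS = {
    "LacI_inv1": {
        ENV_0.label: {
            "": 1.0, "S97P": 1.3, "R207L": 1.0, "T258A": 1.0,
            "S97P;R207L": 1.3, "S97P;T258A": 4.0, "R207L;T258A": 1.0,
            "S97P;R207L;T258A": 8.0,
        },
        ENV_1.label: {
            "": 1.0, "S97P": 0.02, "R207L": 1.0, "T258A": 1.5,
            "S97P;R207L": 0.02, "S97P;T258A": 0.06, "R207L;T258A": 1.5,
            # 20-fold above S97P;T258A: the narrated R207L effect
            "S97P;R207L;T258A": 1.2,
        },
    },
    "LacI_inv2": {
        ENV_0.label: {
            "": 1.0, "S97P": 1.3, "L307H": 1.0, "L349P": 1.0,
            "S97P;L307H": 4.0, "S97P;L349P": 2.0, "L307H;L349P": 1.0,
            "S97P;L307H;L349P": 3.5,
        },
        ENV_1.label: {
            "": 1.0, "S97P": 0.02, "L307H": 2.0, "L349P": 1.5,
            "S97P;L307H": 0.06, "S97P;L349P": 0.06, "L307H;L349P": 3.0,
            "S97P;L307H;L349P": 0.02,
        },
    },
    "LacI_inv3": {
        ENV_0.label: {
            "": 1.0, "S97P": 1.3, "G315D": 1.0, "P339H": 1.0,
            "S97P;G315D": 4.0, "S97P;P339H": 1.3, "G315D;P339H": 1.0,
            "S97P;G315D;P339H": 8.0,
        },
        ENV_1.label: {
            "": 1.0, "S97P": 0.02, "G315D": 2.0, "P339H": 1.5,
            "S97P;G315D": 0.01, "S97P;P339H": 0.06, "G315D;P339H": 3.0,
            "S97P;G315D;P339H": 0.03,
        },
    },
}


def synthetic_expression_tables() -> dict:
    """Synthetic summary-mode maps for the three variants (see module doc)."""
    out = {}
    for vname, by_env in _MEANS.items():
        variant = LACI_VARIANTS[vname]
        gpmap = GenotypePhenotypeMap(variant)
        for env in (ENV_0, ENV_1):
            for label, mean in by_env[env.label].items():
                genotype = variant.genotype(
                    [t for t in label.split(";") if t]
                )
                gpmap.add(
                    ExpressionRecord(
                        genotype, env, summary=(mean, SD_CV * mean, 3)
                    )
                )
        out[vname] = gpmap
    return out
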