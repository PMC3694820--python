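"""Vector-plot rendering of multi-environment genotype-phenotype maps."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .effects import EffectsTable, SignificancePolicy, compute_effects  # noqa: E402
from .gpmap import ENV_0, ENV_1, GenotypePhenotypeMap  # noqa: E402
from .vectors import mutation_vector  # noqa: E402

__all__ = ["render_vector_plot"]

_DEFAULT_COLORS = ("tab:blue", "tab:green", "tab:red", "tab:purple", "tab:orange")


def render_vector_plot(
    gpmap: GenotypePhenotypeMap,
    path: Union[str, Path],
    effects: Optional[EffectsTable] = None,
    policy: SignificancePolicy = SignificancePolicy(),
    log: bool = True,
    title: Optional[str] = None,
) -> Path:
    """Draw every mutation vector of a complete map and save the figure.

    Axes: x = expression in Env_0, y = inverse expression in Env_1, both
    normalized to the reference, which sits at (1, 1); log scale by
    default (expression spans orders of magnitude).  One color per
    mutation, error bars are standard deviations scaled to the
    normalized coordinates.
    """
    gpmap = gpmap.normalize()
    if effects is None:
        effects = compute_effects(gpmap, policy=policy)
    variant = gpmap.variant
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {}
    for mut, fallback in zip(variant.mutations, _DEFAULT_COLORS):
        colors[mut.name] = mut.color or fallback

    for i, mut in enumerate(variant.mutations):
        for background in variant.all_genotypes():
            if background.has(i):
                continue
            vec = mutation_vector(gpmap, mut.name, background, effects)
            (x0, y0), (x1, y1) = vec.start, vec.end
            ax.annotate(
                "",
                xy=(x1, y1),
                xytext=(x0, y0),
                arrowprops=dict(
                    arrowstyle="-|>", color=colors[mut.name], lw=1.4
                ),
            )
    # error bars at each genotype position
    for genotype in variant.all_genotypes():
        r0 = gpmap.get(genotype, ENV_0)
        r1 = gpmap.get(genotype, ENV_1)
        x, y = r0.mean, 1.0 / r1.mean
        # sd of 1/E via the delta method: sd(E) / E^2
        ax.errorbar(
            x,
            y,
            xerr=r0.sd,
            yerr=r1.sd / (r1.mean**2),
            fmt="o",
            ms=3,
            color="0.4",
            ecolor="0.7",
            lw=0.8,
            zorder=1,
        )
    if log:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.axhline(1.0, color="0.85", lw=0.8, zorder=0)
    ax.axvline(1.0, color="0.85", lw=0.8, zorder=0)
    ax.set_xlabel("expression in Env$_0$ (relative to reference)")
    ax.set_ylabel("(expression)$^{-1}$ in Env$_1$ (relative)")
    ax.set_title(title or variant.name)
    handles = [
        plt.Line2D([], [], color=c, label=n) for n, c in colors.items()
    ]
    ax.legend(handles=handles, fontsize=8, loc="best")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
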