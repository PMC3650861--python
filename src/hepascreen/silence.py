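"""Screens for transcriptional silence and liver/paralog divergence.

A gene with zero RNA-seq evidence of expression in normal liver should
produce only background-level array intensity.  "Expressed in a disease
group" is operationalized as a one-sided two-sample Kolmogorov-Smirnov test
of the gene's values in that group against a pooled empirical background
distribution built from the silent-gene registry itself: expression can
only elevate intensity above background, so the alternative is
"stochastically greater".  An alternate null (``same-gene``) compares the
gene's disease values against its own normal-group values instead.

The paralog contrast asks a different question: within tumors, does a liver
development gene behave differently from its non-liver paralog?  That is a
symmetric two-sided two-sample K-S test between the two genes' value
distributions in the same samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import GeneSetRegistry
from .screen import ALPHA_DEFAULT, ks_two_sample
from .types import ExpressionMatrix, POOLED_HCC

MIN_BACKGROUND_GENES = 20


@dataclass
class BackgroundModel:
    """Pooled empirical distribution of log2 intensities of silent genes."""

    values: np.ndarray  # sorted, log2 scale
    n_genes: int
    groups: tuple[str, ...]

    def quantile(self, q) -> np.ndarray | float:
        return np.quantile(self.values, q)


def build_background(expr: ExpressionMatrix, registry: GeneSetRegistry,
                     groups: Sequence[str] = ("NOR",)) -> BackgroundModel:
    """Pool all values of registry silent genes in ``groups`` into one
    empirical background distribution."""
    groups = tuple(groups)
    if not groups:
        raise ValueError("at least one group is needed to build the background")
    present = [g for g in registry.silent if g in expr.values.index]
    if len(present) < MIN_BACKGROUND_GENES:
        raise ValueError(
            f"background needs >= {MIN_BACKGROUND_GENES} registry genes in the "
            f"matrix, found {len(present)}")
    samples: list[str] = []
    for grp in groups:
        samples.extend(expr.samples_in(grp))
    if not samples:
        raise ValueError(f"no samples in groups {groups}")
    pool = np.log2(expr.values.loc[present, samples].to_numpy(dtype=float)).ravel()
    return BackgroundModel(values=np.sort(pool), n_genes=len(present), groups=groups)


def call_expressed(expr: ExpressionMatrix, gene: str, group: str,
                   background: BackgroundModel, alpha: float = ALPHA_DEFAULT,
                   null: str = "pooled") -> tuple[bool, float]:
    """One-sided K-S call of whether ``gene`` is expressed in ``group``.

    ``null='pooled'`` (default) tests against the pooled silent-gene
    background; ``null='same-gene'`` tests against the gene's own
    normal-group values.  Returns ``(expressed, p)`` with
    ``expressed <=> p < alpha``.
    """
    if gene not in expr.values.index:
        raise KeyError(f"gene {gene!r} absent from matrix")
    samples = expr.samples_in(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    x = np.log2(expr.values.loc[gene, samples].to_numpy(dtype=float))
    if null == "pooled":
        ref = background.values
    elif null == "same-gene":
        ref = np.log2(expr.values.loc[gene, expr.samples_in("NOR")].to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown null {null!r}")
    _, p = ks_two_sample(x, ref, alternative="greater")
    return p < alpha, p


def silence_screen(expr: ExpressionMatrix, registry: GeneSetRegistry,
                   group: str = POOLED_HCC, alpha: float = ALPHA_DEFAULT,
                   background_groups: Sequence[str] = ("NOR",),
                   null: str = "pooled") -> pd.DataFrame:
    """Apply :func:`call_expressed` to every registry silent gene present."""
    background = build_background(expr, registry, background_groups)
    rows = []
    for gene in registry.silent:
        if gene not in expr.values.index:
            continue
        expressed, p = call_expressed(expr, gene, group, background, alpha, null)
        rows.append((gene, p, expressed))
    return pd.DataFrame(rows, columns=["gene_id", "p", "expressed"]).set_index("gene_id")


def paralog_contrast(expr: ExpressionMatrix, pair: tuple[str, str],
                     group: str = POOLED_HCC,
                     alpha: float = ALPHA_DEFAULT) -> tuple[bool, float]:
    """Two-sided K-S between a liver gene and its paralog within one group.

    Symmetric in the two genes.  Returns ``(different, p)`` with
    ``different <=> p < alpha``.
    """
    liver, para = pair
    for g in pair:
        if g not in expr.values.index:
            raise KeyError(f"gene {g!r} absent from matrix")
    samples = expr.samples_in(group)
    x = np.log2(expr.values.loc[liver, samples].to_numpy(dtype=float))
    y = np.log2(expr.values.loc[para, samples].to_numpy(dtype=float))
    _, p = ks_two_sample(x, y, alternative="two_sided")
    return p < alpha, p


def paralog_screen(expr: ExpressionMatrix, registry: GeneSetRegistry,
                   group: str = POOLED_HCC,
                   alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Run the paralog contrast over every registry pair."""
    rows = []
    for liver, para in registry.paralog_pairs:
        different, p = paralog_contrast(expr, (liver, para), group, alpha)
        rows.append((liver, para, p, different))
    return pd.DataFrame(rows, columns=["liver_gene", "paralog", "p", "different"])


def density_report(expr: ExpressionMatrix, genes: Iterable[str],
                   groups: Sequence[str], n_grid: int = 256) -> pd.DataFrame:
    """Gaussian-kernel density tables of log2 expression, per gene and group.

    Bandwidth follows Silverman's rule; each density is tabulated on
    ``n_grid`` points spanning the observed range padded by three bandwidths.
    Degenerate (constant) samples fall back to a narrow fixed-bandwidth
    kernel so the report stays plotting-ready.
    """
    frames = []
    for gene in genes:
        if gene not in expr.values.index:
            raise KeyError(f"gene {gene!r} absent from matrix")
        for grp in groups:
            x = np.log2(expr.values.loc[gene, expr.samples_in(grp)].to_numpy(dtype=float))
            if x.size == 0:
                continue
            sd = x.std(ddof=1) if x.size > 1 else 0.0
            if sd == 0:
                bw = 0.01
                grid = np.linspace(x[0] - 0.5, x[0] + 0.5, n_grid)
                dens = stats.norm.pdf(grid, loc=x[0], scale=bw)
            else:
                kde = stats.gaussian_kde(x, bw_method="silverman")
                bw = kde.factor * sd
                grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
                dens = kde(grid)
            frames.append(pd.DataFrame({
                "gene_id": gene, "group": grp, "x": grid, "density": dens,
            }))
    return pd.concat(frames, ignore_index=True)
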