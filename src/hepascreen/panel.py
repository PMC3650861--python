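"""Marker-panel coverage: the "at least one gene with FC > 1.5" rule.

No single gene marks every tumor in a heterogeneous cancer, but a small
panel can: a sample counts as covered when at least one panel gene exceeds
the fold-change threshold (strictly) relative to the normal-group mean.
The coverage statistic is the fraction of target samples covered.  A greedy
set-cover search is provided for building panels from a candidate list.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, PanelReport

FC_THRESHOLD_DEFAULT = 1.5


def _baseline_means(expr: ExpressionMatrix, genes: Sequence[str],
                    baseline_group: str,
                    baseline_samples: Sequence[str] | None = None) -> pd.Series:
    samples = (list(baseline_samples) if baseline_samples is not None
               else expr.samples_in(baseline_group))
    if not samples:
        raise ValueError(f"baseline group {baseline_group!r} has no samples")
    means = expr.values.loc[list(genes), samples].mean(axis=1)
    if (means <= 0).any():
        bad = means.index[means <= 0].tolist()
        raise ValueError(f"non-positive baseline mean for genes: {bad}")
    return means


def per_sample_fold_change(expr: ExpressionMatrix, gene: str, sample: str,
                           baseline_group: str = "NOR",
                           baseline_samples: Sequence[str] | None = None) -> float:
    """One sample's linear value over the baseline-group mean for ``gene``."""
    if gene not in expr.values.index:
        raise KeyError(f"gene {gene!r} absent from matrix")
    base = _baseline_means(expr, [gene], baseline_group, baseline_samples)
    return float(expr.values.at[gene, sample] / base.iloc[0])


def panel_coverage(expr: ExpressionMatrix, panel: Sequence[str],
                   target_samples: Sequence[str],
                   threshold: float = FC_THRESHOLD_DEFAULT,
                   baseline_group: str = "NOR",
                   baseline_samples: Sequence[str] | None = None) -> PanelReport:
    """Coverage of ``target_samples`` by the panel under strict ``FC > threshold``."""
    panel = list(panel)
    targets = list(target_samples)
    if not panel:
        raise ValueError("panel must be non-empty")
    if not targets:
        raise ValueError("target sample list must be non-empty")
    missing = [g for g in panel if g not in expr.values.index]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    base = _baseline_means(expr, panel, baseline_group, baseline_samples)
    fc = expr.values.loc[panel, targets].div(base, axis=0)
    max_fc = fc.max(axis=0)
    covering = fc.idxmax(axis=0)
    covered = max_fc > threshold
    per_sample = pd.DataFrame({
        "max_fc": max_fc, "covering_gene": covering, "covered": covered,
    })
    per_sample.index.name = "sample"
    return PanelReport(panel=panel, threshold=threshold, per_sample=per_sample,
                       coverage=float(covered.mean()))


def greedy_panel_search(expr: ExpressionMatrix, candidates: Sequence[str],
                        target_samples: Sequence[str],
                        threshold: float = FC_THRESHOLD_DEFAULT,
                        max_size: int = 4,
                        baseline_group: str = "NOR") -> list[str]:
    """Greedy set cover over candidate genes.

    Iteratively adds the candidate covering the most still-uncovered target
    samples (ties broken lexicographically by gene id), stopping at full
    coverage or ``max_size`` genes.  May return a panel with partial
    coverage.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    targets = list(target_samples)
    if not targets:
        warnings.warn("empty target sample set; returning an empty panel")
        return []
    base = _baseline_means(expr, candidates, baseline_group)
    fc = expr.values.loc[candidates, targets].div(base, axis=0)
    covers = {g: frozenset(fc.columns[fc.loc[g] > threshold]) for g in candidates}
    chosen: list[str] = []
    covered: set[str] = set()
    while len(chosen) < max_size and len(covered) < len(targets):
        best, best_gain = None, 0
        for g in candidates:
            if g in chosen:
                continue
            gain = len(covers[g] - covered)
            if gain > best_gain:
                best, best_gain = g, gain
        if best is None:
            break
        chosen.append(best)
        covered |= covers[best]
    return chosen
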