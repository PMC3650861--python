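"""Differential-expression screen over curated gene sets.

The screen targets both shifts in mean and loss of regulation (inflated
variance, skewed or bimodal distributions): each contrast is tested with a
Welch t test on the log2 values, a two-sided variance-ratio F test, and
their Fisher combination as the primary p-value, plus a two-sample
Kolmogorov-Smirnov test sensitive to location and shape simultaneously.
Fold-changes are ratios of arithmetic group means on the linear intensity
scale, relative to the normal group.  Calling is at a fixed alpha (default
0.001) without multiplicity correction, with Benjamini-Hochberg available
behind a flag.

Genes are then classified into the qualitative expression patterns of the
disease progression: a cirrhosis peak with decline in tumors, persistent
down-regulation, tumor-only change, late-tumor-only change, and change
shared between cirrhosis and tumors (similar or amplified).
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, POOLED_HCC

ALPHA_DEFAULT = 0.001

#: contrasts computed by the screen, as (baseline-ish group, comparison group)
CONTRASTS: tuple[tuple[str, str], ...] = (
    ("NOR", "CIR"),
    ("NOR", "HCC_EARLY"),
    ("NOR", "HCC_LATE"),
    ("NOR", "HCC"),
    ("CIR", "HCC"),
    ("CIR", "HCC_EARLY"),
    ("CIR", "HCC_LATE"),
    ("HCC_EARLY", "HCC_LATE"),
)

PATTERN_LABELS: tuple[str, ...] = (
    "CIR_PEAK", "DOWN_PERSISTENT", "TUMOR_ONLY", "SHARED_SIMILAR",
    "SHARED_AMPLIFIED", "LATE_ONLY", "UNCHANGED",
)

_TINY = np.finfo(float).tiny


def contrast_key(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def group_fold_change(expr: ExpressionMatrix, gene: str, group: str,
                      baseline: str = "NOR") -> float:
    """Linear-scale ratio of arithmetic group means, ``group / baseline``."""
    row = expr.values.loc[gene]
    num = row[expr.samples_in(group)].mean()
    den = row[expr.samples_in(baseline)].mean()
    if den <= 0:
        raise ValueError(f"baseline mean for gene {gene!r} is not positive")
    return float(num / den)


def fisher_combine(p_values: Iterable[float] | np.ndarray) -> np.ndarray | float:
    """Fisher's method: refer -2 sum(ln p) to chi-square with 2k df."""
    p = np.clip(np.asarray(list(p_values) if not isinstance(p_values, np.ndarray)
                           else p_values, dtype=float), _TINY, 1.0)
    x = -2.0 * np.sum(np.log(p), axis=0)
    return stats.chi2.sf(x, df=2 * p.shape[0])


def mean_variance_test(x, y):
    """Welch t, two-sided variance-ratio F, and their Fisher combination.

    ``x`` and ``y`` are log2-scale values; both accept 2-D arrays with
    observations on the last axis for vectorized screening.  Returns
    ``(p_t, p_f, p_combined)``.  The F p-value is
    ``2 * min(P(F <= f), P(F >= f))``; when both samples have zero variance
    it is set to 1 with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, m = x.shape[-1], y.shape[-1]
    if n < 2 or m < 2:
        raise ValueError("mean_variance_test needs >= 2 observations per sample")
    with np.errstate(divide="ignore", invalid="ignore"):
        p_t = stats.ttest_ind(x, y, axis=-1, equal_var=False).pvalue
        vx = x.var(axis=-1, ddof=1)
        vy = y.var(axis=-1, ddof=1)
        f = vx / vy
        p_f = 2.0 * np.minimum(stats.f.cdf(f, n - 1, m - 1),
                               stats.f.sf(f, n - 1, m - 1))
    p_f = np.minimum(p_f, 1.0)
    both_zero = (vx == 0) & (vy == 0)
    if np.any(both_zero):
        warnings.warn("zero variance in both samples; F p-value set to 1")
        p_f = np.where(both_zero, 1.0, p_f)
        p_t = np.where(both_zero & np.isnan(p_t), 1.0, p_t)
    p_comb = fisher_combine(np.stack([np.atleast_1d(p_t), np.atleast_1d(p_f)]))
    if np.ndim(x) <= 2 and x.shape[0] == 1:
        return float(np.squeeze(p_t)), float(np.squeeze(p_f)), float(np.squeeze(p_comb))
    return p_t, p_f, p_comb


def _ks_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(two-sided D, D+ for x greater, D- for x less) between two samples."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    diff = cdf_y - cdf_x  # positive where x is stochastically greater
    return float(np.max(np.abs(diff))), float(np.max(diff)), float(-np.min(diff))


_EXACT_LIMIT = 12


def ks_two_sample(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``alternative='two_sided'`` uses the sup-norm distance between the two
    empirical CDFs; ``'greater'`` tests whether ``x`` is stochastically
    greater than ``y`` (signed sup).  The p-value is exact by exhaustive
    label permutation when ``len(x) + len(y) <= 12`` and asymptotic
    otherwise.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    d2, dplus, _ = _ks_statistics(x, y)
    d = d2 if alternative == "two_sided" else dplus
    if n + m <= _EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        count = 0
        total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            pd2, pdp, _ = _ks_statistics(pooled[mask], pooled[~mask])
            stat = pd2 if alternative == "two_sided" else pdp
            count += stat >= d - 1e-12
            total += 1
        return d, count / total
    en = n * m / (n + m)
    if alternative == "two_sided":
        p = stats.kstwobign.sf(math.sqrt(en) * d)
    else:
        p = math.exp(-2.0 * en * d * d) if d > 0 else 1.0
    return d, float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

def screen_gene_set(expr: ExpressionMatrix, genes: Iterable[str],
                    alpha: float = ALPHA_DEFAULT,
                    correction: str | None = None) -> pd.DataFrame:
    """Run all contrasts for the listed genes and classify their patterns.

    Returns one row per gene with, for every contrast ``a_vs_b``, the
    columns ``fc`` (mean ratio b/a on the linear scale, except contrasts
    whose reference is NOR where it is the disease-group fold-change),
    ``p_t``, ``p_f``, ``p_comb``, ``p_ks`` and ``sig``, plus a final
    ``pattern`` column.  Unknown gene ids are warned about and skipped.
    ``correction='bh'`` replaces the fixed-alpha call with a
    Benjamini-Hochberg FDR call at the same level.
    """
    genes = list(genes)
    known = [g for g in genes if g in expr.values.index]
    unknown = sorted(set(genes) - set(known))
    if unknown:
        warnings.warn(f"unknown gene ids skipped: {unknown}")
    if not known:
        raise ValueError("no requested genes present in the matrix")
    values = expr.values.loc[known]
    log2v = np.log2(values.to_numpy(dtype=float))
    cols = {s: i for i, s in enumerate(expr.samples)}

    out: dict[str, np.ndarray] = {}
    for a, b in CONTRASTS:
        ia = [cols[s] for s in expr.samples_in(a)]
        ib = [cols[s] for s in expr.samples_in(b)]
        if len(ia) < 2 or len(ib) < 2:
            raise ValueError(f"contrast {a} vs {b}: each side needs >= 2 samples")
        xa, xb = log2v[:, ia], log2v[:, ib]
        fc = values.iloc[:, ib].mean(axis=1) / values.iloc[:, ia].mean(axis=1)
        p_t, p_f, p_comb = mean_variance_test(xb, xa)
        p_t, p_f, p_comb = map(np.atleast_1d, (p_t, p_f, p_comb))
        p_ks = np.array([ks_two_sample(xb[i], xa[i])[1] for i in range(len(known))])
        key = contrast_key(a, b)
        out[f"fc_{key}"] = fc.to_numpy()
        out[f"p_t_{key}"] = p_t
        out[f"p_f_{key}"] = p_f
        out[f"p_comb_{key}"] = p_comb
        out[f"p_ks_{key}"] = p_ks
        if correction == "bh":
            sig = _bh_reject(p_comb, alpha)
        else:
            sig = p_comb < alpha
        out[f"sig_{key}"] = sig

    result = pd.DataFrame(out, index=pd.Index(known, name="gene_id"))
    result["pattern"] = [
        classify_pattern(result.loc[g], alpha) for g in result.index
    ]
    return result


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR ``alpha``."""
    p = np.asarray(p, dtype=float)
    k = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, k + 1)) / k
    passed = p[order] <= thresh
    mask = np.zeros(k, dtype=bool)
    if passed.any():
        mask[order[: np.max(np.flatnonzero(passed)) + 1]] = True
    return mask


def classify_pattern(r: Mapping, alpha: float = ALPHA_DEFAULT) -> str:
    """Assign one expression-pattern label from a screened gene's row.

    The decision tree partitions every gene into exactly one label:

    * ``UNCHANGED`` -- no disease contrast significant;
    * ``LATE_ONLY`` -- among the normal-vs-disease contrasts only
      NOR vs late HCC is significant;
    * ``TUMOR_ONLY`` -- not significant in cirrhosis, significant in tumors;
    * ``CIR_PEAK`` -- up in cirrhosis with a significant decline in tumors;
    * ``DOWN_PERSISTENT`` -- down in cirrhosis with no further tumor change;
    * ``SHARED_AMPLIFIED`` / ``SHARED_SIMILAR`` -- changed in cirrhosis and
      tumors, with strictly larger / comparable log2 magnitude in tumors.
    """
    s_nc = bool(r[f"sig_{contrast_key('NOR', 'CIR')}"])
    s_ne = bool(r[f"sig_{contrast_key('NOR', 'HCC_EARLY')}"])
    s_nl = bool(r[f"sig_{contrast_key('NOR', 'HCC_LATE')}"])
    s_ch = bool(r[f"sig_{contrast_key('CIR', 'HCC')}"])
    fc_cir = float(r[f"fc_{contrast_key('NOR', 'CIR')}"])
    fc_hcc = float(r[f"fc_{contrast_key('NOR', 'HCC')}"])
    fc_early = float(r[f"fc_{contrast_key('NOR', 'HCC_EARLY')}"])
    fc_late = float(r[f"fc_{contrast_key('NOR', 'HCC_LATE')}"])

    if not (s_nc or s_ne or s_nl or s_ch):
        return "UNCHANGED"
    if not s_nc:
        if s_nl and not s_ne:
            return "LATE_ONLY"
        return "TUMOR_ONLY"
    if fc_cir > 1 and s_ch and fc_hcc < fc_cir:
        return "CIR_PEAK"
    if fc_cir < 1 and not s_ch:
        return "DOWN_PERSISTENT"
    if s_ne or s_nl:
        tumor_mag = max(abs(np.log2(fc_early)), abs(np.log2(fc_late)))
        if tumor_mag > abs(np.log2(fc_cir)):
            return "SHARED_AMPLIFIED"
    return "SHARED_SIMILAR"


def flagged_any_disease(result: pd.DataFrame, contrasts=(
        ("NOR", "CIR"), ("NOR", "HCC_EARLY"), ("NOR", "HCC_LATE"))) -> pd.Series:
    """Boolean mask: significant in at least one normal-vs-disease contrast."""
    masks = [result[f"sig_{contrast_key(a, b)}"] for a, b in contrasts]
    return pd.concat(masks, axis=1).any(axis=1)
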