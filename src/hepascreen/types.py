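"""Core data containers shared across the pipeline.

Expression values are kept on the linear intensity scale everywhere; every
statistical routine that needs the log2 scale converts at its own boundary.
Sample groups follow the four-arm cohort design: normal donor liver (NOR),
HCV cirrhosis (CIR), early-stage tumors (HCC_EARLY, stages T1-T2) and
late-stage tumors (HCC_LATE, stages T3-T4).  The pseudo-label ``HCC`` refers
to the pooled tumor arms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SampleGroup(str, enum.Enum):
    """The four sample arms of the cohort design."""

    NOR = "NOR"
    CIR = "CIR"
    HCC_EARLY = "HCC_EARLY"
    HCC_LATE = "HCC_LATE"


GROUP_ORDER: tuple[str, ...] = tuple(g.value for g in SampleGroup)
TUMOR_GROUPS: tuple[str, str] = (SampleGroup.HCC_EARLY.value, SampleGroup.HCC_LATE.value)
#: pseudo-group resolving to the pooled tumor arms
POOLED_HCC = "HCC"

#: metadata columns of the probe-level table, in canonical order
PROBE_META_COLUMNS: tuple[str, ...] = (
    "probe_id",
    "gene_id",
    "gc_fraction",
    "melting_temp",
    "position_index",
)
#: the technical covariates used by normalization
PROBE_COVARIATES: tuple[str, ...] = ("gc_fraction", "melting_temp", "position_index")


def resolve_group(label: str) -> tuple[str, ...]:
    """Expand a group label (or the pooled ``HCC`` pseudo-label) to concrete arms."""
    if label == POOLED_HCC:
        return TUMOR_GROUPS
    if label not in GROUP_ORDER:
        raise ValueError(f"unknown sample group {label!r}; expected one of "
                         f"{GROUP_ORDER + (POOLED_HCC,)}")
    return (label,)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of linear-scale expression with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample; strictly
        positive linear-scale intensities.
    groups
        Series mapping sample id -> group label.  Optional so that matrices
        read from label-free sources (e.g. a GEO series matrix) can be
        represented; any group-aware operation raises if labels are absent.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)
            if self.groups.isna().any():
                missing = self.groups.index[self.groups.isna()].tolist()
                raise ValueError(f"samples without a group label: {missing}")
            bad = sorted(set(self.groups) - set(GROUP_ORDER))
            if bad:
                raise ValueError(f"unknown group labels: {bad}")

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def require_groups(self) -> pd.Series:
        if self.groups is None:
            raise ValueError("this operation needs sample group labels")
        return self.groups

    def samples_in(self, label: str) -> list[str]:
        """Sample ids belonging to ``label`` (``HCC`` pools both tumor arms)."""
        groups = self.require_groups()
        wanted = resolve_group(label)
        return [s for s in self.samples if groups[s] in wanted]

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.groups)


@dataclass
class ProbeTable:
    """Probe-level intensities plus the technical covariates of each probe.

    ``data`` holds the metadata columns of :data:`PROBE_META_COLUMNS` followed
    by one intensity column per sample (strictly positive, linear scale).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"probe table missing covariate column(s): {missing}")
        if self.data["probe_id"].duplicated().any():
            dupes = self.data.loc[self.data["probe_id"].duplicated(), "probe_id"]
            raise ValueError(f"duplicate probe ids: {sorted(set(dupes))}")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.data.columns if c not in PROBE_META_COLUMNS]

    @property
    def intensities(self) -> pd.DataFrame:
        """Probe x sample matrix of intensities, indexed by probe id."""
        out = self.data[self.samples].copy()
        out.index = pd.Index(self.data["probe_id"], name="probe_id")
        return out

    def covariate(self, name: str) -> np.ndarray:
        if name not in PROBE_COVARIATES:
            raise KeyError(f"unknown probe covariate {name!r}")
        return self.data[name].to_numpy(dtype=float)

    def with_intensities(self, values: np.ndarray | pd.DataFrame) -> "ProbeTable":
        """Copy of the table with the intensity block replaced."""
        new = self.data.copy()
        new[self.samples] = np.asarray(values, dtype=float)
        return ProbeTable(new)


@dataclass
class PanelReport:
    """Per-sample maximum fold-change over a marker panel and the coverage rule."""

    panel: list[str]
    threshold: float
    per_sample: pd.DataFrame  # columns: max_fc, covering_gene, covered
    coverage: float

    def covered_samples(self) -> list[str]:
        return self.per_sample.index[self.per_sample["covered"]].tolist()


@dataclass
class ROCReport:
    """LOOCV scores and the ROC summary derived from them."""

    scores: pd.DataFrame  # per-sample: score, tumor (bool)
    curve: pd.DataFrame  # per-threshold: threshold, sensitivity, specificity
    auc: float
    sensitivity: float  # at the Youden-optimal operating point
    specificity: float
    threshold: float


@dataclass
class NormalizationModel:
    """Fitted per-array technical-bias model.

    ``curves[array][covariate]`` tabulates the fitted bias component on the
    sorted covariate values; ``offsets`` holds the per-array scale offset and
    ``fitted`` the total bias that was subtracted (log2 scale), so that
    evaluating the model on its own fitting data reproduces the correction.
    """

    reference: pd.Series  # pooled median pseudo-array (log2, per probe)
    offsets: dict[str, float]
    curves: dict[str, dict[str, pd.DataFrame]]
    fitted: pd.DataFrame  # probe x sample fitted bias (log2)
    bandwidth_frac: float
    n_backfit: int
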