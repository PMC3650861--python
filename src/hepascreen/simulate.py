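"""Synthetic probe-level cohort generator with known ground truth.

The generator emulates the statistical structure the downstream screens
assume, so every stage of the pipeline is testable without any download:

* log-normal baseline expression with additive effects on the log2 scale,
  so planted fold-changes are exact in the zero-noise limit;
* multiplicative per-group effects and optional sub-population effects
  applied to a seeded subset of tumor samples (producing the skewed or
  bimodal tumor densities characteristic of heterogeneous cancers);
* per-group dispersion factors that widen a gene's distribution without
  moving its mean (poor transcriptional regulation);
* transcriptionally silent genes pinned to the array background floor;
* probe-level intensities derived from the gene value plus a fixed,
  median-centered per-probe affinity offset;
* smooth per-array technical bias in GC content, melting temperature and
  probe position, plus a per-array scale offset.

Randomness is split into fixed named streams derived from the master seed,
so adding one stage never perturbs another stage's draws, and a fixed master
seed reproduces byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import registry as reg
from .types import (
    GROUP_ORDER,
    POOLED_HCC,
    PROBE_COVARIATES,
    PROBE_META_COLUMNS,
    TUMOR_GROUPS,
    ExpressionMatrix,
    ProbeTable,
    resolve_group,
)

#: cohort arm sizes of the study design the generator mimics by default
DEFAULT_N_PER_GROUP: dict[str, int] = {
    "NOR": 12, "CIR": 30, "HCC_EARLY": 31, "HCC_LATE": 18,
}

GROUP_PREFIX = {"NOR": "NOR", "CIR": "CIR", "HCC_EARLY": "HCE", "HCC_LATE": "HCL"}


class CohortConfigError(ValueError):
    """Raised when a cohort configuration field is invalid."""


def _rng(master_seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible stream for one generation stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class SubsetEffect:
    """Extra multiplicative effect applied to a sub-population of one group.

    Either ``fraction`` (affected fraction drawn at random) or ``samples``
    (explicit 0-based indices into the group's sample list) selects the
    affected sub-population; ``fold`` is the extra linear fold-change.
    """

    fold: float
    fraction: float | None = None
    samples: tuple[int, ...] | None = None

    def validate(self, gene: str) -> None:
        if self.fold <= 0:
            raise CohortConfigError(f"subset_effects[{gene}]: fold must be > 0")
        if self.samples is None:
            if self.fraction is None or not (0 < self.fraction <= 1):
                raise CohortConfigError(
                    f"subset_effects[{gene}]: fraction_affected must be in (0, 1]")


@dataclass
class CohortConfig:
    """Everything the generator needs; all effects keyed by gene then group.

    Group keys may be concrete arms or the pooled pseudo-group ``HCC``.
    ``silent_flags`` maps gene -> iterable of groups (or ``"ALL"``) in which
    the gene sits at the background floor.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    genes: list[str] = field(default_factory=list)
    n_genes: int | None = None  # used only when ``genes`` is empty
    probes_per_gene: int = 8
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.2
    background_log2_mean: float = 6.0
    noise_log2_sd: float = 0.25
    probe_affinity_log2_sd: float = 0.25
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    dispersion_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    subset_effects: dict[str, dict[str, SubsetEffect]] = field(default_factory=dict)
    silent_flags: dict[str, tuple[str, ...] | str] = field(default_factory=dict)
    baseline_overrides: dict[str, float] = field(default_factory=dict)
    bias_amplitudes: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in PROBE_COVARIATES})
    array_scale_log2_sd: float = 0.0
    master_seed: int = 17

    # -- validation ------------------------------------------------------------
    def validate(self) -> None:
        for group, n in self.n_per_group.items():
            if group not in GROUP_ORDER:
                raise CohortConfigError(f"n_per_group: unknown group {group!r}")
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise CohortConfigError(f"n_per_group[{group}]: counts must be positive")
        if set(self.n_per_group) != set(GROUP_ORDER):
            raise CohortConfigError("n_per_group must cover all four sample groups")
        if not self.genes and not (self.n_genes and self.n_genes > 0):
            raise CohortConfigError("n_genes must be positive when genes is empty")
        if self.probes_per_gene < 1:
            raise CohortConfigError("probes_per_gene must be >= 1")
        if self.noise_log2_sd < 0:
            raise CohortConfigError("noise_log2_sd must be >= 0")
        if self.array_scale_log2_sd < 0:
            raise CohortConfigError("array_scale_log2_sd must be >= 0")
        for gene, effects in self.group_effects.items():
            for group, fc in effects.items():
                if fc <= 0:
                    raise CohortConfigError(
                        f"group_effects[{gene}][{group}]: fold-changes must be > 0")
        for gene, effects in self.dispersion_effects.items():
            for group, d in effects.items():
                if d <= 0:
                    raise CohortConfigError(
                        f"dispersion_effects[{gene}][{group}]: factors must be > 0")
        for gene, by_group in self.subset_effects.items():
            for eff in by_group.values():
                eff.validate(gene)
        for cov in self.bias_amplitudes:
            if cov not in PROBE_COVARIATES:
                raise CohortConfigError(f"bias_amplitudes: unknown covariate {cov!r}")

    def gene_ids(self) -> list[str]:
        if self.genes:
            return list(self.genes)
        return [f"G{i:05d}" for i in range(1, int(self.n_genes) + 1)]

    def silent_groups(self, gene: str) -> tuple[str, ...]:
        flag = self.silent_flags.get(gene)
        if flag is None:
            return ()
        if flag == "ALL":
            return GROUP_ORDER
        return tuple(g for raw in flag for g in resolve_group(raw))


@dataclass
class CohortTruth:
    """Every planted parameter, serializable and reloadable losslessly."""

    config: CohortConfig
    sample_groups: dict[str, str]
    baselines: dict[str, float]
    #: per gene per concrete group: planted linear fold-change vs NOR
    fold_changes: dict[str, dict[str, float]]
    dispersion: dict[str, dict[str, float]]
    silent: dict[str, tuple[str, ...]]
    #: per gene: resolved subset sample ids and extra fold
    subsets: dict[str, dict[str, object]]
    #: per sample: per-covariate bias amplitude and scale offset
    array_bias: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        cfg = asdict(self.config)
        cfg["subset_effects"] = {
            g: {grp: asdict(eff) for grp, eff in by.items()}
            for g, by in self.config.subset_effects.items()
        }
        cfg = plain(cfg)
        return {
            "config": cfg,
            "sample_groups": dict(self.sample_groups),
            "baselines": {g: float(v) for g, v in self.baselines.items()},
            "fold_changes": {g: {k: float(v) for k, v in d.items()}
                             for g, d in self.fold_changes.items()},
            "dispersion": {g: {k: float(v) for k, v in d.items()}
                           for g, d in self.dispersion.items()},
            "silent": {g: list(v) for g, v in self.silent.items()},
            "subsets": {g: {"samples": list(d["samples"]), "fold": float(d["fold"])}
                        for g, d in self.subsets.items()},
            "array_bias": {s: {k: float(v) for k, v in d.items()}
                           for s, d in self.array_bias.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortTruth":
        cfg = dict(d["config"])
        cfg["subset_effects"] = {
            g: {grp: SubsetEffect(
                    fold=e["fold"], fraction=e["fraction"],
                    samples=None if e["samples"] is None else tuple(e["samples"]))
                for grp, e in by.items()}
            for g, by in cfg.get("subset_effects", {}).items()
        }
        cfg["silent_flags"] = {
            g: (v if v == "ALL" else tuple(v)) for g, v in cfg.get("silent_flags", {}).items()
        }
        return cls(
            config=CohortConfig(**cfg),
            sample_groups=dict(d["sample_groups"]),
            baselines=dict(d["baselines"]),
            fold_changes={g: dict(v) for g, v in d["fold_changes"].items()},
            dispersion={g: dict(v) for g, v in d["dispersion"].items()},
            silent={g: tuple(v) for g, v in d["silent"].items()},
            subsets={g: {"samples": tuple(v["samples"]), "fold": v["fold"]}
                     for g, v in d["subsets"].items()},
            array_bias={s: dict(v) for s, v in d["array_bias"].items()},
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def sample_ids(n_per_group: dict[str, int]) -> tuple[list[str], dict[str, str]]:
    ids: list[str] = []
    groups: dict[str, str] = {}
    for group in GROUP_ORDER:
        for i in range(1, n_per_group[group] + 1):
            sid = f"{GROUP_PREFIX[group]}{i:02d}"
            ids.append(sid)
            groups[sid] = group
    return ids, groups


def generate_cohort(config: CohortConfig) -> tuple[ProbeTable, ExpressionMatrix, CohortTruth]:
    """Generate (probe-level table, gene-level matrix, ground truth).

    The gene-level matrix is the noiseless-summarization truth: probe values
    equal the gene value plus a median-centered affinity offset, before any
    technical bias is injected.
    """
    config.validate()
    genes = config.gene_ids()
    samples, group_of = sample_ids(config.n_per_group)
    n_genes, n_samples = len(genes), len(samples)
    group_arr = np.array([group_of[s] for s in samples])
    group_cols = {g: np.flatnonzero(group_arr == g) for g in GROUP_ORDER}

    # baselines ("baseline" stream)
    rng_base = _rng(config.master_seed, "baseline")
    baselines = config.baseline_log2_mean + config.baseline_log2_sd * rng_base.normal(size=n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, b in config.baseline_overrides.items():
        if g in gene_index:
            baselines[gene_index[g]] = b

    # planted log2 means and noise-sd factors
    log2m = np.tile(baselines[:, None], (1, n_samples))
    disp = np.ones((n_genes, n_samples))
    fold_truth: dict[str, dict[str, float]] = {}
    disp_truth: dict[str, dict[str, float]] = {}
    for g, effects in config.group_effects.items():
        if g not in gene_index:
            continue
        i = gene_index[g]
        fold_truth[g] = {}
        for raw, fc in effects.items():
            for grp in resolve_group(raw):
                log2m[i, group_cols[grp]] = baselines[i] + np.log2(fc)
                fold_truth[g][grp] = fc
    for g, effects in config.dispersion_effects.items():
        if g not in gene_index:
            continue
        i = gene_index[g]
        disp_truth[g] = {}
        for raw, d in effects.items():
            for grp in resolve_group(raw):
                disp[i, group_cols[grp]] = d
                disp_truth[g][grp] = d

    # sub-population effects ("subset" stream)
    rng_sub = _rng(config.master_seed, "subset")
    subset_truth: dict[str, dict[str, object]] = {}
    for g in genes:  # iterate in gene order so draws are order-stable
        by_group = config.subset_effects.get(g)
        if not by_group:
            continue
        i = gene_index[g]
        for raw in sorted(by_group):
            eff = by_group[raw]
            cols = np.concatenate([group_cols[grp] for grp in resolve_group(raw)])
            if eff.samples is not None:
                chosen = cols[np.asarray(eff.samples, dtype=int)]
            else:
                k = max(1, int(round(eff.fraction * len(cols))))
                chosen = rng_sub.choice(cols, size=k, replace=False)
            chosen = np.sort(chosen)
            log2m[i, chosen] += np.log2(eff.fold)
            rec = subset_truth.setdefault(g, {"samples": (), "fold": eff.fold})
            rec["samples"] = tuple(sorted(set(rec["samples"]) | {samples[c] for c in chosen}))
            rec["fold"] = eff.fold

    # silent gene-groups: background floor only, plain noise
    silent_truth: dict[str, tuple[str, ...]] = {}
    for g in genes:
        silent_in = config.silent_groups(g)
        if not silent_in:
            continue
        i = gene_index[g]
        silent_truth[g] = silent_in
        for grp in silent_in:
            log2m[i, group_cols[grp]] = config.background_log2_mean
            disp[i, group_cols[grp]] = 1.0
            fold_truth.get(g, {}).pop(grp, None)

    # measurement noise ("noise" stream)
    rng_noise = _rng(config.master_seed, "noise")
    log2v = log2m + config.noise_log2_sd * disp * rng_noise.normal(size=(n_genes, n_samples))

    expr = ExpressionMatrix(
        values=pd.DataFrame(np.exp2(log2v), index=pd.Index(genes, name="gene_id"),
                            columns=samples),
        groups=pd.Series(group_of, name="group"),
    )

    # probe level ("probes" stream): covariates, affinities
    rng_probe = _rng(config.master_seed, "probes")
    k = config.probes_per_gene
    n_probes = n_genes * k
    gc = rng_probe.uniform(0.30, 0.70, size=n_probes)
    tm = 50.0 + 40.0 * gc + rng_probe.normal(0.0, 1.5, size=n_probes)
    position = rng_probe.integers(0, 600, size=n_probes)
    affinity = rng_probe.normal(0.0, config.probe_affinity_log2_sd, size=(n_genes, k))
    affinity -= np.median(affinity, axis=1, keepdims=True)  # unbiased probe-set readout

    probe_log2 = np.repeat(log2v, k, axis=0) + affinity.reshape(-1, 1)
    meta = pd.DataFrame({
        "probe_id": [f"{g}_p{j + 1}" for g in genes for j in range(k)],
        "gene_id": np.repeat(genes, k),
        "gc_fraction": gc,
        "melting_temp": tm,
        "position_index": position,
    })
    probes = ProbeTable(pd.concat(
        [meta, pd.DataFrame(np.exp2(probe_log2), columns=samples)], axis=1))

    truth = CohortTruth(
        config=config,
        sample_groups=group_of,
        baselines={g: float(baselines[gene_index[g]]) for g in genes},
        fold_changes=fold_truth,
        dispersion=disp_truth,
        silent=silent_truth,
        subsets=subset_truth,
        array_bias={},
    )

    if any(a != 0 for a in config.bias_amplitudes.values()) or config.array_scale_log2_sd > 0:
        probes = inject_technical_bias(probes, truth)
    return probes, expr, truth


def _bias_shape(x: np.ndarray) -> np.ndarray:
    """Smooth monotone shape on [-1, 1] over the observed covariate range."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    z = 2.0 * (x - lo) / (hi - lo) - 1.0
    return np.tanh(2.0 * z) / np.tanh(2.0)


def inject_technical_bias(probes: ProbeTable, truth: CohortTruth) -> ProbeTable:
    """Add per-array smooth covariate bias plus a scale offset (log2 scale).

    Per-array signed amplitudes alternate in sign with the array index and
    jitter by +-20% around the configured amplitude, so the pooled-median
    reference stays close to bias-free while each array carries a substantial
    bias of its own.  All parameters are recorded in ``truth.array_bias``.
    """
    config = truth.config
    for cov in PROBE_COVARIATES:
        if cov not in probes.data.columns:
            raise ValueError(f"probe table missing covariate column {cov!r}")
    amps = {c: float(config.bias_amplitudes.get(c, 0.0)) for c in PROBE_COVARIATES}
    if all(a == 0 for a in amps.values()) and config.array_scale_log2_sd == 0:
        truth.array_bias = {s: {**{c: 0.0 for c in PROBE_COVARIATES}, "scale": 0.0}
                            for s in probes.samples}
        return probes

    rng = _rng(config.master_seed, "bias")
    shapes = {c: _bias_shape(probes.covariate(c)) for c in PROBE_COVARIATES}
    log2i = np.log2(probes.intensities.to_numpy())
    bias_rec: dict[str, dict[str, float]] = {}
    for a_idx, sample in enumerate(probes.samples):
        rec: dict[str, float] = {}
        total = np.zeros(log2i.shape[0])
        sign = 1.0 if a_idx % 2 == 0 else -1.0
        for cov in PROBE_COVARIATES:
            amp = amps[cov] * sign * (0.8 + 0.4 * rng.uniform())
            if amps[cov] == 0:
                amp = 0.0
            rec[cov] = amp
            total += amp * shapes[cov]
        scale = (rng.normal(0.0, config.array_scale_log2_sd)
                 if config.array_scale_log2_sd > 0 else 0.0)
        rec["scale"] = scale
        bias_rec[sample] = rec
        log2i[:, a_idx] += total + scale
    truth.array_bias = bias_rec
    return probes.with_intensities(np.exp2(log2i))


# ---------------------------------------------------------------------------
# the default study-mimicking cohort
# ---------------------------------------------------------------------------

#: noise-sd multiplier for dysregulated genes in disease groups; poor
#: transcriptional regulation widens the distribution without moving the
#: mean.  Set by power analysis: every planted gene must be detectable by
#: the combined mean-variance test at alpha < 0.001 under the cohort sizes,
#: which for the small-fold-change tumor-only genes requires the variance
#: channel to carry the detection (tumor log2 sd ~1.0, i.e. values spanning
#: a few two-fold changes -- the "broad, flat" densities of dysregulation).
TUMOR_DISPERSION = 3.0
TUMOR_ONLY_DISPERSION = 4.0
#: extra fold applied to the affected tumor sub-population of panel genes
PANEL_SUBSET_FOLD = 6.0
#: exclusive tumor samples per panel gene (no other panel gene covers them)
PANEL_EXCLUSIVE = 3


def _panel_subsets(n_tumor: int, rng: np.random.Generator) -> dict[str, tuple[int, ...]]:
    """Coordinated tumor sub-populations for the four marker-panel genes.

    Each gene receives ``PANEL_EXCLUSIVE`` reserved samples no other panel
    gene covers (so removing any one gene breaks full coverage), and the
    remaining samples are shared at random with the guarantee that every
    tumor sample is covered by at least one gene.
    """
    panel = list(reg.PANEL)
    reserved = {g: tuple(range(i * PANEL_EXCLUSIVE, (i + 1) * PANEL_EXCLUSIVE))
                for i, g in enumerate(panel)}
    n_res = PANEL_EXCLUSIVE * len(panel)
    members: dict[str, list[int]] = {g: list(reserved[g]) for g in panel}
    for s in range(n_res, n_tumor):
        take = [g for g in panel if rng.uniform() < 0.5]
        if not take:
            take = [panel[int(rng.integers(len(panel)))]]
        for g in take:
            members[g].append(s)
    return {g: tuple(sorted(v)) for g, v in members.items()}


def paper_mimic_config(master_seed: int = 17, probes_per_gene: int = 8) -> CohortConfig:
    """Default cohort mirroring the study design: 12 NOR / 30 CIR / 31 early /
    18 late samples over the 179-gene liver-development registry plus the
    1,399-gene silent registry, with planted effects taken from the published
    fold-change tables."""
    registry = reg.default_registry()
    genes = list(registry.liver_dev) + registry.silent

    group_effects: dict[str, dict[str, float]] = {}
    dispersion: dict[str, dict[str, float]] = {}
    for g, (c, e, l) in reg.CIR_PEAK_FC.items():
        group_effects[g] = {"CIR": c, "HCC_EARLY": e, "HCC_LATE": l}
        dispersion[g] = {"HCC_EARLY": TUMOR_DISPERSION, "HCC_LATE": TUMOR_DISPERSION}
    for g, (e, l) in reg.TUMOR_ONLY_FC.items():
        group_effects[g] = {"HCC_EARLY": e, "HCC_LATE": l}
        dispersion[g] = {"HCC_EARLY": TUMOR_ONLY_DISPERSION,
                         "HCC_LATE": TUMOR_ONLY_DISPERSION}
    for g in reg.DOWN_PERSISTENT:
        group_effects[g] = {"CIR": 0.5, "HCC_EARLY": 0.5, "HCC_LATE": 0.5}
        dispersion[g] = {"HCC_EARLY": TUMOR_DISPERSION, "HCC_LATE": TUMOR_DISPERSION}
    for g, l in reg.LATE_ONLY_FC.items():
        group_effects[g] = {"HCC_LATE": l}
        dispersion[g] = {"HCC_LATE": TUMOR_DISPERSION}
    amp_fill, sim_fill = reg.synthetic_de_fillers()
    for g, (c, e, l) in reg.SHARED_AMPLIFIED_FC.items():
        group_effects[g] = {"CIR": c, "HCC_EARLY": e, "HCC_LATE": l}
        dispersion[g] = {"HCC_EARLY": TUMOR_DISPERSION, "HCC_LATE": TUMOR_DISPERSION}
    for g in amp_fill:
        group_effects[g] = {"CIR": 2.0, "HCC_EARLY": 4.0, "HCC_LATE": 4.5}
        dispersion[g] = {"HCC_EARLY": TUMOR_DISPERSION, "HCC_LATE": TUMOR_DISPERSION}
    for g, (c, e, l) in reg.SHARED_SIMILAR_FC.items():
        group_effects[g] = {"CIR": c, "HCC_EARLY": e, "HCC_LATE": l}
        dispersion[g] = {"HCC_EARLY": TUMOR_DISPERSION, "HCC_LATE": TUMOR_DISPERSION}
    for i, g in enumerate(sim_fill):
        fc = 2.0 if i % 2 == 0 else 0.5
        group_effects[g] = {"CIR": fc, "HCC_EARLY": fc, "HCC_LATE": fc}
        dispersion[g] = {"HCC_EARLY": TUMOR_DISPERSION, "HCC_LATE": TUMOR_DISPERSION}

    # the marker panel: tumor coverage comes from planted sub-populations, not
    # a uniform group shift, so no single gene covers every tumor sample
    n_tumor = DEFAULT_N_PER_GROUP["HCC_EARLY"] + DEFAULT_N_PER_GROUP["HCC_LATE"]
    rng_panel = _rng(master_seed, "panel")
    subsets = _panel_subsets(n_tumor, rng_panel)
    subset_effects: dict[str, dict[str, SubsetEffect]] = {}
    for g in reg.PANEL:
        group_effects.setdefault(g, {})
        group_effects[g]["HCC_EARLY"] = 1.0
        group_effects[g]["HCC_LATE"] = 1.0
        dispersion[g] = {}  # keep tumor noise tight so coverage is subset-driven
        subset_effects[g] = {POOLED_HCC: SubsetEffect(fold=PANEL_SUBSET_FOLD,
                                                      samples=subsets[g])}

    # silent registry genes sit at the background floor in every group
    silent_flags: dict[str, tuple[str, ...] | str] = {g: "ALL" for g in registry.silent}
    for g in reg.SILENT_LIVER_GENES:
        silent_flags[g] = "ALL"

    # liver partners of paralog pairs are anchored well above background so the
    # planted divergence of the 31 expressed pairs is unambiguous
    rng_pairs = _rng(master_seed, "pairs")
    overrides = {}
    for liver, _ in registry.paralog_pairs:
        if liver in reg.SILENT_LIVER_GENES:
            continue
        overrides[liver] = float(np.clip(rng_pairs.normal(9.0, 0.8), 7.5, 11.5))

    return CohortConfig(
        n_per_group=dict(DEFAULT_N_PER_GROUP),
        genes=genes,
        probes_per_gene=probes_per_gene,
        group_effects=group_effects,
        dispersion_effects=dispersion,
        subset_effects=subset_effects,
        silent_flags=silent_flags,
        baseline_overrides=overrides,
        bias_amplitudes={"gc_fraction": 0.4, "melting_temp": 0.3, "position_index": 0.3},
        array_scale_log2_sd=0.15,
        master_seed=master_seed,
    )


def paper_mimic_cohort(master_seed: int = 17, probes_per_gene: int = 8):
    """Convenience wrapper: generate the default study-mimicking cohort."""
    return generate_cohort(paper_mimic_config(master_seed, probes_per_gene))
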