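"""Curated gene-set registry.

The screens operate over named gene sets rather than the whole array:

* ``liver_dev`` -- 179 regulators of embryonic liver development, annotated
  with the five developmental stages (hepatic fate specification, hepatoblast
  migration, liver bud growth, hepatocyte/biliary differentiation,
  maturation).  The published record names roughly half of them together with
  their disease-group fold-changes; the remaining slots in the packaged
  default are synthetic placeholders (``LDEV*``) that keep the registry at
  its full size and are freely replaceable by the user.
* ``silent`` -- 1,399 genes with zero RNA-seq evidence of expression in
  normal adult liver.  Only the 26 non-liver developmental paralogs are
  named; the rest are synthetic placeholders (``SILENT*``).
* ``paralog_pairs`` -- 33 liver-gene/non-liver-paralog pairs over 26 distinct
  paralogs (a paralog may partner several liver genes).
* ``ecm`` / ``bmp`` -- the extra-cellular-matrix and BMP-signaling functional
  sets used for PCA discrimination.
* ``panel`` -- the BMP-inhibitor marker panel GPC3, GREM1, FSTL3, FST.

The registry is a plain YAML-serializable object so users can extend or
replace every set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

STAGES: tuple[str, ...] = (
    "specification",
    "migration",
    "bud_growth",
    "differentiation",
    "maturation",
)

# ---------------------------------------------------------------------------
# Named gene tables.  Fold-changes are linear-scale group-mean ratios versus
# the normal group: (CIR, early HCC, late HCC).
# ---------------------------------------------------------------------------

#: genes over-expressed in cirrhosis with declining values in tumors
CIR_PEAK_FC: dict[str, tuple[float, float, float]] = {
    "EPCAM": (14.8, 14.0, 5.7),
    "MMP7": (7.5, 6.1, 3.5),
    "KRT19": (6.0, 2.9, 1.8),
    "MMP2": (5.4, 4.8, 3.0),
    "VIM": (5.8, 5.2, 4.8),
    "SOX9": (4.9, 3.2, 2.9),
    "LAMA2": (4.4, 2.3, 1.9),
    "FGFR2": (4.3, 2.4, 1.8),
    "KLF6": (3.9, 2.6, 1.8),
    "COL4A2": (3.9, 2.6, 2.3),
    "LAMB1": (3.5, 2.8, 1.5),
    "ARID5B": (3.4, 1.8, 1.7),
    "FSTL3": (3.4, 1.7, 1.5),
    "TGFB1": (3.2, 2.1, 1.5),
    "SMAD7": (3.2, 1.9, 1.4),
    "CITED2": (2.8, 2.0, 1.7),
    "GATA6": (2.8, 1.6, 0.9),
    "SFRP5": (2.6, 1.8, 1.5),
    "ID3": (2.4, 1.7, 1.3),
    "LAMC3": (2.4, 1.9, 1.3),
    "HAND2": (2.2, 1.7, 1.4),
    "NDN": (2.2, 1.3, 1.3),
    "PTN": (2.1, 1.6, 1.4),
    "ZBTB20": (2.1, 1.4, 1.3),
    "CDH1": (1.8, 1.5, 1.5),
    "FGF7": (1.7, 1.3, 1.2),
    "BMP2": (1.6, 1.4, 1.3),
    "COL4A4": (1.6, 1.2, 1.2),
    "CSNK1D": (1.5, 1.1, 1.0),
    "IRS2": (1.4, 1.1, 1.1),
}

#: genes changed only in tumors: (early HCC, late HCC) fold-changes
TUMOR_ONLY_FC: dict[str, tuple[float, float]] = {
    "DKK1": (3.8, 1.8),
    "MMP1": (2.4, 1.5),
    "FST": (1.9, 2.1),
    "TBX3": (1.3, 2.2),
    "MAP4K4": (1.3, 1.3),
    "INHBA": (1.3, 1.3),
    "HHEX": (1.3, 1.3),
    "ATF2": (1.3, 1.4),
    "BSG": (1.3, 1.4),
    "LAMA4": (1.2, 1.3),
    "FOXM1": (1.2, 1.1),
    "KRAS": (0.9, 0.7),
    "PROX1": (0.7, 0.5),
    "TGFBR3": (0.7, 0.6),
    "MST1": (0.6, 0.6),
    "STAT3": (0.6, 0.5),
}

#: genes down-regulated in cirrhosis that stay low in tumors
DOWN_PERSISTENT: tuple[str, ...] = (
    "FOXA1", "FOXA2", "GATA4", "HNF1A", "ACVR2B",
    "RXRA", "NRTN", "MMP15", "NF2",
)

#: genes changed exclusively in late-stage tumors: late-HCC fold-change
LATE_ONLY_FC: dict[str, float] = {
    "ACVR1": 2.0,
    "HMGA2": 2.5,
    "IGF2": 3.0,
    "CP": 0.5,
    "YAP1": 2.0,
}

#: cirrhosis-changed genes with larger-magnitude change in tumors
SHARED_AMPLIFIED_FC: dict[str, tuple[float, float, float]] = {
    "GPC3": (2.0, 7.2, 10.4),
    "GREM1": (2.0, 4.0, 6.0),
}

#: cirrhosis-changed genes with similar change persisting in tumors
SHARED_SIMILAR_FC: dict[str, tuple[float, float, float]] = {
    "BMPR1A": (2.0, 2.0, 1.9),
    "TIMP2": (1.8, 1.8, 1.8),
    "JUN": (0.6, 0.6, 0.7),
    "SOX17": (2.0, 2.0, 2.0),
    "KIT": (0.6, 0.5, 0.6),
    "HLX": (1.8, 1.8, 1.7),
    "FOXA3": (0.6, 0.6, 0.6),
    "AFP": (2.5, 2.5, 2.5),
    "FGF2": (1.7, 1.7, 1.6),
    "FGF4": (1.6, 1.6, 1.6),
    "WNT2": (0.6, 0.6, 0.6),
    "ID1": (1.8, 1.8, 1.8),
    "KDR": (1.7, 1.7, 1.7),
    "NFKB1": (0.6, 0.6, 0.6),
    "IL6": (1.8, 1.8, 1.9),
    "CCND1": (1.7, 1.7, 1.7),
    "LEF1": (1.6, 1.6, 1.6),
    "TCF3": (1.7, 1.7, 1.6),
}

#: genes expressed in liver but unchanged across disease groups
NULL_NAMED: tuple[str, ...] = ("BMP4", "HGF", "LHX2")

#: liver-development genes transcriptionally silent in every group; these are
#: the liver partners of the two paralog pairs whose distributions do not
#: diverge (synthetic placeholders -- the published record does not name them)
SILENT_LIVER_GENES: tuple[str, ...] = ("LDEVS01", "LDEVS02")

#: named non-liver developmental paralogs (silent in liver and tumors)
NAMED_PARALOGS: tuple[str, ...] = (
    "BMP3", "CDH3", "FGF3", "FGF12", "GATA1", "RXRG", "SOX1",
)

#: named liver-gene <-> paralog pairs
NAMED_PAIRS: tuple[tuple[str, str], ...] = (
    ("RXRA", "RXRG"),
    ("SOX9", "SOX1"),
    ("BMP2", "BMP3"),
    ("CDH1", "CDH3"),
    ("FGF7", "FGF3"),
    ("FGF2", "FGF12"),
    ("GATA4", "GATA1"),
    ("GATA6", "GATA1"),
)

ECM_SET: tuple[str, ...] = (
    "EPCAM", "MMP7", "MMP2", "MMP1", "LAMA2", "LAMB1", "LAMC3", "LAMA4",
    "COL4A2", "COL4A4", "CDH1", "VIM", "KRT19", "BSG", "TIMP2",
)

BMP_SET: tuple[str, ...] = (
    "BMP2", "BMPR1A", "GPC3", "GREM1", "FSTL3", "FST", "ID3", "ID1",
    "SMAD7", "FGF7", "FGFR2",
)

PANEL: tuple[str, ...] = ("GPC3", "GREM1", "FSTL3", "FST")

N_LIVER_DEV = 179
N_SILENT = 1399
N_PARALOGS = 26
N_PAIRS = 33


def _synthetic(prefix: str, count: int, start: int = 1) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(start, start + count)]


@dataclass
class GeneSetRegistry:
    """Named gene sets driving the screens; YAML round-trippable."""

    liver_dev: dict[str, str]  # gene -> developmental stage
    silent: list[str]
    paralog_pairs: list[tuple[str, str]]
    ecm: list[str]
    bmp: list[str]
    panel: list[str]

    def __post_init__(self) -> None:
        for name in ("silent", "ecm", "bmp", "panel"):
            ids = getattr(self, name)
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate gene ids in set {name!r}")
        bad_stages = {s for s in self.liver_dev.values() if s not in STAGES}
        if bad_stages:
            raise ValueError(f"unknown developmental stages: {sorted(bad_stages)}")
        silent = set(self.silent)
        loose = [p for _, p in self.paralog_pairs if p not in silent]
        if loose:
            raise ValueError(f"paralogs missing from the silent set: {sorted(set(loose))}")
        for liver, para in self.paralog_pairs:
            if liver == para:
                raise ValueError(f"pair references the same gene twice: {liver}")

    @property
    def paralogs(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, p in self.paralog_pairs:
            seen.setdefault(p)
        return list(seen)

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "liver_dev": dict(self.liver_dev),
            "silent": list(self.silent),
            "paralog_pairs": [list(p) for p in self.paralog_pairs],
            "ecm": list(self.ecm),
            "bmp": list(self.bmp),
            "panel": list(self.panel),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSetRegistry":
        return cls(
            liver_dev=dict(d["liver_dev"]),
            silent=list(d["silent"]),
            paralog_pairs=[tuple(p) for p in d["paralog_pairs"]],
            ecm=list(d["ecm"]),
            bmp=list(d["bmp"]),
            panel=list(d["panel"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneSetRegistry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def liver_dev_genes() -> list[str]:
    """The 179 liver-development registry slots, named genes first."""
    named = (
        list(CIR_PEAK_FC)
        + list(TUMOR_ONLY_FC)
        + list(DOWN_PERSISTENT)
        + list(LATE_ONLY_FC)
        + list(SHARED_AMPLIFIED_FC)
        + list(SHARED_SIMILAR_FC)
        + list(NULL_NAMED)
        + list(SILENT_LIVER_GENES)
    )
    assert len(named) == len(set(named)), "registry tables overlap"
    fillers_de = _synthetic("LDEV", 18, start=101)  # planted-effect placeholder slots
    fillers_null = _synthetic("LDEV", N_LIVER_DEV - len(named) - 18, start=201)
    return named + fillers_de + fillers_null


def synthetic_de_fillers() -> tuple[list[str], list[str]]:
    """Placeholder liver-dev slots carrying planted effects.

    Returns (amplified-in-tumor slots, similar-in-tumor slots); together with
    the named tables these bring the planted differential-expression count to
    98 of the 179 registry genes.
    """
    fillers = _synthetic("LDEV", 18, start=101)
    return fillers[:8], fillers[8:]


def silent_genes() -> list[str]:
    paralogs = list(NAMED_PARALOGS) + _synthetic("NLP", N_PARALOGS - len(NAMED_PARALOGS))
    return paralogs + _synthetic("SILENT", N_SILENT - len(paralogs))


def paralog_pairs() -> list[tuple[str, str]]:
    """The 33 liver/paralog pairs (26 distinct paralogs)."""
    synth_paralogs = _synthetic("NLP", N_PARALOGS - len(NAMED_PARALOGS))
    # liver partners for the synthetic pairs, drawn from the planted-effect sets
    liver_partners = [
        "EPCAM", "MMP7", "KRT19", "MMP2", "VIM", "LAMA2", "FGFR2", "KLF6",
        "COL4A2", "LAMB1", "ARID5B", "FSTL3", "TGFB1", "SMAD7", "CITED2",
        "SFRP5", "ID3", "LAMC3", "HAND2", "NDN", "PTN", "ZBTB20", "COL4A4",
    ]
    pairs = list(NAMED_PAIRS)
    # first six synthetic paralogs partner two liver genes each
    queue = synth_paralogs[:6] * 2 + synth_paralogs[6:17]
    for liver, para in zip(liver_partners, queue):
        pairs.append((liver, para))
    # the two non-divergent pairs: liver partner silent in tumors as well
    pairs.append((SILENT_LIVER_GENES[0], synth_paralogs[17]))
    pairs.append((SILENT_LIVER_GENES[1], synth_paralogs[18]))
    assert len(pairs) == N_PAIRS
    assert len({p for _, p in pairs}) == N_PARALOGS
    return pairs


def default_registry() -> GeneSetRegistry:
    """The packaged registry mirroring the published gene lists."""
    genes = liver_dev_genes()
    stages = {g: STAGES[i % len(STAGES)] for i, g in enumerate(genes)}
    # anchor a few well-characterized regulators to their actual stages
    stages.update({
        "FOXA1": "specification", "FOXA2": "specification", "GATA4": "specification",
        "GATA6": "specification", "HHEX": "migration", "PROX1": "migration",
        "TBX3": "bud_growth", "HGF": "bud_growth", "HLX": "bud_growth",
        "SOX9": "differentiation", "FGF7": "differentiation", "FGFR2": "differentiation",
        "HNF1A": "maturation", "CDH1": "maturation",
    })
    return GeneSetRegistry(
        liver_dev=stages,
        silent=silent_genes(),
        paralog_pairs=paralog_pairs(),
        ecm=list(ECM_SET),
        bmp=list(BMP_SET),
        panel=list(PANEL),
    )
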