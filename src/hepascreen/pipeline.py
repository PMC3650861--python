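"""End-to-end orchestration of the synthetic-cohort analysis.

``run_pipeline`` executes simulate -> preprocess -> screen -> silence ->
panel -> discriminate on a (by default study-mimicking) synthetic cohort and
writes every stage's report to the output directory together with a run
manifest (package version, master seed, config digest).  Given the same
configuration and seed the report directory is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as hio
from .discriminate import loocv_roc, pca_fit
from .panel import panel_coverage
from .preprocess import background_correct, covariate_normalize, qc_flag_arrays, summarize_probes
from .registry import default_registry
from .screen import flagged_any_disease, screen_gene_set
from .silence import paralog_screen, silence_screen
from .simulate import CohortConfig, generate_cohort, paper_mimic_config
from .types import TUMOR_GROUPS

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "screen", "silence", "panel", "discriminate")


def run_pipeline(out_dir, master_seed: int = 17,
                 config: CohortConfig | None = None,
                 alpha: float = 0.001) -> dict:
    """Run every stage; returns the manifest dict.  Any stage failure raises
    with the stage name; partial outputs are preserved."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    if config is None:
        config = paper_mimic_config(master_seed)
    else:
        config.master_seed = master_seed

    stage = "simulate"
    try:
        probes, expr, truth = generate_cohort(config)
        hio.write_probe_tsv(probes, out / "probes.tsv")
        hio.write_expression_tsv(expr, out / "expr.tsv", out / "groups.tsv")
        hio.write_truth(truth, out / "truth.json")

        stage = "preprocess"
        flagged = qc_flag_arrays(probes)
        (out / "qc.txt").write_text("\n".join(flagged) + ("\n" if flagged else ""))
        corrected = background_correct(probes, floor_quantile=0.0)
        normalized, _ = covariate_normalize(corrected)
        summarized = summarize_probes(normalized)
        summarized.groups = expr.groups
        hio.write_expression_tsv(summarized, out / "expr_normalized.tsv")

        stage = "screen"
        genes = [g for g in registry.liver_dev if g in expr.values.index]
        de = screen_gene_set(expr, genes, alpha=alpha)
        de.insert(0, "flagged_any_disease", flagged_any_disease(de))
        de.to_csv(out / "de_screen.tsv", sep="\t")

        stage = "silence"
        sil = silence_screen(expr, registry, alpha=alpha)
        sil.to_csv(out / "silence_report.tsv", sep="\t")
        pairs = paralog_screen(expr, registry, alpha=alpha)
        pairs.to_csv(out / "paralog_report.tsv", sep="\t", index=False)

        stage = "panel"
        tumors = [s for s in expr.samples if expr.groups[s] in TUMOR_GROUPS]
        report = panel_coverage(expr, registry.panel, tumors)
        report.per_sample.to_csv(out / "panel_report.tsv", sep="\t")

        stage = "discriminate"
        model = pca_fit(expr, [g for g in registry.bmp if g in expr.values.index])
        model.training_scores.to_csv(out / "pca_scores.tsv", sep="\t")
        tumor_labels = expr.groups.isin(TUMOR_GROUPS)
        roc = loocv_roc(expr, registry.panel, tumor_labels)
        roc.curve.to_csv(out / "roc_curve.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "master_seed": int(master_seed),
        "alpha": alpha,
        "config_digest": hashlib.sha256(
            json.dumps(_config_digest_payload(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_samples": int(expr.values.shape[1]),
        "n_genes": int(expr.values.shape[0]),
        "qc_flagged": flagged,
        "panel_coverage": report.coverage,
        "n_flagged_liver_genes": int(de["flagged_any_disease"].sum()),
        "n_expressed_silent": int(sil["expressed"].sum()),
        "n_divergent_pairs": int(pairs["different"].sum()),
        "loocv_auc": roc.auc,
        "loocv_sensitivity": roc.sensitivity,
        "loocv_specificity": roc.specificity,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_digest_payload(config: CohortConfig) -> dict:
    from dataclasses import asdict

    def plain(obj):
        if isinstance(obj, dict):
            return {str(k): plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        return obj

    return plain(asdict(config))
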