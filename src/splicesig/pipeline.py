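"""End-to-end orchestration of the two analysis arms.

Splicing arm: quantify the targeted splice event per sample, rank samples by
splicing percentage, stratify into tertiles and compare survival.  Signature
arm: select a gene signature from a DGE table (or load one from GMT), map
orthologs, score samples by ssGSEA, stratify, run KM/log-rank and Cox, and
optionally the random-signature specificity null.  Every run emits a
provenance manifest (config hash, derived seeds, package version) so results
are reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (PipelineConfig, derive_seed, load_target, read_clinical,
                 read_dge_table, read_expression, read_fastq, read_gmt,
                 write_counts_tsv)
from .junction import count_from_alignments, quantify_sample
from .signatures import map_orthologs, select_signature, ssgsea_score
from .survival import (cox_multivariate, km_logrank, random_signature_specificity,
                       stratify_by_score)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _require(config: PipelineConfig, *names: str) -> None:
    missing = [n for n in names if getattr(config, n) is None]
    if missing:
        raise ValueError(f"configuration is missing required paths/fields: {missing}")


def _jsonable(obj):
    if isinstance(obj, float) and obj != obj:
        return None
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute whichever arms the configuration describes; return the report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"arms": []}

    has_splicing = config.reads is not None or config.alignments is not None
    has_signature = config.expression is not None and config.clinical is not None

    if not has_splicing and not has_signature:
        raise ValueError("configuration describes neither analysis arm")

    # validate up front, before any computation
    if has_splicing:
        _require(config, "reference", "junction_start")
        if config.clinical is None:
            logger.info("splicing arm: no clinical table; survival step skipped")
    if has_signature:
        if config.dge_table is None and config.signature_gmt is None:
            raise ValueError("signature arm needs a DGE table or a signature GMT")

    if has_splicing:
        report["arms"].append("splicing")
        target = load_target(config.reference, config.junction_start,
                             config.excision_length)
        thresholds = config.detection_thresholds()
        if config.reads is not None:
            counts = quantify_sample(read_fastq(config.reads), target,
                                     config.alignment_params(), thresholds,
                                     sample_id=Path(config.reads).stem)
        else:
            counts = count_from_alignments(config.alignments, target, thresholds,
                                           sample_id=Path(config.alignments).stem)
        write_counts_tsv([counts], out_dir / "junction_counts.tsv")
        report["splicing"] = {
            "sample_id": counts.sample_id,
            "spliced_count": counts.spliced_count,
            "unspliced_count": counts.unspliced_count,
            "uninformative_count": counts.uninformative_count,
            "spliced_percent": _jsonable(counts.spliced_percent),
            "pass_threshold": counts.pass_threshold,
        }

    if has_signature:
        report["arms"].append("signature")
        expr = read_expression(config.expression)
        clinical = read_clinical(config.clinical)

        if config.dge_table is not None:
            table = read_dge_table(config.dge_table)
            sig = select_signature(table, config.log2fc_min, config.fdr_max,
                                   config.p_max, direction="up")
        else:
            sigs = read_gmt(config.signature_gmt)
            if not sigs:
                raise ValueError(f"{config.signature_gmt}: no gene sets")
            sig = sigs[0]
        if config.ortholog_map is not None:
            mapping = pd.read_csv(config.ortholog_map, sep="\t")
            mapped = map_orthologs(sig, mapping, first_match=True)
            logger.info("ortholog mapping: %d mapped, %d dropped",
                        mapped.n_mapped, mapped.n_dropped)
            sig = mapped.signature
        if len(sig) == 0:
            raise ValueError("selected signature is empty; relax the cutoffs")

        scores = ssgsea_score(expr, sig, alpha=config.ssgsea_alpha,
                              normalize=config.ssgsea_normalize)
        scores.to_csv(out_dir / "ssgsea_scores.tsv", sep="\t")
        cohort = stratify_by_score(scores[sig.name], mode=config.stratify_mode,
                                   ranking=sig.name)
        km = km_logrank(clinical, cohort)
        cox = cox_multivariate(clinical, cohort, covariates=config.covariates,
                               reference=config.cox_reference)
        sig_report = {
            "signature": sig.name,
            "signature_size": len(sig),
            "strata_n": km.n,
            "km_medians": {k: _jsonable(v) for k, v in km.medians.items()},
            "logrank_statistic": km.statistic,
            "logrank_p": km.p_value,
            "cox_converged": cox.converged,
        }
        if cox.summary is not None:
            sig_report["cox_terms"] = cox.summary.to_dict(orient="records")

        if config.universe is not None:
            universe = [ln.strip() for ln in open(config.universe)
                        if ln.strip()]
            spec = random_signature_specificity(
                expr, clinical, sig, universe,
                n_random=config.n_random, alpha=config.specificity_alpha,
                seed=derive_seed(config.seed, "specificity"),
                ssgsea_alpha=config.ssgsea_alpha)
            pd.DataFrame({"p_value": spec.p_values}).to_csv(
                out_dir / "random_signature_pvalues.tsv", sep="\t", index=False)
            sig_report["specificity"] = {
                "n_random": spec.n_random,
                "signature_length": spec.signature_length,
                "specificity": spec.specificity,
                "alpha": spec.alpha,
            }
        report["signature_arm"] = sig_report

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "derived_seeds": {"specificity": derive_seed(config.seed, "specificity")},
        "version": __version__,
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    with open(out_dir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, default=float)
    return report
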