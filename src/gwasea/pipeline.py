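"""End-to-end pipeline: annotation -> scores -> correction -> enrichment, with
a run manifest (input hashes, seed, version) so every output number is
recomputable from the output directory alone."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .correction import (
    apply_analytic_correction,
    permutation_correct,
    stepwise_regression_correct,
)
from .covariates import (
    compute_covariates,
    read_cumulative_map,
    read_hotspots,
    read_indep_snps,
    write_covariates,
)
from .enrichment import read_gmt, run_enrichment, write_results
from .gene_model import (
    BoundaryConfig,
    InputError,
    assign_snps,
    extend_boundaries,
    load_refflat,
    read_snp_table,
    write_regions,
)
from .scoring import score_genes, write_gene_scores

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A computation failure, tagged with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_inputs(config: RunConfig, need_gmt: bool) -> None:
    paths = config.input_paths()
    if need_gmt and "gmt" not in paths:
        raise InputError("enrichment inputs: no GMT gene-set file given")
    for name, path in paths.items():
        if not os.path.exists(path):
            stage = "enrichment inputs" if name == "gmt" else "inputs"
            raise InputError(f"{stage}: {name} file not found: {path}")


def run_pipeline(config: RunConfig, enrich: bool | None = None) -> str:
    """Run scoring (and, when a GMT is configured, enrichment); returns out_dir.

    Outputs written: ``config.yaml``, ``manifest.json``, ``gene_regions.tsv``,
    ``gene_scores.tsv``, ``covariates.tsv`` + ``regression_report.txt`` (for
    regression correction), and ``enrichment.tsv`` when gene sets are tested.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    do_enrich = bool(config.gmt) if enrich is None else enrich
    _validate_inputs(config, need_gmt=do_enrich)
    if config.genome_build:
        logger.info("genome build label: %s", config.genome_build)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        genes = load_refflat(config.refflat, max_span_bp=config.max_span_bp)
        snps = read_snp_table(config.assoc)
        cfg = BoundaryConfig(
            upstream_bp=config.upstream_bp,
            downstream_bp=config.downstream_bp,
            strand_aware=config.strand_aware,
        )
        regions = assign_snps(extend_boundaries(genes, cfg), snps)
        write_regions(regions, out / "gene_regions.tsv")
    except InputError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("gene model", exc) from exc

    try:
        scores = score_genes(regions, snps)
    except Exception as exc:
        raise PipelineError("scoring", exc) from exc

    model = None
    try:
        if config.correction == "regression":
            covs = compute_covariates(
                regions,
                snps,
                indep_snp_ids=read_indep_snps(config.indep_snps) if config.indep_snps else None,
                hotspots=read_hotspots(config.hotspots) if config.hotspots else None,
                genetic_map=read_cumulative_map(config.genetic_map) if config.genetic_map else None,
                ldu_map=read_cumulative_map(config.ldu_map) if config.ldu_map else None,
            )
            write_covariates(covs, out / "covariates.tsv")
            scores, model = stepwise_regression_correct(
                scores, covs,
                entry_p=config.entry_p, removal_p=config.removal_p,
                covariates=config.covariates, missing=config.missing_covariates,
            )
            (out / "regression_report.txt").write_text(model.report_text() + "\n")
            model.report_frame().to_csv(
                out / "regression_report.tsv", sep="\t", index=False, na_rep="NA",
                float_format="%.6g",
            )
        elif config.correction in ("sidak", "modified_sidak"):
            scores = apply_analytic_correction(scores, method=config.correction)
        elif config.correction == "permutation":
            stack = pd.read_csv(config.null_stack, sep="\t", index_col=0)
            scores = permutation_correct(scores, stack.reindex(scores.index))
        else:  # none: pass the raw best-SNP p through
            scores = scores.copy()
            scores["p_corrected"] = scores["p_best"]
            scores["z_corrected"] = scores["z_raw"]
    except InputError:
        raise
    except Exception as exc:
        raise PipelineError("correction", exc) from exc

    write_gene_scores(scores, out / "gene_scores.tsv")

    if do_enrich:
        try:
            sets = read_gmt(config.gmt)
            results = run_enrichment(
                sets, scores,
                stat=config.stat,
                cutoff_percentile=config.cutoff_percentile,
                n_null=config.n_null,
                adaptive=config.adaptive,
                seed=config.seed,
                min_set_size=config.min_set_size,
                max_n_null=config.max_n_null,
                null_method=config.null_method,
            )
            write_results(results, out / "enrichment.tsv")
        except Exception as exc:
            raise PipelineError("enrichment", exc) from exc

    config.to_yaml(out / "config.yaml")
    manifest = {
        "package": "gwasea",
        "version": __version__,
        "seed": config.seed,
        "inputs": {name: {"path": p, "sha256": _sha256(p)} for name, p in config.input_paths().items()},
        "n_genes": int(len(scores)),
        "n_genes_no_snps": int(scores["excluded_no_snps"].sum()),
        "n_snps": int(len(snps)),
        "correction": config.correction,
        "selected_covariates": model.selected_covariates if model else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return str(out)
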