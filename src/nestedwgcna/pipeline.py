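"""End-to-end orchestration: filter -> CGMs -> cores -> FGMs -> outputs.

`run_full` executes the complete two-stage analysis and writes a
reproducible output bundle:

* ``modules.gmt`` — one set per CGM (``CGM_<k>``), its maximum core
  (``CGM_<k>_core``) and each fine-grained module (``CGM_<k>_FGM_<j>``);
* ``cgm_assignment.tsv`` / ``fgm_assignment.tsv`` — per-gene labels;
* ``run_metadata.json`` — every parameter, derived value and the seed, plus
  a config hash so two identical runs are provably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_decomposition import extract_core
from .gmt import write_gmt
from .matrix import ExpressionMatrix, ValidationError, load_expression
from .module_detection import (
    DEFAULT_MIN_CLUSTER_SIZE,
    ModuleAssignment,
    derive_params,
    detect_cgms,
)
from .nested_inference import (
    DEFAULT_CV_RATIO_THRESHOLD,
    DEFAULT_FGM_MIN_CLUSTER_SIZE,
    DEFAULT_RHO_THRESHOLD,
    FGMSet,
    infer_fgms,
)
from .network import compute_adjacency
from .preprocessing import DEFAULT_ME_THRESHOLD, filter_genes, load_annotation

__all__ = ["RunConfig", "RunResult", "run_full"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run depends on; hashed into the output metadata."""

    input_path: str | None = None
    input_format: str | None = None
    annotation_path: str | None = None
    transform: str = "none"
    corr_method: str = "pearson"
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    fgm_min_cluster_size: int = DEFAULT_FGM_MIN_CLUSTER_SIZE
    rho_threshold: float = DEFAULT_RHO_THRESHOLD
    cv_ratio_threshold: float = DEFAULT_CV_RATIO_THRESHOLD
    me_threshold: float = DEFAULT_ME_THRESHOLD
    skip_gene_filter: bool = False
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunResult:
    cgms: ModuleAssignment
    cores: dict[int, set[str]]
    fgms: dict[int, FGMSet]
    gene_sets: dict[str, list[str]]
    metadata: dict


def run_full(config: RunConfig, expr: ExpressionMatrix | None = None) -> RunResult:
    """Run the two-stage pipeline from a config (and optionally an
    in-memory matrix instead of ``config.input_path``)."""
    if expr is None:
        if config.input_path is None:
            raise ValidationError("config has no input_path and no matrix was given")
        expr = load_expression(
            config.input_path, format=config.input_format, transform=config.transform
        )

    if config.skip_gene_filter:
        filtered, report = expr, None
    else:
        annotation = (
            load_annotation(config.annotation_path) if config.annotation_path else None
        )
        filtered, report = filter_genes(
            expr, annotation=annotation, me_threshold=config.me_threshold
        )
        logger.info(
            "gene filter: %d -> %d genes (%d noncoding, %d low-information dropped)",
            expr.n_genes,
            filtered.n_genes,
            len(report.dropped_noncoding),
            len(report.dropped_low_information),
        )

    cgms = detect_cgms(
        filtered,
        min_cluster_size=config.min_cluster_size,
        seed=config.seed,
        corr_method=config.corr_method,
    )
    logger.info("detected %d CGMs (%d noise genes)", cgms.n_modules, len(cgms.noise_genes))

    work = filtered.log2p1() if filtered.space == "linear" else filtered
    adj = compute_adjacency(work, corr_method=config.corr_method)

    cores: dict[int, set[str]] = {}
    fgms: dict[int, FGMSet] = {}
    gene_sets: dict[str, list[str]] = {}
    for m in cgms.module_ids:
        genes = cgms.module_genes(m)
        gene_sets[f"CGM_{m}"] = genes
        core = extract_core(genes, adj)
        cores[m] = core
        gene_sets[f"CGM_{m}_core"] = sorted(core)
        try:
            fgm = infer_fgms(
                filtered,
                cgm_genes=genes,
                core_genes=core,
                fgm_min_cluster_size=config.fgm_min_cluster_size,
                seed=config.seed,
                parent_cgm=m,
                rho_threshold=config.rho_threshold,
                cv_ratio_threshold=config.cv_ratio_threshold,
                corr_method=config.corr_method,
            )
        except ValidationError as exc:
            # one module failing its normalization gate should not void the
            # rest of the run; it simply yields no FGMs
            logger.warning("FGM inference skipped for CGM %d: %s", m, exc)
            fgm = FGMSet(
                parent_cgm=m,
                assignment=ModuleAssignment(
                    gene_ids=sorted(genes),
                    labels=np.full(len(genes), -1),
                    level="FGM",
                    parent_module=m,
                ),
            )
        fgms[m] = fgm
        for j, fgm_genes in fgm.fgm_genes.items():
            gene_sets[f"CGM_{m}_FGM_{j}"] = fgm_genes

    cgm_params = derive_params(filtered.n_samples, config.min_cluster_size, config.seed)
    metadata = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes_input": expr.n_genes,
        "n_genes_after_filter": filtered.n_genes,
        "n_samples": expr.n_samples,
        "derived_params": cgm_params.as_dict(),
        "n_cgms": cgms.n_modules,
        "n_fgms": {m: fgms[m].n_fgms for m in fgms},
        "core_sizes": {m: len(cores[m]) for m in cores},
    }
    if report is not None:
        metadata["gene_filter"] = {
            "dropped_noncoding": len(report.dropped_noncoding),
            "dropped_low_information": len(report.dropped_low_information),
            "threshold": report.threshold,
        }

    result = RunResult(
        cgms=cgms, cores=cores, fgms=fgms, gene_sets=gene_sets, metadata=metadata
    )
    if config.output_dir is not None:
        write_bundle(result, Path(config.output_dir))
    return result


def write_bundle(result: RunResult, outdir: Path) -> None:
    """Write the GMT / TSV / JSON output bundle."""
    outdir.mkdir(parents=True, exist_ok=True)
    write_gmt(result.gene_sets, outdir / "modules.gmt")
    result.cgms.to_tsv(outdir / "cgm_assignment.tsv")
    fgm_rows = []
    for m, fgm in result.fgms.items():
        for g, l in zip(fgm.assignment.gene_ids, fgm.assignment.labels):
            fgm_rows.append({"gene_id": g, "parent_cgm": m, "fgm_label": int(l)})
    pd.DataFrame(fgm_rows).to_csv(outdir / "fgm_assignment.tsv", sep="\t", index=False)
    with open(outdir / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(result.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
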