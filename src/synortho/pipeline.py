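"""End-to-end orchestration: anchors -> collinearity -> orthology -> transfer
-> comparison/validation, from a single config with one root seed.

Every stage communicates through files written into the run directory, so a
run can be resumed or inspected stage by stage; the manifest records counts
and checksums for reproducibility (same config + seed => same checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import coexpr_validate, collinearity, maa_extract, orthology, transfer
from .collinearity import DetectionParams, GENE_PARAMS, MAA_PARAMS
from .formats_io import (
    read_annotation_table,
    read_expression_matrix,
    read_gene_models,
    read_homology_table,
    read_maf,
    read_obo,
    read_phylo_order,
    write_annotation_table,
)

logger = logging.getLogger("synortho")

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    maf: str
    gff_by_species: dict[str, str]
    hits: str
    phylo_order: str
    out_dir: str
    obo: str | None = None
    annotations_by_species: dict[str, str] = field(default_factory=dict)
    expression: str | None = None
    maa_params: DetectionParams = MAA_PARAMS
    gene_params: DetectionParams = GENE_PARAMS
    min_overlap: float = orthology.DEFAULT_MIN_OVERLAP
    evalue_cutoff: float = orthology.DEFAULT_EVALUE
    min_term_genes: int = transfer.DEFAULT_MIN_TERM_GENES
    max_term_genes: int = transfer.DEFAULT_MAX_TERM_GENES
    alpha: float = coexpr_validate.DEFAULT_ALPHA
    repeats: int = coexpr_validate.DEFAULT_REPEATS
    seed: int = 0
    validate: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("maa_params", "gene_params"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = DetectionParams(**raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> dict[str, Any]:
    """Run all stages in order; returns the run manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": {}, "seed": config.seed}

    def record(stage: str, counts: dict[str, Any], files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "counts": counts,
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        logger.info("stage %s done: %s", stage, counts)

    order = read_phylo_order(config.phylo_order)
    ref = order.reference
    genes_by_species = {
        sp: read_gene_models(path, species=sp)
        for sp, path in config.gff_by_species.items()
    }

    # --- stage 1: anchors -------------------------------------------------
    blocks = read_maf(config.maf, reference_species=ref)
    maas = maa_extract.extract_maas(blocks, set(order.species))
    maa_bed = out / "maas.bed"
    maa_extract.anchors_to_bed(maas, maa_bed)
    record("maa", {"blocks": len(blocks), "maas": len(maas)}, [maa_bed])

    # --- stage 2: collinearity with both marker types ---------------------
    hits = read_homology_table(config.hits)
    maa_segments: list[collinearity.CollinearSegment] = []
    gene_segments: list[collinearity.CollinearSegment] = []
    ref_maa_markers = collinearity.maa_markers(blocks, ref)
    ref_gene_markers = collinearity.gene_markers(genes_by_species[ref])
    for sp in order.species[1:]:
        sp_maa = collinearity.maa_markers(blocks, sp)
        pairs = collinearity.build_homology_pairs(ref_maa_markers, sp_maa)
        maa_segments.extend(
            collinearity.detect_pairwise_segments(
                ref_maa_markers, sp_maa, pairs, config.maa_params, ref, sp
            )
        )
        sp_genes = collinearity.gene_markers(genes_by_species[sp])
        gpairs = collinearity.build_homology_pairs(
            ref_gene_markers, sp_genes, hits, config.evalue_cutoff
        )
        gene_segments.extend(
            collinearity.detect_pairwise_segments(
                ref_gene_markers, sp_genes, gpairs, config.gene_params, ref, sp
            )
        )
    seg_files = []
    for name, segs in (("maa_segments.tsv", maa_segments), ("gene_segments.tsv", gene_segments)):
        path = out / name
        collinearity.segments_to_table(segs).to_csv(path, sep="\t", index=False)
        seg_files.append(path)
    n_way, pairwise = collinearity.classify_levels(maa_segments, order)
    levels_path = out / "maa_levels.tsv"
    collinearity.segment_summary(n_way + pairwise).to_csv(levels_path, sep="\t", index=False)
    record(
        "collinearity",
        {
            "maa_segments": len(maa_segments),
            "gene_segments": len(gene_segments),
            "n_way_levels": len(n_way),
            "pairwise_levels": len(pairwise),
        },
        seg_files + [levels_path],
    )

    # --- stage 3: orthology -----------------------------------------------
    opps = orthology.infer_opps(
        genes_by_species,
        maa_segments,
        gene_segments,
        hits,
        order,
        min_overlap=config.min_overlap,
        evalue_cutoff=config.evalue_cutoff,
    )
    opp_path = out / "opps.tsv"
    orthology.opps_to_table(opps).to_csv(opp_path, sep="\t", index=False)
    record("orthology", {"opps": len(opps)}, [opp_path])

    # --- stage 4: annotation transfer --------------------------------------
    ann_files = []
    transferred = None
    if config.annotations_by_species:
        sources = {
            sp: read_annotation_table(path)
            for sp, path in config.annotations_by_species.items()
        }
        transferred = transfer.transfer_annotations(opps, sources, ref)
        transferred = transfer.filter_term_sizes(
            transferred, config.min_term_genes, config.max_term_genes
        )
        ann_path = out / "transferred_annotations.tsv"
        write_annotation_table(transferred, ann_path)
        ann_files.append(ann_path)
        summary = transfer.annotation_summary(
            transferred, [g.gene_id for g in genes_by_species[ref]]
        )
        record(
            "transfer",
            {
                "n_genes": summary.n_genes,
                "n_terms": summary.n_terms,
                "mean_terms_per_gene": summary.mean_terms_per_gene,
                "coverage": summary.coverage_fraction,
            },
            ann_files,
        )

    # --- stage 5: co-expression validation ---------------------------------
    if config.validate and config.expression and transferred is not None:
        matrix = read_expression_matrix(config.expression)
        dag = read_obo(config.obo) if config.obo else None
        rng = np.random.default_rng(config.seed)
        summary, results = coexpr_validate.validation_summary(
            transferred,
            matrix,
            dag,
            alpha=config.alpha,
            term_size_limits=(config.min_term_genes, config.max_term_genes),
            repeats=config.repeats,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        val_path = out / "validation.tsv"
        coexpr_validate.results_to_table(results, dag).to_csv(val_path, sep="\t", index=False)
        record(
            "validate",
            {ns: {"tested": n, "significant": s, "ratio": r}
             for ns, (n, s, r) in summary.items()},
            [val_path],
        )

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
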