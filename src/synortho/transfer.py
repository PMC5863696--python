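"""Cross-species transfer of ontology terms through ortholog pairs.

A target gene inherits the union of the terms of all its orthologs in
annotated source species; provenance records every contributing ortholog and
its OPSS.  A term-size filter then removes terms with fewer than 5 or more
than 300 associated target genes, the standard guard against uninformative
(overly specific or overly generic) terms.  The procedure is
ontology-agnostic: GO and PO tables run through the same operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats_io import AnnotationSet
from .orthology import OrthologPair

__all__ = [
    "transfer_annotations",
    "filter_term_sizes",
    "annotation_summary",
    "AnnotationSummary",
]

DEFAULT_MIN_TERM_GENES = 5
DEFAULT_MAX_TERM_GENES = 300


@dataclass(frozen=True)
class AnnotationSummary:
    n_genes: int
    n_terms: int
    mean_terms_per_gene: float
    mean_genes_per_term: float
    coverage_fraction: float | None


def transfer_annotations(
    opps: Sequence[OrthologPair],
    source_annotations: Mapping[str, AnnotationSet],
    target_species: str | None = None,
) -> AnnotationSet:
    """Annotate target genes with the union of their orthologs' terms.

    OPPs whose partner species has no annotation set are skipped silently.
    ``target_species`` is informational; the target gene of each OPP is its
    reference-side gene (gene_a).
    """
    pairs: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for opp in opps:
        source = source_annotations.get(opp.species_b)
        if source is None:
            continue
        for term in source.terms_of(opp.gene_b):
            key = (opp.gene_a, term)
            pairs.add(key)
            provenance.setdefault(key, []).append((opp.gene_b, opp.species_b, opp.opss))
    return AnnotationSet(pairs, provenance)


def filter_term_sizes(
    annset: AnnotationSet,
    min_genes: int = DEFAULT_MIN_TERM_GENES,
    max_genes: int = DEFAULT_MAX_TERM_GENES,
) -> AnnotationSet:
    """Keep terms whose gene count is within [min_genes, max_genes]."""
    keep_terms = {
        t for t in annset.terms if min_genes <= len(annset.genes_of(t)) <= max_genes
    }
    pairs = {(g, t) for g, t in annset.pairs if t in keep_terms}
    provenance = {k: v for k, v in annset.provenance.items() if k in pairs}
    return AnnotationSet(pairs, provenance)


def annotation_summary(
    annset: AnnotationSet, gene_universe: Sequence[str] | None = None
) -> AnnotationSummary:
    """Per-gene and per-term averages, plus coverage of a supplied universe."""
    n_genes, n_terms, n_pairs = len(annset.genes), len(annset.terms), len(annset.pairs)
    coverage = None
    if gene_universe is not None and len(gene_universe) > 0:
        coverage = n_genes / len(gene_universe)
    return AnnotationSummary(
        n_genes=n_genes,
        n_terms=n_terms,
        mean_terms_per_gene=n_pairs / n_genes if n_genes else 0.0,
        mean_genes_per_term=n_pairs / n_terms if n_terms else 0.0,
        coverage_fraction=coverage,
    )
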