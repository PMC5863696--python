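"""Ortholog inference from collinear segments and the OPSS evidence score.

A cross-species gene pair is accepted as an orthologous protein-coding gene
pair (OPP) when (i) the genes share sequence similarity (a hit at E <= 1e-5)
and (ii) at least half of each gene's length lies inside the two sides of one
MAA-based collinear segment.  Two optional lines of evidence are recorded:
(iii) the pair is a bidirectional best hit (BBH), and (iv) condition (ii)
also holds for a segment detected with protein-coding genes as markers.

Each OPP carries a composite support score

    OPSS = M + 0.5 * P + B

where M is the collinearity degree (n of the deepest n-way level, or 2 for a
purely pairwise segment) of the best supporting MAA-based segment, P the same
for gene-based segments (0 when absent), and B is 2 for BBH pairs, else 0.
A pair supported only by a pairwise MAA segment therefore scores exactly 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .collinearity import CollinearSegment, annotate_segment_degrees
from .formats_io import GeneModel, HomologyHit, PhyloOrder

__all__ = [
    "OrthologPair",
    "compute_bbh",
    "gene_segment_overlap",
    "infer_opps",
    "score_opss",
    "opss_distribution",
    "opps_to_table",
]

BBH_SCORE = 2.0
DEFAULT_EVALUE = 1e-5
DEFAULT_MIN_OVERLAP = 0.5


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    species_b: str
    has_similarity: bool
    maa_overlap_ok: bool
    is_bbh: bool
    protein_collinear_ok: bool
    m_score: float
    p_score: float
    b_score: float

    @property
    def opss(self) -> float:
        return score_opss(self.m_score, self.p_score, self.b_score)


def score_opss(
    m_score: float, p_score: float, b_score: float, max_degree: int = 15
) -> float:
    """OPSS = M + 0.5 * P + B, with component ranges validated."""
    for name, v in (("m_score", m_score), ("p_score", p_score)):
        if v != 0 and not (2 <= v <= max_degree):
            raise ValueError(f"{name} must be 0 or in [2, {max_degree}], got {v}")
    if b_score not in (0, BBH_SCORE):
        raise ValueError(f"b_score must be 0 or {BBH_SCORE}, got {b_score}")
    return float(m_score + 0.5 * p_score + b_score)


def compute_bbh(
    hits: Sequence[HomologyHit],
    gene_species: Mapping[str, str],
    evalue_cutoff: float = DEFAULT_EVALUE,
) -> set[frozenset[str]]:
    """Bidirectional best hits between species.

    For every gene and every other species, the best subject is the hit with
    the largest bitscore (ties: smaller e-value, then lexicographic subject
    id).  A pair is a BBH when each gene is the other's best in its species.
    """
    best: dict[tuple[str, str], tuple[float, float, str]] = {}
    for h in hits:
        if h.e_value > evalue_cutoff:
            continue
        sp_q = gene_species.get(h.query_gene)
        sp_s = gene_species.get(h.subject_gene)
        if sp_q is None or sp_s is None or sp_q == sp_s:
            continue
        for q, s, sp in ((h.query_gene, h.subject_gene, sp_s),
                         (h.subject_gene, h.query_gene, sp_q)):
            cand = (-h.bitscore, h.e_value, s)
            cur = best.get((q, sp))
            if cur is None or cand < cur:
                best[(q, sp)] = cand
    out: set[frozenset[str]] = set()
    for (q, sp), (_, _, s) in best.items():
        rec = best.get((s, gene_species[q]))
        if rec is not None and rec[2] == q:
            out.add(frozenset((q, s)))
    return out


def gene_segment_overlap(gene: GeneModel, region) -> float:
    """Fraction of the gene's length inside a segment region on its genome."""
    return gene.interval.overlap(region) / gene.interval.length


def _supporting_segments(
    gene_ref: GeneModel,
    gene_other: GeneModel,
    segments: Sequence[CollinearSegment],
    min_overlap: float,
) -> list[CollinearSegment]:
    out = []
    for seg in segments:
        if (
            gene_segment_overlap(gene_ref, seg.region_a) >= min_overlap
            and gene_segment_overlap(gene_other, seg.region_b) >= min_overlap
        ):
            out.append(seg)
    return out


def infer_opps(
    genes_by_species: Mapping[str, Sequence[GeneModel]],
    maa_segments: Sequence[CollinearSegment],
    gene_segments: Sequence[CollinearSegment],
    hits: Sequence[HomologyHit],
    order: PhyloOrder,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    evalue_cutoff: float = DEFAULT_EVALUE,
) -> list[OrthologPair]:
    """Infer OPPs between the reference and every partner species.

    Segments must be anchored on the reference (genome_a).  M- and P-scores
    take the MAXIMUM degree over supporting segments of the respective marker
    type; a purely pairwise supporting segment contributes degree 2.
    """
    gene_index: dict[str, GeneModel] = {}
    gene_species: dict[str, str] = {}
    for sp, genes in genes_by_species.items():
        for g in genes:
            gene_index[g.gene_id] = g
            gene_species[g.gene_id] = sp
    for seg_list, kind in ((gene_segments, "gene-based"),):
        for seg in seg_list:
            for ga, gb in seg.anchors:
                if ga not in gene_index or gb not in gene_index:
                    missing = ga if ga not in gene_index else gb
                    raise ValueError(
                        f"{kind} segment {seg.segment_id} references unknown gene {missing!r}"
                    )

    reference = order.reference
    maa_by_species: dict[str, list[CollinearSegment]] = {}
    for seg in maa_segments:
        maa_by_species.setdefault(seg.genome_b, []).append(seg)
    gene_by_species_seg: dict[str, list[CollinearSegment]] = {}
    for seg in gene_segments:
        gene_by_species_seg.setdefault(seg.genome_b, []).append(seg)

    maa_degrees = annotate_segment_degrees(maa_segments, order) if maa_segments else {}
    gene_degrees = annotate_segment_degrees(gene_segments, order) if gene_segments else {}
    bbh = compute_bbh(hits, gene_species, evalue_cutoff)

    candidates: set[tuple[str, str]] = set()
    for h in hits:
        if h.e_value > evalue_cutoff:
            continue
        sp_q = gene_species.get(h.query_gene)
        sp_s = gene_species.get(h.subject_gene)
        if sp_q is None or sp_s is None:
            continue
        if sp_q == reference and sp_s != reference:
            candidates.add((h.query_gene, h.subject_gene))
        elif sp_s == reference and sp_q != reference:
            candidates.add((h.subject_gene, h.query_gene))

    opps: list[OrthologPair] = []
    for gene_ref_id, gene_other_id in sorted(candidates):
        g_ref = gene_index[gene_ref_id]
        g_other = gene_index[gene_other_id]
        sp_other = gene_species[gene_other_id]
        maa_support = _supporting_segments(
            g_ref, g_other, maa_by_species.get(sp_other, []), min_overlap
        )
        if not maa_support:
            continue
        gene_support = _supporting_segments(
            g_ref, g_other, gene_by_species_seg.get(sp_other, []), min_overlap
        )
        m = max(maa_degrees[s.segment_id] for s in maa_support)
        p = max((gene_degrees[s.segment_id] for s in gene_support), default=0)
        is_bbh = frozenset((gene_ref_id, gene_other_id)) in bbh
        opps.append(
            OrthologPair(
                gene_a=gene_ref_id,
                gene_b=gene_other_id,
                species_b=sp_other,
                has_similarity=True,
                maa_overlap_ok=True,
                is_bbh=is_bbh,
                protein_collinear_ok=bool(gene_support),
                m_score=float(m),
                p_score=float(p),
                b_score=BBH_SCORE if is_bbh else 0.0,
            )
        )
    return opps


def opss_distribution(
    opps: Sequence[OrthologPair], bins: Iterable[float]
) -> pd.DataFrame:
    """Histogram of OPSS values; fractions sum to 1 on non-empty input."""
    bins = np.asarray(list(bins), dtype=float)
    values = np.array([o.opss for o in opps], dtype=float)
    counts, edges = np.histogram(values, bins=bins)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "fraction": counts / total if total else np.zeros_like(counts, dtype=float),
        }
    )


def table_to_opps(df: pd.DataFrame) -> list[OrthologPair]:
    """Rebuild OrthologPair records from an opps_to_table frame."""
    return [
        OrthologPair(
            gene_a=str(r.gene_a),
            gene_b=str(r.gene_b),
            species_b=str(r.species_b),
            has_similarity=True,
            maa_overlap_ok=True,
            is_bbh=bool(r.is_bbh),
            protein_collinear_ok=bool(r.protein_collinear_ok),
            m_score=float(r.m_score),
            p_score=float(r.p_score),
            b_score=float(r.b_score),
        )
        for r in df.itertuples()
    ]


def opps_to_table(opps: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": o.gene_a,
                "gene_b": o.gene_b,
                "species_b": o.species_b,
                "m_score": o.m_score,
                "p_score": o.p_score,
                "b_score": o.b_score,
                "opss": o.opss,
                "is_bbh": o.is_bbh,
                "protein_collinear_ok": o.protein_collinear_ok,
            }
            for o in opps
        ]
    )
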