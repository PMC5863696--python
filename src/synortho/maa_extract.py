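"""Extraction of multiple-alignment anchors (MAAs) and marker statistics.

An MAA is an alignment block conserved across every species of a required set
(typically all species in the multi-genome alignment), projected onto the
reference genome.  Because they are short, structurally stable and densely
distributed, MAAs serve as genome-wide markers for collinearity detection in
place of protein-coding genes.  This module also computes the descriptive
statistics used to characterise a marker set: length distribution, genome
coverage, GC enrichment over background, per-chromosome uniformity, and
composition by genomic feature class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import GeneModel, GenomicInterval, MultiAlignmentBlock

__all__ = [
    "Anchor",
    "MarkerStats",
    "extract_maas",
    "marker_stats",
    "gc_enrichment",
    "uniformity_test",
    "feature_composition",
    "anchors_to_bed",
]

#: Per-base classification precedence when feature annotations overlap.
FEATURE_PRECEDENCE = ["CDS", "UTR", "ncRNA", "intron", "intergenic", "gene_desert"]

#: An intergenic stretch longer than this is classified as gene desert.
GENE_DESERT_MIN_GAP = 30_000


@dataclass(frozen=True)
class Anchor:
    """A genomic marker: an MAA projection or a gene, on the reference."""

    anchor_id: str
    reference_interval: GenomicInterval
    species_present: frozenset[str]
    kind: str = "MAA"  # "MAA" or "gene"


@dataclass(frozen=True)
class MarkerStats:
    count: int
    mean_length: float
    median_length: float
    min_length: int
    max_length: int
    genome_coverage: float


def extract_maas(
    blocks: Sequence[MultiAlignmentBlock], required_species: Iterable[str]
) -> list[Anchor]:
    """Keep blocks conserved across ``required_species``; project onto the reference.

    One block yields one anchor; overlapping reference projections are not
    merged.  Anchors are returned sorted by reference position.
    """
    required = frozenset(required_species)
    if not blocks:
        return []
    reference = blocks[0].reference_species
    if reference not in required:
        raise ValueError(
            f"required species set must contain the reference {reference!r}"
        )
    anchors = []
    for block in blocks:
        if block.species >= required:
            anchors.append(
                Anchor(
                    anchor_id="",  # assigned after sorting
                    reference_interval=block.reference_interval,
                    species_present=frozenset(block.species),
                )
            )
    anchors.sort(key=lambda a: (a.reference_interval.chrom, a.reference_interval.start))
    return [
        Anchor(f"MAA{i:06d}", a.reference_interval, a.species_present, a.kind)
        for i, a in enumerate(anchors, start=1)
    ]


def _union_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases in the union of intervals, overlaps counted once."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for s, e in spans[1:]:
            if s > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        total += cur_end - cur_start
    return total


def marker_stats(anchors: Sequence[Anchor], reference_genome_length: int) -> MarkerStats:
    """Length distribution and union coverage of a marker set."""
    if not anchors:
        raise ValueError("cannot compute marker statistics on an empty anchor set")
    lengths = np.array([a.reference_interval.length for a in anchors])
    max_end = max(a.reference_interval.end for a in anchors)
    if reference_genome_length < max_end:
        raise ValueError(
            f"genome length {reference_genome_length} smaller than max anchor end {max_end}"
        )
    return MarkerStats(
        count=len(anchors),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        genome_coverage=_union_length([a.reference_interval for a in anchors])
        / reference_genome_length,
    )


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc_enrichment(
    anchors: Sequence[Anchor],
    genome_sequences: Mapping[str, str],
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Compare anchor GC against length-matched random background windows.

    For each anchor, one window of the same length is drawn uniformly at
    random from the same chromosome; the two per-element GC distributions are
    compared with a two-sided Mann-Whitney rank-sum test.  Returns
    (mean anchor GC, mean background GC, p-value).
    """
    rng = np.random.default_rng(seed)
    anchor_gc, background_gc = [], []
    for a in anchors:
        iv = a.reference_interval
        seq = genome_sequences.get(iv.chrom)
        if seq is None or iv.end > len(seq):
            raise ValueError(f"anchor {a.anchor_id} outside sequence bounds on {iv.chrom}")
        anchor_gc.append(_gc_fraction(seq[iv.start : iv.end]))
        max_start = len(seq) - iv.length
        wstart = int(rng.integers(0, max_start + 1)) if max_start > 0 else 0
        background_gc.append(_gc_fraction(seq[wstart : wstart + iv.length]))
    anchor_gc = np.asarray(anchor_gc)
    background_gc = np.asarray(background_gc)
    if len(anchors) == 1 or (
        np.ptp(anchor_gc) == 0 and np.ptp(background_gc) == 0
        and anchor_gc[0] == background_gc[0]
    ):
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(anchor_gc, background_gc, alternative="two-sided").pvalue
        )
    return float(anchor_gc.mean()), float(background_gc.mean()), p


def uniformity_test(
    markers: Sequence[Anchor | GeneModel],
    chromosome_lengths: Mapping[str, int],
    min_markers: int = 8,
) -> dict[str, tuple[float, float]]:
    """Per-chromosome one-sample KS test of marker midpoints against uniform.

    Chromosomes with fewer than ``min_markers`` markers are skipped with a
    warning.  Returns chrom -> (D statistic, p-value).
    """
    midpoints: dict[str, list[float]] = {}
    for m in markers:
        iv = m.reference_interval if isinstance(m, Anchor) else m.interval
        midpoints.setdefault(iv.chrom, []).append(iv.midpoint)
    out: dict[str, tuple[float, float]] = {}
    for chrom, length in chromosome_lengths.items():
        pts = midpoints.get(chrom, [])
        if len(pts) < min_markers:
            warnings.warn(
                f"chromosome {chrom}: only {len(pts)} markers, skipping KS test",
                stacklevel=2,
            )
            continue
        res = stats.kstest(np.array(pts) / length, "uniform")
        out[chrom] = (float(res.statistic), float(res.pvalue))
    return out


def feature_composition(
    anchors: Sequence[Anchor],
    feature_intervals: Mapping[str, Sequence[GenomicInterval]],
    chromosome_lengths: Mapping[str, int],
    gene_models: Sequence[GeneModel] | None = None,
    desert_min_gap: int = GENE_DESERT_MIN_GAP,
) -> dict[str, float]:
    """Fraction of anchor bases falling in each feature class.

    Overlapping annotations are resolved per base with the precedence
    CDS > UTR > ncRNA > intron; unannotated bases are intergenic, and
    intergenic stretches between adjacent genes longer than ``desert_min_gap``
    are reclassified as gene desert.  Fractions sum to 1.
    """
    classes = FEATURE_PRECEDENCE
    code = {c: i for i, c in enumerate(classes)}
    # paint chromosomes in reverse precedence so higher-priority classes win
    paint: dict[str, np.ndarray] = {
        chrom: np.full(length, code["intergenic"], dtype=np.int8)
        for chrom, length in chromosome_lengths.items()
    }
    if gene_models is not None:
        genes_by_chrom: dict[str, list[GenomicInterval]] = {}
        for g in gene_models:
            genes_by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for chrom, arr in paint.items():
            gaps = []
            ivs = sorted(genes_by_chrom.get(chrom, []), key=lambda iv: iv.start)
            prev_end = 0
            for iv in ivs:
                gaps.append((prev_end, iv.start))
                prev_end = max(prev_end, iv.end)
            gaps.append((prev_end, len(arr)))
            for s, e in gaps:
                if e - s > desert_min_gap:
                    arr[s:e] = code["gene_desert"]
    for cls in reversed([c for c in classes if c not in ("intergenic", "gene_desert")]):
        for iv in feature_intervals.get(cls, []):
            if iv.chrom in paint:
                paint[iv.chrom][iv.start : iv.end] = code[cls]
    counts = np.zeros(len(classes), dtype=np.int64)
    for a in anchors:
        iv = a.reference_interval
        if iv.chrom not in paint:
            continue
        counts += np.bincount(paint[iv.chrom][iv.start : iv.end], minlength=len(classes))
    total = counts.sum()
    if total == 0:
        return {c: 0.0 for c in classes}
    return {c: float(counts[code[c]] / total) for c in classes}


def anchors_to_bed(anchors: Sequence[Anchor], path) -> None:
    """Export anchors as BED6 (name = anchor id, score = species count)."""
    with open(path, "w") as fh:
        for a in anchors:
            iv = a.reference_interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{a.anchor_id}\t"
                f"{len(a.species_present)}\t{iv.strand}\n"
            )
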