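"""Collinear-segment detection from ordered genomic markers.

Markers (MAAs or protein-coding genes) are reduced to per-chromosome rank
orders; a collinear segment is a chained run of homologous marker pairs whose
ranks are strictly monotone in both genomes (increasing, or decreasing on one
side for an inversion), with at most ``gap_size`` intervening non-homologous
markers between consecutive anchor points and at least ``anchor_points``
anchors in total.  Candidate chains are paths in a sparse compatibility DAG;
the detector returns every subset-maximal chain that passes a binomial-tail
significance filter, so its output is directly comparable to exhaustive
enumeration on small instances.

Segments between a reference genome and several partner species are then
classified into levels: each pairwise segment is a 2way-d segment (d the
partner's divergence index), and reference regions simultaneously covered by
segments with the first n-1 partners of the phylogenetic order form n-way
segments, labelled at the largest n they satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .formats_io import GeneModel, GenomicInterval, MultiAlignmentBlock, PhyloOrder

__all__ = [
    "DetectionParams",
    "Marker",
    "CollinearSegment",
    "SegmentLevel",
    "gene_markers",
    "maa_markers",
    "build_homology_pairs",
    "detect_pairwise_segments",
    "segment_significance",
    "classify_levels",
    "nway_coverage_regions",
    "annotate_segment_degrees",
    "assign_unique_pairs",
    "segment_summary",
    "segments_to_table",
]


@dataclass(frozen=True)
class DetectionParams:
    """Chaining parameters with the semantics of anchor-based synteny tools."""

    anchor_points: int = 3
    gap_size: int = 30
    prob_cutoff: float = 0.01

    def __post_init__(self) -> None:
        if self.anchor_points < 2:
            raise ValueError("anchor_points must be >= 2")
        if self.gap_size < 1:
            raise ValueError("gap_size must be >= 1")
        if not (0 < self.prob_cutoff <= 1):
            raise ValueError("prob_cutoff must be in (0, 1]")


#: Defaults matching the two marker types: MAA chains tolerate more
#: intervening markers because MAAs are an order of magnitude denser.
MAA_PARAMS = DetectionParams(anchor_points=3, gap_size=30, prob_cutoff=0.01)
GENE_PARAMS = DetectionParams(anchor_points=3, gap_size=10, prob_cutoff=0.01)


@dataclass(frozen=True)
class Marker:
    """A rank-ordered marker on one genome."""

    marker_id: str
    chrom: str
    rank: int
    interval: GenomicInterval


@dataclass(frozen=True)
class CollinearSegment:
    segment_id: str
    genome_a: str
    genome_b: str
    region_a: GenomicInterval
    region_b: GenomicInterval
    anchors: tuple[tuple[str, str], ...]
    orientation: str  # "same" | "inverted"
    p_value: float


@dataclass(frozen=True)
class SegmentLevel:
    """A classified collinearity level on the reference genome."""

    kind: str  # "n_way" | "pairwise"
    reference_region: GenomicInterval
    n: int | None = None
    d: int | None = None

    @property
    def label(self) -> str:
        return f"{self.n}-way" if self.kind == "n_way" else f"2way-{self.d}"


def gene_markers(genes: Sequence[GeneModel]) -> list[Marker]:
    """Use protein-coding genes as markers (ranks taken from the gene models)."""
    return [Marker(g.gene_id, g.interval.chrom, g.rank, g.interval) for g in genes]


def maa_markers(
    blocks: Sequence[MultiAlignmentBlock], species: str, ids: Sequence[str] | None = None
) -> list[Marker]:
    """Project alignment blocks onto one genome and rank them per chromosome.

    The same block projected onto two genomes yields markers with the same id,
    which makes the two projections homologous by construction.
    """
    if ids is None:
        ids = [f"B{i:06d}" for i in range(len(blocks))]
    raw = []
    for bid, block in zip(ids, blocks):
        if species in block.rows:
            raw.append((bid, block.rows[species][0]))
    by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
    for bid, iv in raw:
        by_chrom.setdefault(iv.chrom, []).append((bid, iv))
    out = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda e: (e[1].start, e[1].end, e[0]))
        for rank, (bid, iv) in enumerate(entries, start=1):
            out.append(Marker(bid, chrom, rank, iv))
    return out


def build_homology_pairs(
    markers_a: Sequence[Marker],
    markers_b: Sequence[Marker],
    hits=None,
    evalue_cutoff: float = 1e-5,
) -> set[tuple[str, str]]:
    """Candidate anchor pairs between two marker sets.

    With ``hits`` (gene markers) a pair is kept when a hit at E <= cutoff
    joins the two markers in either direction; without hits (MAA markers)
    markers sharing an id are homologous by construction.
    """
    ids_a = {m.marker_id for m in markers_a}
    ids_b = {m.marker_id for m in markers_b}
    if hits is None:
        return {(mid, mid) for mid in ids_a & ids_b}
    pairs = set()
    for h in hits:
        if h.e_value > evalue_cutoff:
            continue
        if h.query_gene in ids_a and h.subject_gene in ids_b:
            pairs.add((h.query_gene, h.subject_gene))
        if h.subject_gene in ids_a and h.query_gene in ids_b:
            pairs.add((h.subject_gene, h.query_gene))
    return pairs


def segment_significance(
    k: int, span_a: int, span_b: int, density: float, n_windows: int = 1
) -> float:
    """Tail probability of >= k homologous pairs in a span_a x span_b window.

    The null scatters candidate pairs independently with probability
    ``density`` per marker-pair cell; the tail is Bonferroni-scaled by the
    number of windows scanned, capped at 1.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    if k < 2 or span_a < k or span_b < k:
        raise ValueError("need k >= 2 and spans >= k")
    p = float(stats.binom.sf(k - 1, span_a * span_b, density))
    return min(1.0, p * max(1, n_windows))


def _enumerate_maximal_chains(
    nodes: list[tuple[int, int, str, str]], gap: int, inverted: bool
) -> list[list[int]]:
    """All subset-maximal monotone chains over candidate pair nodes.

    Nodes are (rank_a, rank_b, id_a, id_b).  A full edge u->v exists when
    both rank gaps are within ``gap`` and the b-ranks move in the requested
    direction.  Because edge validity is a rank-window constraint, any node
    that fits between the endpoints of an edge on both genomes is itself
    edge-compatible with both endpoints; hence a chain is subset-maximal
    exactly when it starts at a node without predecessors, ends at a node
    without successors, and uses only irreducible edges (u->v with no w such
    that u->w->v).  Enumerating root-to-leaf paths of the reduced DAG
    therefore yields exactly the subset-maximal chains, without the
    exponential blow-up of enumerating every chain.
    """
    from bisect import bisect_right

    n = len(nodes)
    ranks_a = [nd[0] for nd in nodes]  # nodes are sorted by (rank_a, rank_b)
    succ: list[list[int]] = [[] for _ in range(n)]
    has_pred = [False] * n
    for i in range(n):
        ra, rb = nodes[i][0], nodes[i][1]
        lo = bisect_right(ranks_a, ra)
        hi = bisect_right(ranks_a, ra + gap + 1)
        for j in range(lo, hi):
            sb = nodes[j][1]
            if inverted:
                ok = sb < rb and rb - sb <= gap + 1
            else:
                ok = rb < sb <= rb + gap + 1
            if ok:
                succ[i].append(j)
                has_pred[j] = True
    succ_sets = [set(s) for s in succ]
    reduced: list[list[int]] = []
    for i in range(n):
        reduced.append(
            [j for j in succ[i] if not any(j in succ_sets[w] for w in succ[i] if w != j)]
        )
    chains: list[list[int]] = []
    for root in range(n):
        if has_pred[root]:
            continue
        stack: list[list[int]] = [[root]]
        while stack:
            path = stack.pop()
            node = path[-1]
            if not succ[node]:
                chains.append(path)
                continue
            for child in reduced[node]:
                stack.append(path + [child])
    return chains


def detect_pairwise_segments(
    markers_a: Sequence[Marker],
    markers_b: Sequence[Marker],
    pairs: Iterable[tuple[str, str]],
    params: DetectionParams = MAA_PARAMS,
    genome_a: str = "A",
    genome_b: str = "B",
) -> list[CollinearSegment]:
    """Detect all significant subset-maximal collinear chains between two genomes."""
    pairs = set(pairs)
    if not pairs:
        return []
    idx_a = {m.marker_id: m for m in markers_a}
    idx_b = {m.marker_id: m for m in markers_b}
    chrom_counts_a: dict[str, int] = {}
    chrom_counts_b: dict[str, int] = {}
    for m in markers_a:
        chrom_counts_a[m.chrom] = chrom_counts_a.get(m.chrom, 0) + 1
    for m in markers_b:
        chrom_counts_b[m.chrom] = chrom_counts_b.get(m.chrom, 0) + 1

    grouped: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for ida, idb in pairs:
        ma, mb = idx_a.get(ida), idx_b.get(idb)
        if ma is None or mb is None:
            continue
        grouped.setdefault((ma.chrom, mb.chrom), []).append(
            (ma.rank, mb.rank, ida, idb)
        )

    segments: list[CollinearSegment] = []
    for (ca, cb), nodes in sorted(grouped.items()):
        nodes = sorted(set(nodes))
        n_a, n_b = chrom_counts_a[ca], chrom_counts_b[cb]
        density = min(1.0, len(nodes) / (n_a * n_b))
        candidates = []
        for inverted in (False, True):
            for chain in _enumerate_maximal_chains(nodes, params.gap_size, inverted):
                if len(chain) >= params.anchor_points:
                    candidates.append((inverted, [nodes[i] for i in chain]))
        # Bonferroni over the hypotheses actually tested: one per candidate chain
        n_tests = max(1, len(candidates))

        def window_p(members: list[tuple[int, int, str, str]]) -> float:
            span_a = members[-1][0] - members[0][0] + 1
            ranks_b = [m[1] for m in members]
            span_b = max(ranks_b) - min(ranks_b) + 1
            return segment_significance(len(members), span_a, span_b, density, n_tests)

        # A chain that drifts through incidental background pairs loses
        # significance even though a core run inside it is strongly collinear;
        # validity includes the significance constraint, so each structural
        # chain is refined to its maximal significant contiguous windows.
        emitted: dict[tuple[str, tuple[tuple[str, str], ...]], tuple[list, float]] = {}
        for inverted, members in candidates:
            k = len(members)
            windows = []
            for i in range(k):
                for j in range(i + params.anchor_points - 1, k):
                    p = window_p(members[i : j + 1])
                    if p <= params.prob_cutoff:
                        windows.append((i, j, p))
            maximal = [
                (i, j, p)
                for i, j, p in windows
                if not any(
                    (i2 <= i and j <= j2 and (i2, j2) != (i, j)) for i2, j2, _ in windows
                )
            ]
            orient = "inverted" if inverted else "same"
            for i, j, p in maximal:
                core = members[i : j + 1]
                emitted[(orient, tuple((m[2], m[3]) for m in core))] = (core, p)

        # cross-chain subset-maximality on anchor-pair sets
        anchor_sets = {key: frozenset(key[1]) for key in emitted}
        for (orient, anchors), (members, p) in emitted.items():
            s = anchor_sets[(orient, anchors)]
            if any(
                s < other
                for key2, other in anchor_sets.items()
                if key2 != (orient, anchors)
            ):
                continue
            ivs_a = [idx_a[m[2]].interval for m in members]
            ivs_b = [idx_b[m[3]].interval for m in members]
            segments.append(
                CollinearSegment(
                    segment_id="",
                    genome_a=genome_a,
                    genome_b=genome_b,
                    region_a=GenomicInterval(
                        ca, min(iv.start for iv in ivs_a), max(iv.end for iv in ivs_a)
                    ),
                    region_b=GenomicInterval(
                        cb, min(iv.start for iv in ivs_b), max(iv.end for iv in ivs_b)
                    ),
                    anchors=tuple((m[2], m[3]) for m in members),
                    orientation=orient,
                    p_value=p,
                )
            )
    segments.sort(
        key=lambda s: (
            s.region_a.chrom,
            s.region_a.start,
            s.region_b.chrom,
            s.region_b.start,
            s.orientation,
        )
    )
    return [
        CollinearSegment(
            f"{genome_a}-{genome_b}.{i:05d}",
            s.genome_a,
            s.genome_b,
            s.region_a,
            s.region_b,
            s.anchors,
            s.orientation,
            s.p_value,
        )
        for i, s in enumerate(segments, start=1)
    ]


def assign_unique_pairs(
    segments: Sequence[CollinearSegment],
) -> dict[tuple[str, str], str]:
    """Assign each anchor pair to a single segment.

    Segments claim pairs in order of more anchors, then lower p, then smaller
    reference start, so a marker pair shared by overlapping chains counts only
    once in downstream evidence.
    """
    order = sorted(
        segments, key=lambda s: (-len(s.anchors), s.p_value, s.region_a.start)
    )
    owner: dict[tuple[str, str], str] = {}
    for seg in order:
        for pair in seg.anchors:
            owner.setdefault(pair, seg.segment_id)
    return owner


# ---------------------------------------------------------------------------
# Level classification on the reference genome
# ---------------------------------------------------------------------------

def _elementary_coverage(
    segments: Sequence[CollinearSegment],
) -> dict[str, list[tuple[int, int, frozenset[str]]]]:
    """Per reference chromosome: elementary intervals with their covering species."""
    by_chrom: dict[str, list[CollinearSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.region_a.chrom, []).append(s)
    out: dict[str, list[tuple[int, int, frozenset[str]]]] = {}
    for chrom, segs in by_chrom.items():
        bounds = sorted({s.region_a.start for s in segs} | {s.region_a.end for s in segs})
        pieces = []
        for lo, hi in zip(bounds, bounds[1:]):
            cover = frozenset(
                s.genome_b for s in segs if s.region_a.start <= lo and s.region_a.end >= hi
            )
            if cover:
                pieces.append((lo, hi, cover))
        out[chrom] = pieces
    return out


def _max_prefix_n(cover: frozenset[str], order: PhyloOrder) -> int:
    """Largest n >= 3 with all of the order's first n-1 partners covered (0 if none)."""
    n = 1
    for sp in order.species[1:]:
        if sp in cover:
            n += 1
        else:
            break
    return n if n >= 3 else 0


def classify_levels(
    segments: Sequence[CollinearSegment], order: PhyloOrder
) -> tuple[list[SegmentLevel], list[SegmentLevel]]:
    """Classify reference-anchored segments into n-way and 2way-d levels.

    Every pairwise segment yields one 2way-d level (d its partner's index).
    n-way levels are maximal reference regions simultaneously covered by
    segments with each of the first n-1 partners of the phylogenetic order,
    reported only at the largest n they satisfy.
    """
    d_index = order.d_index
    for s in segments:
        if s.genome_a != order.reference:
            raise ValueError(f"segment {s.segment_id} not anchored on the reference")
        if s.genome_b not in d_index:
            raise ValueError(f"species {s.genome_b!r} absent from the phylo order")
    pairwise = [
        SegmentLevel(kind="pairwise", reference_region=s.region_a, d=d_index[s.genome_b])
        for s in segments
    ]
    n_way: list[SegmentLevel] = []
    for chrom, pieces in sorted(_elementary_coverage(segments).items()):
        labelled = [(lo, hi, _max_prefix_n(cov, order)) for lo, hi, cov in pieces]
        labelled = [(lo, hi, n) for lo, hi, n in labelled if n >= 3]
        # merge adjacent pieces carrying the same maximal n
        merged: list[tuple[int, int, int]] = []
        for lo, hi, n in labelled:
            if merged and merged[-1][1] == lo and merged[-1][2] == n:
                merged[-1] = (merged[-1][0], hi, n)
            else:
                merged.append((lo, hi, n))
        for lo, hi, n in merged:
            n_way.append(
                SegmentLevel(kind="n_way", reference_region=GenomicInterval(chrom, lo, hi), n=n)
            )
    return n_way, pairwise


def nway_coverage_regions(
    segments: Sequence[CollinearSegment], order: PhyloOrder, n: int
) -> list[GenomicInterval]:
    """Reference regions covered by segments with *at least* the first n-1 partners.

    These at-least-n region sets are nested: the (n+1)-way set is contained in
    the n-way set.
    """
    if not (3 <= n <= len(order)):
        raise ValueError(f"n must be in [3, {len(order)}]")
    required = set(order.species[1:n])
    out: list[GenomicInterval] = []
    for chrom, pieces in sorted(_elementary_coverage(segments).items()):
        merged: list[tuple[int, int]] = []
        for lo, hi, cov in pieces:
            if not required <= cov:
                continue
            if merged and merged[-1][1] == lo:
                merged[-1] = (merged[-1][0], hi)
            else:
                merged.append((lo, hi))
        out.extend(GenomicInterval(chrom, lo, hi) for lo, hi in merged)
    return out


def annotate_segment_degrees(
    segments: Sequence[CollinearSegment], order: PhyloOrder
) -> dict[str, int]:
    """Collinearity degree of each segment: the deepest n-way level its
    reference region participates in, with a floor of 2 (pairwise)."""
    coverage = _elementary_coverage(segments)
    degrees: dict[str, int] = {}
    for s in segments:
        deg = 2
        for lo, hi, cov in coverage.get(s.region_a.chrom, []):
            if lo < s.region_a.end and hi > s.region_a.start:
                deg = max(deg, _max_prefix_n(cov, order))
        degrees[s.segment_id] = deg
    return degrees


def segment_summary(levels: Sequence[SegmentLevel]) -> pd.DataFrame:
    """One row per level value: count, total and mean reference length."""
    rows: dict[str, list[int]] = {}
    for lv in levels:
        rows.setdefault(lv.label, []).append(lv.reference_region.length)
    data = [
        {
            "level": label,
            "count": len(lengths),
            "total_length": int(sum(lengths)),
            "mean_length": sum(lengths) / len(lengths),
        }
        for label, lengths in sorted(rows.items())
    ]
    return pd.DataFrame(data, columns=["level", "count", "total_length", "mean_length"])


def segments_to_table(segments: Sequence[CollinearSegment]) -> pd.DataFrame:
    """Paired-region table for TSV export."""
    return pd.DataFrame(
        [
            {
                "segment_id": s.segment_id,
                "genome_a": s.genome_a,
                "chrom_a": s.region_a.chrom,
                "start_a": s.region_a.start,
                "end_a": s.region_a.end,
                "genome_b": s.genome_b,
                "chrom_b": s.region_b.chrom,
                "start_b": s.region_b.start,
                "end_b": s.region_b.end,
                "n_anchors": len(s.anchors),
                "orientation": s.orientation,
                "p_value": s.p_value,
            }
            for s in segments
        ]
    )
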