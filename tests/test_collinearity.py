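"""Collinear-segment detection: significance model, chaining oracle, levels."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from synortho.collinearity import (
    DetectionParams,
    GENE_PARAMS,
    Marker,
    annotate_segment_degrees,
    assign_unique_pairs,
    build_homology_pairs,
    classify_levels,
    detect_pairwise_segments,
    gene_markers,
    maa_markers,
    nway_coverage_regions,
    segment_significance,
    segment_summary,
    CollinearSegment,
    SegmentLevel,
)
from synortho.formats_io import GenomicInterval, HomologyHit, PhyloOrder
from synortho.synth import generate_world

from conftest import clean_config, detect_world_segments


def make_markers(n, prefix="m", chrom="c"):
    return [
        Marker(f"{prefix}{i}", chrom, i + 1, GenomicInterval(chrom, i * 100, i * 100 + 60))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# homology pair construction
# ---------------------------------------------------------------------------

class TestBuildHomologyPairs:
    def test_maa_identity_pairs(self):
        ma = make_markers(5, "x")
        mb = make_markers(3, "x")
        assert build_homology_pairs(ma, mb) == {(f"x{i}", f"x{i}") for i in range(3)}

    def test_evalue_threshold_excludes_weak_hits(self):
        ma, mb = make_markers(2, "a"), make_markers(2, "b")
        hits = [
            HomologyHit("a0", "b0", 1e-6, 100),
            HomologyHit("a1", "b1", 1e-4, 100),
        ]
        assert build_homology_pairs(ma, mb, hits) == {("a0", "b0")}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        ma, mb = make_markers(20, "a"), make_markers(20, "b")
        hits = [
            HomologyHit(
                f"a{rng.integers(0, 25)}", f"b{rng.integers(0, 25)}",
                float(10.0 ** -rng.uniform(2, 10)), 100.0,
            )
            for _ in range(40)
        ]
        got = build_homology_pairs(ma, mb, hits)
        ids_a = {m.marker_id for m in ma}
        ids_b = {m.marker_id for m in mb}
        expected = {
            (h.query_gene, h.subject_gene)
            for h in hits
            if h.e_value <= 1e-5 and h.query_gene in ids_a and h.subject_gene in ids_b
        }
        assert got == expected


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

class TestSegmentSignificance:
    def test_saturated_null_gives_one(self):
        assert segment_significance(5, 5, 5, 1.0) == 1.0

    def test_monotone_decreasing_in_anchor_count(self):
        ps = [segment_significance(k, 30, 30, 0.01) for k in range(2, 10)]
        assert ps == sorted(ps, reverse=True)

    def test_monotone_increasing_in_density(self):
        ps = [segment_significance(4, 20, 20, d) for d in (0.001, 0.01, 0.1, 0.5)]
        assert ps == sorted(ps)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            segment_significance(3, 5, 5, 0.0)
        with pytest.raises(ValueError):
            segment_significance(3, 5, 5, 1.5)

    @pytest.mark.parametrize(
        "k,span,density",
        [(3, 6, 0.05), (3, 10, 0.02), (4, 8, 0.1), (5, 10, 0.1), (4, 20, 0.02)],
    )
    def test_matches_monte_carlo_tail(self, k, span, density):
        rng = np.random.default_rng(k * 100 + span)
        draws = (rng.random((10_000, span * span)) < density).sum(axis=1)
        mc = (draws >= k).mean()
        p = segment_significance(k, span, span, density)
        assert mc > 0
        assert 0.5 <= p / mc <= 2.0


# ---------------------------------------------------------------------------
# detection vs exhaustive oracle
# ---------------------------------------------------------------------------

def oracle_segments(markers_a, markers_b, pairs, params):
    """Exhaustive enumeration of subset-maximal significant chains.

    Independent of the detector: grows every monotone chain recursively with
    a full validity re-check, then filters by size, significance and subset
    maximality.
    """
    idx_a = {m.marker_id: m for m in markers_a}
    idx_b = {m.marker_id: m for m in markers_b}
    grouped = {}
    for ida, idb in pairs:
        if ida in idx_a and idb in idx_b:
            ma, mb = idx_a[ida], idx_b[idb]
            grouped.setdefault((ma.chrom, mb.chrom), set()).add(
                (ma.rank, mb.rank, ida, idb)
            )
    results = set()
    for (ca, cb), nodeset in grouped.items():
        nodes = sorted(nodeset)
        n_a = sum(1 for m in markers_a if m.chrom == ca)
        n_b = sum(1 for m in markers_b if m.chrom == cb)
        density = min(1.0, len(nodes) / (n_a * n_b))

        def step_ok(prev, cur, direction):
            if not (prev[0] < cur[0] <= prev[0] + params.gap_size + 1):
                return False
            if direction > 0:
                return prev[1] < cur[1] <= prev[1] + params.gap_size + 1
            return cur[1] < prev[1] <= cur[1] + params.gap_size + 1

        all_chains = []

        def grow(chain, direction):
            all_chains.append((direction, tuple(chain)))
            for nxt in nodes:
                if nxt[0] > chain[-1][0] and step_ok(chain[-1], nxt, direction):
                    grow(chain + [nxt], direction)

        for direction in (1, -1):
            for start in nodes:
                grow([start], direction)

        def vset(chain):
            return frozenset(chain)

        # structurally maximal chains define the number of tests
        long_enough = [c for c in all_chains if len(c[1]) >= params.anchor_points]
        allsets = [vset(c[1]) for c in all_chains]
        maximal_structural = [
            c for c in long_enough
            if not any(vset(c[1]) < s for s in allsets)
        ]
        n_tests = max(1, len(maximal_structural))

        def pvalue(chain):
            ra = [m[0] for m in chain]
            rb = [m[1] for m in chain]
            return segment_significance(
                len(chain), max(ra) - min(ra) + 1, max(rb) - min(rb) + 1,
                density, n_tests,
            )

        significant = [c for c in long_enough if pvalue(c[1]) <= params.prob_cutoff]
        sig_sets = [vset(c[1]) for c in significant]
        for direction, chain in significant:
            if any(vset(chain) < s for s in sig_sets):
                continue
            results.add(
                (
                    "same" if direction > 0 else "inverted",
                    frozenset((m[2], m[3]) for m in chain),
                    round(pvalue(chain), 12),
                )
            )
    return results


def random_instance(seed, gap):
    """A small two-genome marker map with planted runs plus scattered pairs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(25, 41))
    ma, mb = make_markers(n, "a"), make_markers(n, "b")
    pairs = set()
    for _ in range(int(rng.integers(1, 3))):
        run = int(rng.integers(4, 8))
        sa = int(rng.integers(0, n - run))
        sb = int(rng.integers(0, n - run))
        inverted = rng.random() < 0.3
        for i in range(run):
            if rng.random() < 0.85:
                b = sb + (run - 1 - i if inverted else i)
                pairs.add((f"a{sa + i}", f"b{b}"))
    for _ in range(int(rng.integers(4, 12))):
        pairs.add((f"a{rng.integers(0, n)}", f"b{rng.integers(0, n)}"))
    return ma, mb, pairs


class TestDetectorOracleEquivalence:
    def test_planted_run_is_one_segment(self):
        # five consecutive co-oriented pairs among many unpaired markers
        ma, mb = make_markers(40, "a"), make_markers(40, "b")
        pairs = {(f"a{10 + i}", f"b{20 + i}") for i in range(5)}
        segs = detect_pairwise_segments(ma, mb, pairs, DetectionParams(3, 3, 0.01))
        assert len(segs) == 1
        assert len(segs[0].anchors) == 5
        assert segs[0].orientation == "same"

    def test_two_pairs_cannot_form_a_segment(self):
        ma, mb = make_markers(40, "a"), make_markers(40, "b")
        pairs = {("a1", "b1"), ("a2", "b2")}
        assert detect_pairwise_segments(ma, mb, pairs, DetectionParams(3, 3, 0.01)) == []

    def test_inverted_run_detected_with_inverted_orientation(self):
        ma, mb = make_markers(40, "a"), make_markers(40, "b")
        pairs = {(f"a{10 + i}", f"b{30 - i}") for i in range(5)}
        segs = detect_pairwise_segments(ma, mb, pairs, DetectionParams(3, 3, 0.01))
        assert len(segs) == 1
        assert segs[0].orientation == "inverted"

    @pytest.mark.parametrize("gap", [3, 10])
    @pytest.mark.parametrize("seed", range(50))
    def test_equals_exhaustive_enumeration(self, seed, gap):
        ma, mb, pairs = random_instance(seed, gap)
        params = DetectionParams(anchor_points=3, gap_size=gap, prob_cutoff=0.01)
        segs = detect_pairwise_segments(ma, mb, pairs, params)
        got = {
            (s.orientation, frozenset(s.anchors), round(s.p_value, 12)) for s in segs
        }
        assert got == oracle_segments(ma, mb, pairs, params)


class TestDetectorProperties:
    def test_gap_increase_never_loses_anchors(self):
        world = generate_world(clean_config(seed=5, background_maas_per_gap=0))
        ref = world.reference
        sp = world.order.species[1]
        ma = gene_markers(world.genes_by_species[ref])
        mb = gene_markers(world.genes_by_species[sp])
        pairs = build_homology_pairs(ma, mb, world.hits)
        counts = []
        for gap in (2, 5, 10, 20):
            segs = detect_pairwise_segments(
                ma, mb, pairs, DetectionParams(3, gap, 0.01)
            )
            counts.append(len({p for s in segs for p in s.anchors}))
        assert counts == sorted(counts)

    def test_anchor_points_increase_never_adds_segments(self):
        world = generate_world(clean_config(seed=6, background_maas_per_gap=0))
        ref = world.reference
        sp = world.order.species[1]
        ma = gene_markers(world.genes_by_species[ref])
        mb = gene_markers(world.genes_by_species[sp])
        pairs = build_homology_pairs(ma, mb, world.hits)
        counts = [
            len(detect_pairwise_segments(ma, mb, pairs, DetectionParams(ap, 10, 0.01)))
            for ap in (3, 5, 7, 9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_unique_pair_assignment_covers_each_pair_once(self):
        world = generate_world(clean_config(seed=7))
        maa_segs, _ = detect_world_segments(world, "maa")
        owner = assign_unique_pairs(maa_segs)
        all_pairs = {p for s in maa_segs for p in s.anchors}
        assert set(owner) == all_pairs

    def test_deterministic_output_order(self):
        world = generate_world(clean_config(seed=8))
        a, _ = detect_world_segments(world, "maa")
        b, _ = detect_world_segments(world, "maa")
        assert [(s.segment_id, s.anchors) for s in a] == [
            (s.segment_id, s.anchors) for s in b
        ]


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(20))
    def test_noise_free_blocks_recovered_exactly(self, seed):
        world = generate_world(clean_config(seed=300 + seed))
        _, gene_segs = detect_world_segments(world, "gene")
        detected = {frozenset(s.anchors) for s in gene_segs}
        for blk in world.truth_blocks:
            if len(blk.pairs) >= 5:
                assert frozenset(blk.pairs) in detected


# ---------------------------------------------------------------------------
# level classification
# ---------------------------------------------------------------------------

def seg(sp, start, end, sid="s"):
    iv = GenomicInterval("chr1", start, end)
    return CollinearSegment(sid, "ref", sp, iv, iv, (("x", "x"),), "same", 1e-6)


class TestClassifyLevels:
    ORDER = PhyloOrder(["ref", "melo", "lanatus", "vinifera"])

    def test_prefix_coverage_gives_three_way(self):
        segments = [seg("melo", 0, 1000, "s1"), seg("lanatus", 0, 1000, "s2")]
        n_way, pairwise = classify_levels(segments, self.ORDER)
        assert [lv.label for lv in n_way] == ["3-way"]
        assert n_way[0].reference_region == GenomicInterval("chr1", 0, 1000)

    def test_second_species_alone_is_2way_2(self):
        n_way, pairwise = classify_levels([seg("melo", 0, 500)], self.ORDER)
        assert n_way == []
        assert [lv.label for lv in pairwise] == ["2way-2"]

    def test_gap_in_prefix_blocks_higher_levels(self):
        # vinifera coverage without lanatus cannot form a 4-way region
        segments = [seg("melo", 0, 1000, "s1"), seg("vinifera", 0, 1000, "s2")]
        n_way, _ = classify_levels(segments, self.ORDER)
        assert n_way == []

    def test_unknown_species_is_an_error(self):
        with pytest.raises(ValueError, match="absent"):
            classify_levels([seg("intruder", 0, 10)], self.ORDER)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_per_base_coverage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        species = self.ORDER.species[1:]
        segments = []
        for i in range(int(rng.integers(2, 10))):
            sp = species[rng.integers(0, len(species))]
            start = int(rng.integers(0, 900))
            segments.append(seg(sp, start, start + int(rng.integers(50, 300)), f"s{i}"))
        n_way, _ = classify_levels(segments, self.ORDER)
        # per-base oracle
        length = 1500
        covered = {sp: np.zeros(length, dtype=bool) for sp in species}
        for s in segments:
            covered[s.genome_b][s.region_a.start : s.region_a.end] = True
        base_n = np.zeros(length, dtype=int)
        for b in range(length):
            n = 1
            for sp in species:
                if covered[sp][b]:
                    n += 1
                else:
                    break
            base_n[b] = n if n >= 3 else 0
        expected = np.zeros(length, dtype=int)
        got = np.zeros(length, dtype=int)
        for lv in n_way:
            got[lv.reference_region.start : lv.reference_region.end] = lv.n
        assert np.array_equal(got, base_n)

    @pytest.mark.parametrize("seed", range(10))
    def test_nway_regions_are_nested(self, seed):
        rng = np.random.default_rng(seed)
        species = self.ORDER.species[1:]
        segments = []
        for i in range(8):
            sp = species[rng.integers(0, len(species))]
            start = int(rng.integers(0, 900))
            segments.append(seg(sp, start, start + int(rng.integers(50, 400)), f"s{i}"))
        length = 1500
        masks = {}
        for n in (3, 4):
            mask = np.zeros(length, dtype=bool)
            for iv in nway_coverage_regions(segments, self.ORDER, n):
                mask[iv.start : iv.end] = True
            masks[n] = mask
        assert not np.any(masks[4] & ~masks[3])

    def test_every_pairwise_segment_in_exactly_one_bucket(self):
        segments = [seg("melo", 0, 100, "s1"), seg("vinifera", 0, 100, "s2"),
                    seg("melo", 500, 600, "s3")]
        _, pairwise = classify_levels(segments, self.ORDER)
        assert len(pairwise) == len(segments)
        assert sorted(lv.d for lv in pairwise) == [2, 2, 4]


class TestSegmentSummaryAndDegrees:
    def test_summary_counts_and_means(self):
        levels = [
            SegmentLevel("n_way", GenomicInterval("chr1", 0, 1000), n=3),
            SegmentLevel("n_way", GenomicInterval("chr1", 2000, 5000), n=3),
        ]
        table = segment_summary(levels)
        assert table.loc[0, "count"] == 2
        assert table.loc[0, "mean_length"] == 2000

    def test_empty_summary(self):
        assert segment_summary([]).empty

    def test_degrees_floor_at_two(self):
        order = PhyloOrder(["ref", "melo", "lanatus"])
        s1 = seg("melo", 0, 100, "s1")
        degrees = annotate_segment_degrees([s1], order)
        assert degrees["s1"] == 2

    def test_degrees_reflect_prefix_coverage(self):
        order = PhyloOrder(["ref", "melo", "lanatus"])
        s1, s2 = seg("melo", 0, 100, "s1"), seg("lanatus", 0, 100, "s2")
        degrees = annotate_segment_degrees([s1, s2], order)
        assert degrees == {"s1": 3, "s2": 3}
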