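"""Anchor extraction and marker statistics."""

import numpy as np
import pytest

from synortho.formats_io import GeneModel, GenomicInterval, MultiAlignmentBlock
from synortho.maa_extract import (
    Anchor,
    extract_maas,
    feature_composition,
    gc_enrichment,
    marker_stats,
    uniformity_test,
)


def block(species_ivs, reference="ref"):
    return MultiAlignmentBlock(
        rows={sp: (iv, None) for sp, iv in species_ivs.items()},
        reference_species=reference,
    )


def anchor(start, end, chrom="chr1", aid="a"):
    return Anchor(aid, GenomicInterval(chrom, start, end), frozenset({"ref"}))


class TestExtractMaas:
    def make_blocks(self, counts, n_species=15):
        species = [f"sp{i}" for i in range(n_species)]
        blocks = []
        for j, c in enumerate(counts):
            ivs = {
                sp: GenomicInterval("chr1", 100 * j + 10, 100 * j + 60)
                for sp in (["sp0"] + species[1:c])
            }
            blocks.append(block(ivs, reference="sp0"))
        return blocks, set(species)

    def test_only_fully_conserved_blocks_become_anchors(self):
        blocks, required = self.make_blocks([15, 15, 14])
        assert len(extract_maas(blocks, required)) == 2

    def test_reference_only_requirement_keeps_everything(self):
        blocks, _ = self.make_blocks([15, 15, 14])
        assert len(extract_maas(blocks, {"sp0"})) == 3

    def test_required_set_must_contain_reference(self):
        blocks, _ = self.make_blocks([15])
        with pytest.raises(ValueError, match="reference"):
            extract_maas(blocks, {"sp1", "sp2"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        species = [f"sp{i}" for i in range(6)]
        blocks = []
        for j in range(30):
            present = ["sp0"] + [sp for sp in species[1:] if rng.random() < 0.7]
            ivs = {sp: GenomicInterval("chr1", j * 50, j * 50 + 20) for sp in present}
            blocks.append(block(ivs, reference="sp0"))
        required = set(species)
        got = extract_maas(blocks, required)
        expected = [b for b in blocks if set(b.rows) >= required]
        assert len(got) == len(expected)
        assert {a.reference_interval for a in got} == {
            b.reference_interval for b in expected
        }

    def test_monotone_in_required_species(self):
        blocks, _ = self.make_blocks([15, 12, 8, 5, 15])
        species = sorted({sp for b in blocks for sp in b.rows})
        counts = [
            len(extract_maas(blocks, set(["sp0"] + species[1:k])))
            for k in range(1, len(species) + 1)
        ]
        assert counts == sorted(counts, reverse=True)


class TestMarkerStats:
    def test_basic_arithmetic_and_coverage(self):
        stats = marker_stats([anchor(0, 100), anchor(500, 550)], 1000)
        assert stats.mean_length == 75
        assert stats.median_length == 75
        assert stats.genome_coverage == pytest.approx(0.15)

    def test_union_counts_overlap_once(self):
        stats = marker_stats([anchor(0, 100), anchor(0, 100)], 1000)
        assert stats.genome_coverage == pytest.approx(0.1)

    def test_empty_anchor_set_is_an_error(self):
        with pytest.raises(ValueError):
            marker_stats([], 1000)

    @pytest.mark.parametrize("seed", range(5))
    def test_coverage_matches_per_base_count(self, seed):
        rng = np.random.default_rng(seed)
        genome_len = 5000
        anchors = []
        mask = np.zeros(genome_len, dtype=bool)
        for i in range(40):
            start = int(rng.integers(0, genome_len - 100))
            length = int(rng.integers(1, 100))
            anchors.append(anchor(start, start + length, aid=f"a{i}"))
            mask[start : start + length] = True
        stats = marker_stats(anchors, genome_len)
        assert stats.genome_coverage == pytest.approx(mask.sum() / genome_len)


class TestGcEnrichment:
    def test_extreme_separation(self):
        seqs = {"chr1": "GC" * 200 + "AT" * 800}
        anchors = [anchor(i * 20, i * 20 + 20, aid=f"a{i}") for i in range(10)]
        ga, gb, p = gc_enrichment(anchors, seqs, seed=0)
        assert ga == 1.0
        assert p < 0.05

    def test_identical_single_window(self):
        seqs = {"chr1": "GCGC"}
        ga, gb, p = gc_enrichment([anchor(0, 4)], seqs, seed=0)
        assert ga == gb == 1.0

    def test_planted_shift_detected(self):
        # anchors from a GC-rich subsequence vs an AT-biased background
        rng = np.random.default_rng(42)
        hits = 0
        n_runs = 30
        for run in range(n_runs):
            base = rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=20_000)
            seq = "".join(base)
            rich = "".join(rng.choice(list("ACGT"), p=[0.225, 0.275, 0.275, 0.225], size=4000))
            seq = rich + seq[4000:]
            anchors = [anchor(i * 20, i * 20 + 20, aid=f"a{i}") for i in range(200)]
            _, _, p = gc_enrichment(anchors, {"chr1": seq}, seed=run)
            hits += p < 0.001
        assert hits >= int(0.95 * n_runs)

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        false_pos = 0
        n_runs = 400
        for run in range(n_runs):
            r = np.random.default_rng(1000 + run)
            starts = r.integers(0, 49_000, size=100)
            anchors = [anchor(int(s), int(s) + 40, aid=f"a{i}") for i, s in enumerate(starts)]
            _, _, p = gc_enrichment(anchors, {"chr1": seq}, seed=run)
            false_pos += p < 0.05
        assert 0.02 <= false_pos / n_runs <= 0.08


class TestUniformity:
    def test_regular_grid_is_near_uniform(self):
        anchors = [anchor(i * 10 + 4, i * 10 + 6, aid=f"a{i}") for i in range(100)]
        (d, p) = uniformity_test(anchors, {"chr1": 1000})["chr1"]
        assert d <= 0.01

    def test_clustered_markers_have_large_statistic(self):
        anchors = [anchor(i, i + 1, aid=f"a{i}") for i in range(0, 100, 10)]
        (d, p) = uniformity_test(anchors, {"chr1": 1000})["chr1"]
        assert d >= 0.9
        assert p < 1e-3

    def test_sparse_chromosome_skipped_with_warning(self):
        anchors = [anchor(0, 10)]
        with pytest.warns(UserWarning, match="skipping"):
            out = uniformity_test(anchors, {"chr1": 1000})
        assert out == {}

    @pytest.mark.parametrize("seed", range(10))
    def test_statistic_matches_ecdf_supremum(self, seed):
        rng = np.random.default_rng(seed)
        length = 10_000
        starts = np.sort(rng.integers(0, length - 2, size=50))
        anchors = [anchor(int(s), int(s) + 2, aid=f"a{i}") for i, s in enumerate(starts)]
        (d, _) = uniformity_test(anchors, {"chr1": length})["chr1"]
        mids = np.sort([(2 * s + 2) / 2 / length for s in starts])
        n = len(mids)
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        expected = max(np.max(ecdf_hi - mids), np.max(mids - ecdf_lo))
        assert d == pytest.approx(expected, abs=1e-12)


class TestFeatureComposition:
    CHROMS = {"chr1": 10_000}

    def test_anchors_entirely_in_cds(self):
        features = {"CDS": [GenomicInterval("chr1", 0, 5000)]}
        frac = feature_composition(
            [anchor(100, 200), anchor(1000, 1100)], features, self.CHROMS
        )
        assert frac["CDS"] == 1.0

    def test_half_cds_half_intergenic(self):
        features = {"CDS": [GenomicInterval("chr1", 0, 150)]}
        frac = feature_composition([anchor(100, 200)], features, self.CHROMS)
        assert frac["CDS"] == pytest.approx(0.5)
        assert frac["intergenic"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        features = {
            "CDS": [GenomicInterval("chr1", 0, 1000)],
            "intron": [GenomicInterval("chr1", 500, 2000)],
            "UTR": [GenomicInterval("chr1", 900, 1200)],
        }
        frac = feature_composition(
            [anchor(0, 3000), anchor(2500, 4000)], features, self.CHROMS
        )
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)

    def test_gene_desert_classification(self):
        genes = [
            GeneModel("g1", "ref", GenomicInterval("chr1", 0, 100), 1),
            GeneModel("g2", "ref", GenomicInterval("chr1", 9_900, 10_000), 2),
        ]
        frac = feature_composition(
            [anchor(5000, 5100)], {}, self.CHROMS, gene_models=genes,
            desert_min_gap=5000,
        )
        assert frac["gene_desert"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_classification(self, seed):
        rng = np.random.default_rng(seed)
        order = ["CDS", "UTR", "ncRNA", "intron"]
        features = {
            cls: [
                GenomicInterval(
                    "chr1", int(s := rng.integers(0, 9000)), int(s + rng.integers(50, 800))
                )
                for _ in range(4)
            ]
            for cls in order
        }
        anchors = [
            anchor(int(s := rng.integers(0, 9900)), int(s + rng.integers(1, 100)), aid=f"a{i}")
            for i in range(30)
        ]
        got = feature_composition(anchors, features, self.CHROMS)
        # independent per-base classification with explicit precedence
        classes = np.full(10_000, "intergenic", dtype=object)
        for cls in reversed(order):
            for iv in features[cls]:
                classes[iv.start : iv.end] = cls
        counts: dict[str, int] = {}
        for a in anchors:
            for b in range(a.reference_interval.start, a.reference_interval.end):
                counts[classes[b]] = counts.get(classes[b], 0) + 1
        total = sum(counts.values())
        for cls, fraction in got.items():
            assert fraction == pytest.approx(counts.get(cls, 0) / total, abs=1e-12)
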