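"""Interval permutation enrichment and GC comparison."""

import numpy as np
import pandas as pd
import pytest

from loopcgh.cnvr import CNVR
from loopcgh.enrichment import (
    FeatureSet,
    filter_sd_features,
    gc_compare,
    overlap_count,
    permutation_test,
)
from loopcgh.exceptions import DataError, PlacementError
from loopcgh.synthetic import make_genome


def features_from(intervals, name="feat"):
    return FeatureSet(
        name, pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    )


def random_regions(rng, genome, n=30, size=10_000, cnv_type="loss"):
    out = []
    for _ in range(n):
        chrom = genome.names[int(rng.integers(0, len(genome.names)))]
        start = int(rng.integers(0, genome.lengths[chrom] - size))
        out.append(CNVR(chrom, start, start + size, cnv_type))
    return out


class TestOverlapCount:
    def test_paper_style_fraction(self):
        # 61 of 304 regions overlap a feature
        regions = [
            CNVR("chr1", i * 10_000, i * 10_000 + 5_000, "loss") for i in range(304)
        ]
        feats = features_from(
            [("chr1", i * 10_000 + 1_000, i * 10_000 + 2_000) for i in range(61)]
        )
        count, fraction = overlap_count(regions, feats)
        assert count == 61
        assert fraction == pytest.approx(61 / 304)
        assert round(fraction, 2) == 0.20

    def test_disjoint_sets(self):
        regions = [CNVR("chr1", 0, 100, "loss")]
        feats = features_from([("chr1", 200, 300)])
        assert overlap_count(regions, feats) == (0, 0.0)

    def test_self_overlap(self):
        regions = [CNVR("chr1", i * 1_000, i * 1_000 + 500, "loss") for i in range(10)]
        feats = features_from([(r.chrom, r.start, r.end) for r in regions])
        count, fraction = overlap_count(regions, feats)
        assert count == 10
        assert fraction == 1.0

    def test_unknown_chromosome_rejected(self):
        regions = [CNVR("chr1", 0, 100, "loss")]
        feats = features_from([("chrMT", 0, 10)])
        with pytest.raises(DataError):
            overlap_count(regions, feats, chroms={"chr1"})

    def test_translation_symmetry(self, rng):
        genome = make_genome(1, 1_000_000)
        regions = random_regions(rng, genome, n=15, size=2_000)
        feats = features_from(
            [("chr1", int(s), int(s) + 1_000) for s in rng.integers(0, 900_000, 25)]
        )
        count0, _ = overlap_count(regions, feats)
        offset = 17_000
        shifted_regions = [
            CNVR(r.chrom, r.start + offset, r.end + offset, r.type) for r in regions
        ]
        shifted_feats = features_from(
            [(c, s + offset, e + offset) for c, s, e in feats.frame.itertuples(index=False)]
        )
        count1, _ = overlap_count(shifted_regions, shifted_feats)
        assert count0 == count1


class TestPermutationTest:
    def test_saturated_features_p_one(self, rng):
        genome = make_genome(1, 500_000)
        regions = random_regions(rng, genome, n=10, size=5_000)
        feats = features_from([("chr1", 0, 500_000)])
        result = permutation_test(regions, feats, genome, n_perm=200, seed=1)
        assert result.observed == 10
        assert np.all(result.null == 10)
        assert result.p_value == 1.0

    def test_reproducible_with_seed(self, rng):
        genome = make_genome(2, 400_000)
        regions = random_regions(rng, genome, n=10, size=3_000)
        feats = features_from(
            [("chr1", int(s), int(s) + 2_000) for s in rng.integers(0, 390_000, 20)]
        )
        a = permutation_test(regions, feats, genome, n_perm=300, seed=7)
        b = permutation_test(regions, feats, genome, n_perm=300, seed=7)
        assert np.array_equal(a.null, b.null)
        assert a.p_value == b.p_value

    def test_planted_enrichment_detected(self, rng):
        genome = make_genome(1, 2_000_000)
        feats = features_from(
            [("chr1", int(s), int(s) + 5_000) for s in range(0, 300_000, 10_000)]
        )
        # most regions forced onto features: ~3x more overlap than chance
        regions = [
            CNVR("chr1", i * 10_000 + 1_000, i * 10_000 + 4_000, "loss")
            for i in range(25)
        ]
        result = permutation_test(regions, feats, genome, n_perm=1_000, seed=3)
        assert result.p_value < 0.01

    def test_planted_depletion_detected(self, rng):
        genome = make_genome(1, 1_000_000)
        # features cover half the chromosome, regions all avoid them
        feats = features_from([("chr1", 0, 500_000)])
        regions = [
            CNVR("chr1", 500_000 + i * 15_000, 500_000 + i * 15_000 + 5_000, "loss")
            for i in range(30)
        ]
        result = permutation_test(
            regions, feats, genome, n_perm=1_000, seed=5, mode="depletion"
        )
        assert result.p_value < 0.001

    def test_placements_avoid_gaps(self, rng):
        genome = make_genome(1, 200_000, gap_fraction=0.3, seed=2)
        regions = [CNVR("chr1", 0, 1_000, "loss")]
        gaps = features_from(
            [("chr1", s, e) for s, e in genome.sorted_gaps("chr1")], name="gaps"
        )
        result = permutation_test(regions, gaps, genome, n_perm=2_000, seed=4)
        assert np.all(result.null == 0)

    def test_oversized_region_rejected(self):
        genome = make_genome(1, 10_000)
        regions = [CNVR("chr1", 0, 9_000, "loss")]
        feats = features_from([("chr1", 0, 100)])
        with pytest.raises(PlacementError):
            permutation_test(
                [CNVR("chr1", 0, 20_000, "loss")], feats, genome, n_perm=10
            )
        with pytest.raises(DataError):
            permutation_test(
                [CNVR("chr9", 0, 100, "loss")], feats, genome, n_perm=10
            )
        # in-bounds control works
        permutation_test(regions, feats, genome, n_perm=10, seed=1)

    def test_p_value_plus_one_correction(self, rng):
        genome = make_genome(1, 100_000)
        regions = [CNVR("chr1", 0, 1_000, "loss")]
        feats = features_from([("chr1", 0, 100_000)])
        result = permutation_test(regions, feats, genome, n_perm=99, seed=1)
        assert result.p_value == 1.0  # (1 + 99) / (1 + 99)
        assert 0 < result.p_value <= 1


class TestFilterSdFeatures:
    def test_high_identity_unconfirmed_dropped(self):
        frame = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [0, 100, 200, 300],
                "end": [50, 150, 250, 350],
                "identity": [96.0, 96.0, 93.0, 99.0],
                "evidence": ["WGAC", "both", "WGAC", "WSSD"],
            }
        )
        out = filter_sd_features(FeatureSet("sd", frame))
        assert list(out.frame["start"]) == [100, 200, 300]

    def test_without_columns_passthrough(self):
        feats = features_from([("chr1", 0, 100)])
        assert filter_sd_features(feats) is feats


class TestGcCompare:
    def test_all_gc_sequence(self):
        seqs = {"chr1": "G" * 1_000}
        regions = [CNVR("chr1", 100, 300, "loss")]
        gc_in, gc_genome = gc_compare(regions, seqs)
        assert gc_in == 1.0
        assert gc_genome == 1.0

    def test_planted_islands_recovered(self, rng):
        background = rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=100_000)
        island = rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=10_000)
        seq = background.copy()
        seq[40_000:50_000] = island
        regions = [CNVR("chr1", 40_000, 50_000, "gain")]
        gc_in, gc_genome = gc_compare(regions, {"chr1": "".join(seq)})
        assert gc_in == pytest.approx(0.6, abs=0.02)
        assert gc_genome == pytest.approx(0.42, abs=0.02)

    def test_footprint_not_double_counted(self):
        seqs = {"chr1": "G" * 500 + "A" * 500}
        regions = [
            CNVR("chr1", 0, 400, "loss"),
            CNVR("chr1", 200, 500, "gain"),  # overlaps the first
        ]
        gc_in, _ = gc_compare(regions, seqs)
        assert gc_in == 1.0

    def test_ambiguous_bases_excluded(self):
        seqs = {"chr1": "GCGC" + "N" * 100 + "ATAT"}
        regions = [CNVR("chr1", 0, 104, "loss")]
        gc_in, gc_genome = gc_compare(regions, seqs)
        assert gc_in == 1.0
        assert gc_genome == pytest.approx(0.5)

    def test_empty_cnvr_set(self):
        seqs = {"chr1": "ACGT" * 100}
        with pytest.raises(DataError):
            gc_compare([], seqs)
        gc_in, gc_genome = gc_compare([], seqs, allow_empty=True)
        assert gc_in is None
        assert gc_genome == pytest.approx(0.5)

    def test_missing_chromosome(self):
        with pytest.raises(DataError):
            gc_compare([CNVR("chr9", 0, 10, "loss")], {"chr1": "ACGT"})
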