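"""Synthetic experiment generators: invariants and derived oracles."""

import numpy as np
import pytest

from loopcgh import synthetic
from loopcgh.exceptions import DesignConsistencyError, InvalidArgumentError
from loopcgh.synthetic import (
    AnimalPanel,
    Hybridization,
    make_genome,
    make_loop_design,
    make_panel,
    make_self_self_design,
    plant_cnvs,
    simulate_hybridization,
    theoretical_resolution,
    tile_probes,
)


class TestMakeGenome:
    def test_no_gap_case(self):
        genome = make_genome(1, 1_000_000, gap_fraction=0.0, seed=1)
        assert genome.names == ("chr1",)
        assert genome.total_length == 1_000_000
        assert genome.gap_length() == 0

    def test_gap_total_recomputed_from_output(self):
        genome = make_genome(2, [500_000, 300_000], gap_fraction=0.05, seed=7)
        total = sum(
            e - s for chrom in genome.names for s, e in genome.sorted_gaps(chrom)
        )
        assert total == pytest.approx(0.05 * 800_000, rel=0.02)

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_genome(1, 0)

    def test_gap_fraction_bounds(self):
        with pytest.raises(InvalidArgumentError):
            make_genome(1, 1000, gap_fraction=0.5)

    def test_gaps_within_bounds_and_disjoint(self):
        genome = make_genome(3, 200_000, gap_fraction=0.1, seed=3)
        for chrom in genome.names:
            prev = 0
            for s, e in genome.sorted_gaps(chrom):
                assert 0 <= s < e <= genome.lengths[chrom]
                assert s >= prev
                prev = e

    def test_deterministic(self):
        a = make_genome(2, 100_000, gap_fraction=0.08, seed=42)
        b = make_genome(2, 100_000, gap_fraction=0.08, seed=42)
        assert a == b

    def test_x_chromosome_naming(self):
        genome = make_genome(2, 100_000, x_chromosome=True)
        assert genome.names == ("chr1", "chrX")


class TestTileProbes:
    def test_exact_spacing_no_jitter(self):
        genome = make_genome(1, 1_000_000)
        probes = tile_probes(genome, median_spacing=301, probe_length=60, jitter=0.0)
        assert len(probes) == 3323  # floor((1e6 - 60) / 301) + 1
        assert (np.diff(probes["start"]) == 301).all()

    def test_median_spacing_under_jitter(self):
        genome = make_genome(1, 2_000_000)
        probes = tile_probes(genome, 301, 60, jitter=0.5, seed=1)
        spacing = np.median(np.diff(probes["start"]))
        assert abs(spacing - 301) <= 0.1 * 301

    def test_spacing_precondition(self):
        genome = make_genome(1, 10_000)
        with pytest.raises(InvalidArgumentError):
            tile_probes(genome, median_spacing=50, probe_length=60)

    def test_probes_avoid_gaps_and_sorted(self):
        genome = make_genome(2, 300_000, gap_fraction=0.1, seed=5)
        probes = tile_probes(genome, 301, 60, jitter=0.2, seed=2)
        for chrom in genome.names:
            sub = probes[probes["chrom"] == chrom]
            assert (np.diff(sub["start"]) > 0).all()
            for s, e in genome.sorted_gaps(chrom):
                overlap = (sub["start"] < e) & (sub["end"] > s)
                assert not overlap.any()

    def test_grid_coordinates_unique(self):
        genome = make_genome(1, 100_000)
        probes = tile_probes(genome, 301, 60)
        assert not probes.duplicated(["x", "y"]).any()


class TestTheoreticalResolution:
    @pytest.mark.parametrize(
        "spacing, length, k, expected",
        [(300, 53, 5, 1465), (301, 60, 5, 1504), (1, 1, 1, 1)],
    )
    def test_values(self, spacing, length, k, expected):
        assert theoretical_resolution(spacing, length, k) == expected

    def test_positive_preconditions(self):
        with pytest.raises(InvalidArgumentError):
            theoretical_resolution(0, 60, 5)


class TestPlantCnvs:
    def test_empty_truth_set(self):
        panel = make_panel(1)
        genome = make_genome(1, 100_000)
        assert plant_cnvs(panel, genome, 0) == []

    def test_counts_and_loss_fraction(self):
        panel = make_panel(10)
        genome = make_genome(2, 2_000_000)
        truth = plant_cnvs(panel, genome, 5, loss_fraction=0.66, seed=3)
        assert len(truth) == 50
        losses = sum(1 for c in truth if c.state == "loss")
        # binomial(50, 0.66): +- 3 sd
        assert abs(losses - 33) <= 3 * np.sqrt(50 * 0.66 * 0.34)

    def test_paper_like_loss_share(self):
        panel = make_panel(20)
        genome = make_genome(4, 3_000_000)
        truth = plant_cnvs(panel, genome, 15, loss_fraction=0.664, seed=1)
        share = sum(1 for c in truth if c.state == "loss") / len(truth)
        assert share == pytest.approx(202 / 304, abs=0.08)

    def test_min_size_enforced(self):
        panel = make_panel(1)
        genome = make_genome(1, 100_000)
        with pytest.raises(InvalidArgumentError):
            plant_cnvs(panel, genome, 1, size_range=(500, 2_000))

    def test_avoids_gaps(self):
        panel = make_panel(3)
        genome = make_genome(1, 500_000, gap_fraction=0.2, seed=2)
        truth = plant_cnvs(panel, genome, 3, size_range=(1_000, 5_000), seed=4)
        for cnv in truth:
            for s, e in genome.sorted_gaps(cnv.chrom):
                assert cnv.end <= s or cnv.start >= e

    def test_disjoint_across_animals(self):
        panel = make_panel(5)
        genome = make_genome(1, 1_000_000)
        truth = plant_cnvs(panel, genome, 4, seed=6)
        for i, a in enumerate(truth):
            for b in truth[i + 1 :]:
                assert a.chrom != b.chrom or a.end <= b.start or b.end <= a.start


class TestLoopDesign:
    def test_ring_structure(self):
        panel = make_panel(6)
        design = make_loop_design(panel)
        assert len(design.hybridizations) == 12  # 6 pairs x 2 orientations
        partners = {a: set() for a in panel.animals}
        seen = set()
        for h in design.hybridizations:
            partners[h.cy3_animal].add(h.cy5_animal)
            partners[h.cy5_animal].add(h.cy3_animal)
            key = (h.cy3_animal, h.cy5_animal)
            assert key not in seen  # each (pair, orientation) exactly once
            seen.add(key)
        for animal, p in partners.items():
            assert len(p) == 2

    def test_swap_mates_exchange_roles(self):
        design = make_loop_design(make_panel(4))
        for h in design.hybridizations:
            mate = design[design.swap_mate[h.array_id]]
            assert mate.cy3_animal == h.cy5_animal
            assert mate.cy5_animal == h.cy3_animal

    def test_too_few_animals(self):
        with pytest.raises(InvalidArgumentError):
            make_loop_design(make_panel(2))

    def test_inconsistent_design_rejected(self):
        hybs = (
            Hybridization("x", "a1", "a2"),
            Hybridization("y", "a1", "a2"),  # not swapped
        )
        with pytest.raises(DesignConsistencyError):
            synthetic.LoopDesign(hybs, {"x": "y", "y": "x"})


class TestSimulateHybridization:
    def _setup(self, n_animals=3, length=100_000, seed=0):
        genome = make_genome(1, length)
        panel = make_panel(n_animals, seed=seed)
        probes = tile_probes(genome, 301, 60)
        return genome, panel, probes

    def test_self_self_identity(self):
        _, panel, probes = self._setup()
        hyb = Hybridization("s", "a1", "a1")
        table = simulate_hybridization(hyb, probes, [], panel, noise_sd=0.0)
        assert np.allclose(table.frame["ratio"], 0.0)

    def test_planted_loss_is_minus_one(self):
        _, panel, probes = self._setup()
        truth = [synthetic.PlantedCNV("a1", "chr1", 20_000, 30_000, 1)]
        hyb = Hybridization("h", "a1", "a2")
        table = simulate_hybridization(hyb, probes, truth, panel, noise_sd=0.0)
        mid = (table.frame["start"] + table.frame["end"]) // 2
        inside = (mid >= 20_000) & (mid < 30_000)
        assert np.allclose(table.frame.loc[inside, "ratio"], -1.0)
        assert np.allclose(table.frame.loc[~inside, "ratio"], 0.0)

    def test_male_vs_female_chrx_dosage(self):
        genome = make_genome(2, 100_000, x_chromosome=True)
        panel = AnimalPanel(("m", "f"), {"m": "male", "f": "female"})
        probes = tile_probes(genome, 301, 60)
        hyb = Hybridization("sx", "m", "f")
        table = simulate_hybridization(hyb, probes, [], panel, noise_sd=0.0)
        on_x = table.frame["chrom"] == "chrX"
        assert np.allclose(table.frame.loc[on_x, "ratio"], -1.0)
        assert np.allclose(table.frame.loc[~on_x, "ratio"], 0.0)

    def test_dye_swap_antisymmetry(self):
        _, panel, probes = self._setup()
        truth = [synthetic.PlantedCNV("a1", "chr1", 10_000, 25_000, 3)]
        fwd = Hybridization("f", "a1", "a2")
        rev = Hybridization("r", "a2", "a1")
        tf = simulate_hybridization(fwd, probes, truth, panel, noise_sd=0.0, seed=1)
        tr = simulate_hybridization(rev, probes, truth, panel, noise_sd=0.0, seed=2)
        assert np.allclose(tf.frame["ratio"], -tr.frame["ratio"])

    def test_unknown_animal_rejected(self):
        _, panel, probes = self._setup()
        with pytest.raises(DesignConsistencyError):
            simulate_hybridization(
                Hybridization("h", "a1", "ghost"), probes, [], panel
            )

    def test_mean_ratio_near_zero_low_noise(self):
        _, panel, probes = self._setup(length=500_000)
        hyb = Hybridization("h", "a1", "a2")
        table = simulate_hybridization(hyb, probes, [], panel, noise_sd=0.01, seed=3)
        assert abs(table.frame["ratio"].mean()) < 0.005

    def test_expected_ratio_decomposition_with_bias(self):
        _, panel, probes = self._setup()
        hyb = Hybridization("h", "a1", "a2")
        table = simulate_hybridization(
            hyb, probes, [], panel, noise_sd=0.0, dye_bias=0.37
        )
        assert np.allclose(table.frame["ratio"], 0.37)

    def test_determinism_byte_identical(self):
        _, panel, probes = self._setup()
        hyb = Hybridization("h", "a1", "a2")
        a = simulate_hybridization(hyb, probes, [], panel, noise_sd=0.3, seed=9)
        b = simulate_hybridization(hyb, probes, [], panel, noise_sd=0.3, seed=9)
        assert a.frame.equals(b.frame)

    def test_truth_round_trip_oracle_threshold(self):
        """At noise 0, |shift| >= 1 CNVs are recoverable by thresholding."""
        genome = make_genome(1, 300_000)
        panel = make_panel(3, seed=1)
        probes = tile_probes(genome, 301, 60)
        truth = plant_cnvs(panel, genome, 2, size_range=(3_000, 8_000), seed=2,
                           loss_fraction=1.0)
        for hyb in make_loop_design(panel).hybridizations:
            table = simulate_hybridization(hyb, probes, truth, panel, noise_sd=0.0)
            mid = (table.frame["start"] + table.frame["end"]) // 2
            for cnv in truth:
                if cnv.animal not in (hyb.cy3_animal, hyb.cy5_animal):
                    continue
                if cnv.animal == hyb.cy3_animal:
                    expected_sign = -1 if cnv.state == "loss" else 1
                else:
                    expected_sign = 1 if cnv.state == "loss" else -1
                inside = (mid >= cnv.start) & (mid < cnv.end)
                assert inside.sum() >= 5
                assert np.all(
                    np.sign(table.frame.loc[inside, "ratio"]) == expected_sign
                )


class TestSelfSelfDesign:
    def test_structure(self):
        design = make_self_self_design("a1")
        assert len(design.hybridizations) == 2
        assert design.animals == {"a1"}
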