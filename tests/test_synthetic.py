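import math

import numpy as np
import pytest

from netmap import (InvalidParameterError, gen_annotations, gen_cohort,
                    gen_dige_tables, gen_interactome, gen_planted_partition)
from netmap.synthetic import PlantedDigeTruth


class TestGenInteractome:
    def test_seed_expansion_node_arithmetic(self):
        inter, seeds = gen_interactome(45, 821, 3000, rng_seed=7)
        expanded = set(seeds)
        for s in seeds:
            expanded |= inter.partners(s)
        assert len(expanded) == 45 + 821
        assert len(inter.symbols) == 866

    def test_every_seed_interacts(self):
        inter, seeds = gen_interactome(5, 20, 0, rng_seed=1)
        assert all(inter.partners(s) for s in seeds)

    def test_seeded_determinism(self):
        a, _ = gen_interactome(45, 821, 3000, rng_seed=7)
        b, _ = gen_interactome(45, 821, 3000, rng_seed=7)
        assert a.pairs == b.pairs

    def test_single_isolated_seed_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_interactome(1, 0, 0, rng_seed=1)

    def test_two_seeds_no_partners_link_each_other(self):
        inter, seeds = gen_interactome(2, 0, 0, rng_seed=1)
        assert inter.pairs == frozenset({tuple(sorted(seeds))})

    def test_nonpositive_seeds_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_interactome(0, 10, 0, rng_seed=1)


class TestGenPlantedPartition:
    def test_edge_density_matches_probabilities(self):
        sizes = [25, 25, 25, 25]
        inter, truth = gen_planted_partition(sizes, 0.3, 0.01, rng_seed=11)
        labels = truth.partition_labels
        within = sum(1 for a, b in inter.pairs if labels[a] == labels[b])
        between = len(inter.pairs) - within
        n_within_pairs = 4 * math.comb(25, 2)
        n_between_pairs = math.comb(100, 2) - n_within_pairs
        for count, pairs, p in [(within, n_within_pairs, 0.3),
                                (between, n_between_pairs, 0.01)]:
            sd = math.sqrt(pairs * p * (1 - p))
            assert abs(count - pairs * p) <= 4 * sd

    def test_node_count_and_label_cover(self):
        inter, truth = gen_planted_partition([10, 10, 10], 0.5, 0.05, rng_seed=2)
        assert len(truth.partition_labels) == 30
        assert inter.symbols <= set(truth.partition_labels)

    def test_forced_disjoint_edges(self):
        inter, _ = gen_planted_partition([2, 2], 1.0, 0.0, rng_seed=1)
        assert len(inter.pairs) == 2

    def test_forced_triangle(self):
        inter, _ = gen_planted_partition([3], 1.0, 0.0, rng_seed=1)
        assert len(inter.pairs) == 3

    def test_probability_ordering_enforced(self):
        with pytest.raises(InvalidParameterError):
            gen_planted_partition([5, 5], 0.1, 0.1, rng_seed=1)

    def test_seeded_determinism(self):
        a, _ = gen_planted_partition([10, 10], 0.4, 0.02, rng_seed=5)
        b, _ = gen_planted_partition([10, 10], 0.4, 0.02, rng_seed=5)
        assert a.pairs == b.pairs


@pytest.fixture(scope="module")
def partition_labels():
    return {f"G{i:03d}": i // 25 for i in range(100)}


class TestGenAnnotations:

    def test_planted_terms_exceed_background(self, partition_labels):
        ann, truth = gen_annotations(partition_labels, 4, 0.8, 0.02, 20000,
                                     rng_seed=3)
        for module, term in truth.enriched_pairs:
            members = {g for g, m in partition_labels.items() if m == module}
            in_rate = len(ann.term_to_genes[term] & members) / len(members)
            out_rate = len(ann.term_to_genes[term] - members) / (20000 - 25)
            assert in_rate > out_rate

    def test_universe_recorded(self, partition_labels):
        ann, _ = gen_annotations(partition_labels, 2, 0.5, 0.01, 20000, rng_seed=1)
        assert ann.universe_size == 20000

    def test_equal_rates_rejected(self, partition_labels):
        with pytest.raises(InvalidParameterError):
            gen_annotations(partition_labels, 2, 0.5, 0.5, 20000, rng_seed=1)

    def test_small_universe_rejected(self, partition_labels):
        with pytest.raises(InvalidParameterError):
            gen_annotations(partition_labels, 2, 0.5, 0.01, 50, rng_seed=1)

    def test_seeded_determinism(self, partition_labels):
        a, _ = gen_annotations(partition_labels, 3, 0.7, 0.02, 5000, rng_seed=4)
        b, _ = gen_annotations(partition_labels, 3, 0.7, 0.02, 5000, rng_seed=4)
        assert a.term_to_genes == b.term_to_genes


class TestGenDigeTables:
    def test_zero_noise_ratios_exact(self):
        truth = PlantedDigeTruth(differential_spots={"S0001": 2.0}, noise_sd=0.0)
        exp = gen_dige_tables(3, 4, truth, rng_seed=1)
        for gel in exp.gels:
            assert gel.spot_ratios["S0001"] == pytest.approx(2.0)
            assert gel.spot_ratios["S0002"] == pytest.approx(1.0)

    def test_dye_swap_gels_emit_reciprocal_orientation(self):
        truth = PlantedDigeTruth(differential_spots={"S0001": 4.0}, noise_sd=0.0,
                                 dye_swap_gels=frozenset({"GEL2"}))
        exp = gen_dige_tables(2, 2, truth, rng_seed=1)
        plain, swapped = exp.gels
        assert plain.dye_orientation == "complete_cy5"
        assert swapped.dye_orientation == "complete_cy3"
        assert swapped.spot_ratios["S0001"] == pytest.approx(
            1.0 / plain.spot_ratios["S0001"])

    def test_noise_magnitude(self):
        truth = PlantedDigeTruth(noise_sd=0.1)
        exp = gen_dige_tables(500, 7, truth, rng_seed=5)
        logs = np.log2([r for g in exp.gels for r in g.spot_ratios.values()])
        assert np.std(logs) == pytest.approx(0.1, rel=0.1)

    def test_seeded_determinism(self):
        truth = PlantedDigeTruth(differential_spots={"S0001": 2.0})
        a = gen_dige_tables(10, 7, truth, rng_seed=8)
        b = gen_dige_tables(10, 7, truth, rng_seed=8)
        for ga, gb in zip(a.gels, b.gels):
            assert ga.spot_ratios == gb.spot_ratios

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            PlantedDigeTruth(noise_sd=-0.1)
        with pytest.raises(InvalidParameterError):
            PlantedDigeTruth(differential_spots={"S0001": 0.5})
        with pytest.raises(InvalidParameterError):
            gen_dige_tables(3, 1, PlantedDigeTruth(), rng_seed=1)
        with pytest.raises(InvalidParameterError):
            gen_dige_tables(3, 4, PlantedDigeTruth(
                differential_spots={"S9999": 2.0}), rng_seed=1)


class TestGenCohort:
    def test_fields_within_ranges(self):
        table = gen_cohort(14, (19, 55), (1, 8), ["A", "C", "D"], rng_seed=2)
        assert len(table) == 14
        assert table.df["age"].between(19, 55).all()
        assert table.df["days_post_injury"].between(1, 8).all()
        assert set(table.df["ais_grade"]) <= {"A", "C", "D"}

    def test_single_row(self):
        assert len(gen_cohort(1, (40, 40), (1, 1), ["A"], rng_seed=1)) == 1

    def test_empty_grades_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_cohort(5, (19, 55), (1, 8), [], rng_seed=1)

    def test_seeded_determinism(self):
        a = gen_cohort(14, (19, 55), (1, 8), ["A", "C"], rng_seed=2)
        b = gen_cohort(14, (19, 55), (1, 8), ["A", "C"], rng_seed=2)
        assert a.df.equals(b.df)
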