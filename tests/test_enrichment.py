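import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netmap import (AnnotationSet, EnrichmentConfig, InvalidParameterError,
                    bh_fdr, enrich_all, enrich_module, gen_annotations,
                    gen_planted_partition, girvan_newman, hypergeom_upper)
from netmap.modularity import Partition


def exact_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Independent oracle: exact rational upper-tail by full enumeration."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


class TestHypergeomUpper:
    def test_small_urn_value(self):
        # 4 draws from an urn of 10 with 5 marked; all 4 marked: 1/42
        assert hypergeom_upper(10, 5, 4, 4) == pytest.approx(1 / 42, abs=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_upper(100, 10, 5, 0) == 1.0

    def test_term_covering_universe_is_one(self):
        assert hypergeom_upper(50, 50, 7, 7) == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_enumeration_for_all_small_configs(self):
        for N in range(1, 13):
            for K, n in itertools.product(range(N + 1), repeat=2):
                for k in range(min(n, K) + 1):
                    expected = float(exact_upper_tail(N, K, n, k))
                    assert hypergeom_upper(N, K, n, k) == \
                        pytest.approx(expected, abs=1e-12), (N, K, n, k)

    def test_pmf_sums_to_one(self):
        # P(X >= 0) exhausts the support for every small configuration
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    assert exact_upper_tail(N, K, n, 0) == 1

    def test_strictly_decreasing_in_k(self):
        N, K, n = 1000, 50, 40
        values = [hypergeom_upper(N, K, n, k) for k in range(0, 12)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_numerically_stable_at_genome_scale(self):
        p = hypergeom_upper(100000, 500, 100, 30)
        assert 0 < p < 1e-20

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            hypergeom_upper(10, 12, 4, 2)
        with pytest.raises(InvalidParameterError):
            hypergeom_upper(10, 5, 4, 5)


class TestBhFdr:
    def test_single_value_identity(self):
        assert bh_fdr([0.05]) == [0.05]

    def test_step_up_by_hand(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_empty(self):
        assert bh_fdr([]) == []

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=30))
    def test_output_dominates_input(self, pvals):
        corrected = bh_fdr(pvals)
        assert all(q >= p - 1e-12 for p, q in zip(pvals, corrected))
        assert all(q <= 1.0 for q in corrected)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2,
                    max_size=20), st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rng):
        order = list(range(len(pvals)))
        rng.shuffle(order)
        direct = bh_fdr([pvals[i] for i in order])
        reference = bh_fdr(pvals)
        assert direct == pytest.approx([reference[i] for i in order])

    def test_idempotent_on_tie_collapsed_corrected_list(self):
        # step-up output whose values are the running minimum is a fixed point
        once = bh_fdr([0.01, 0.02, 0.03])
        assert bh_fdr(once) == pytest.approx(once)


class TestEnrichModule:
    def test_strong_overlap_is_tiny(self):
        term = frozenset(f"T{i}" for i in range(50))
        ann = AnnotationSet(term_to_genes={"GO:1": term}, universe_size=20000)
        module = [f"T{i}" for i in range(8)] + ["X1", "X2"]
        with pytest.raises(InvalidParameterError):
            # X1/X2 are outside the annotation universe: n would drop below
            # min_module_size only if all genes were unannotated; size check ok
            enrich_module("M1", ["X1"], ann)
        results = enrich_module("M1", module, ann)
        assert len(results) == 1
        r = results[0]
        assert (r.k, r.K, r.N) == (8, 50, 20000)
        assert r.hyp < 1e-12

    def test_term_absent_from_module_produces_no_row(self):
        ann = AnnotationSet(term_to_genes={"GO:1": frozenset({"A", "B"})},
                            universe_size=100)
        assert enrich_module("M1", ["X", "Y", "Z"], ann) == []

    def test_unannotated_module_mirrors_no_annotations(self):
        ann = AnnotationSet(term_to_genes={"GO:1": frozenset({"A", "B"})},
                            universe_size=100)
        assert enrich_module("M6", ["P", "Q"], ann) == []


@pytest.fixture(scope="module")
def planted():
    inter, truth = gen_planted_partition([25, 25, 25, 25], 0.3, 0.01,
                                         rng_seed=11)
    partition = girvan_newman(inter.to_graph())
    annotations, etruth = gen_annotations(truth.partition_labels, 4, 0.8,
                                          0.02, 20000, rng_seed=3)
    return partition, annotations, etruth, truth


class TestEnrichAll:

    def test_planted_pairs_significant_no_false_positives(self, planted):
        partition, annotations, etruth, truth = planted
        results = enrich_all(partition, annotations)
        significant = {(r.module_id, r.term_id) for r in results if r.significant}
        # map detected module ids onto planted ids via majority membership
        detected_to_planted = {}
        for mod_id, members in partition.modules().items():
            labels = [truth.partition_labels[n] for n in members]
            detected_to_planted[mod_id] = max(set(labels), key=labels.count)
        mapped = {(detected_to_planted[m], t) for m, t in significant}
        assert mapped == set(etruth.enriched_pairs)
        assert len(significant) == len(etruth.enriched_pairs)

    def test_alpha_cutoff_is_strict(self):
        ann = AnnotationSet(term_to_genes={"GO:1": frozenset({"A", "B"})},
                            universe_size=100)
        partition = Partition(assignment={"A": 0, "B": 0}, modularity_q=None,
                              method="fixed", n_modules=1)
        results = enrich_all(partition, ann, EnrichmentConfig(alpha=0.001))
        (r,) = results
        r.hyp_star = 0.001  # exactly at the cutoff
        assert not (r.hyp_star < 0.001)

    def test_small_modules_skipped(self):
        ann = AnnotationSet(term_to_genes={"GO:1": frozenset({"A", "B", "C"})},
                            universe_size=10)
        partition = Partition(assignment={"A": 0, "B": 0, "C": 1},
                              modularity_q=None, method="fixed", n_modules=2)
        results = enrich_all(partition, ann)
        assert {r.module_id for r in results} == {0}

    def test_null_false_positive_rate_controlled(self):
        """Annotations independent of modules: FPR at alpha 0.001 stays tiny."""
        rng = np.random.default_rng(123)
        universe = [f"G{i:04d}" for i in range(2000)]
        term_to_genes = {}
        for t in range(200):
            mask = rng.random(len(universe)) < 0.05
            genes = frozenset(g for g, m in zip(universe, mask) if m)
            term_to_genes[f"T{t:03d}"] = genes or frozenset({universe[t]})
        ann = AnnotationSet(term_to_genes=term_to_genes,
                            universe_size=len(universe))
        assignment = {g: i // 10 for i, g in enumerate(universe[:500])}
        partition = Partition(assignment=assignment, modularity_q=None,
                              method="fixed", n_modules=50)
        results = enrich_all(partition, ann)
        n_tests = 50 * 200  # (module, term) pairs examined
        n_false = sum(r.significant for r in results)
        assert n_false / n_tests <= 0.005
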