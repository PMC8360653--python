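"""The core statistic: TSS capture, hypergeometric tail, fold, BH, scan."""

from fractions import Fraction

import numpy as np
import pytest

from conftest import (
    brute_genes_near_peaks,
    brute_hypergeom_upper_tail,
    make_universe,
    random_micro_instance,
)
from tssenrich.enrichment import (
    DEFAULT_LADDER,
    DistanceLadder,
    EnrichmentResult,
    adjust_bh,
    fold_enrichment,
    genes_near_peaks,
    hypergeom_upper_tail,
    neglog10p_matrix,
    pegs_scan,
)
from tssenrich.gene_sets import GeneCluster
from tssenrich.intervals import Peak, PeakSet


class TestHypergeomUpperTail:
    def test_matches_exact_enumeration_example(self):
        # tail of Hypergeometric(N=10, K=4, n=5) at k=3 is 66/252
        oracle = brute_hypergeom_upper_tail(10, 4, 5, 3)
        assert oracle == Fraction(66, 252)
        assert abs(hypergeom_upper_tail(10, 4, 5, 3) - float(oracle)) < 1e-12

    def test_certain_overlap_and_empty_overlap_are_probability_one(self):
        assert hypergeom_upper_tail(10, 5, 10, 5) == 1.0
        assert hypergeom_upper_tail(10, 5, 5, 0) == 1.0
        assert hypergeom_upper_tail(20000, 100, 0, 0) == 1.0

    def test_matches_enumeration_on_random_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            N = int(rng.integers(1, 40))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = float(brute_hypergeom_upper_tail(N, K, n, k))
            assert abs(hypergeom_upper_tail(N, K, n, k) - expected) < 1e-12

    def test_contract_violations_raise(self):
        for N, K, n, k in [(10, 11, 5, 0), (10, 4, 11, 0), (10, 4, 5, 5), (10, 4, 5, -1)]:
            with pytest.raises(ValueError):
                hypergeom_upper_tail(N, K, n, k)

    def test_extreme_tail_stays_positive(self):
        p = hypergeom_upper_tail(20000, 200, 200, 200)
        assert 0.0 < p < 1e-300


class TestFoldEnrichment:
    def test_arithmetic(self):
        assert fold_enrichment(20000, 100, 2000, 40) == pytest.approx(4.0)

    def test_saturation_is_one(self):
        assert fold_enrichment(100, 10, 100, 10) == pytest.approx(1.0)

    def test_zero_overlap_or_empty_near_set_is_zero(self):
        assert fold_enrichment(100, 10, 50, 0) == 0.0
        assert fold_enrichment(100, 10, 0, 0) == 0.0

    def test_empty_cluster_is_contract_error(self):
        with pytest.raises(ValueError):
            fold_enrichment(100, 0, 50, 0)


class TestGenesNearPeaks:
    def test_empty_peakset(self, tiny_universe, tiny_bounds):
        assert genes_near_peaks(PeakSet("e"), 100, tiny_universe, bounds=tiny_bounds) == set()

    def test_only_tss_inside_extended_peak_captured(self, tiny_universe, tiny_bounds):
        peaks = PeakSet("p", [Peak("chr1", 4900, 5100)])
        near = genes_near_peaks(peaks, 100, tiny_universe, bounds=tiny_bounds)
        assert near == {"geneB"}

    def test_saturating_lambda_captures_all_genes_on_peak_chromosomes(
        self, tiny_universe, tiny_bounds
    ):
        peaks = PeakSet("p", [Peak("chr1", 0, 1)])
        near = genes_near_peaks(peaks, 10_000_000, tiny_universe, bounds=tiny_bounds)
        assert near == {"geneA", "geneB", "geneC"}

    def test_gene_counted_once_despite_multiple_hits(self, tiny_bounds):
        universe = make_universe({"g": {("chr1", 100, "+"), ("chr1", 300, "+")}})
        peaks = PeakSet("p", [Peak("chr1", 90, 110), Peak("chr1", 290, 310)])
        assert genes_near_peaks(peaks, 10, universe, bounds=tiny_bounds) == {"g"}

    def test_matches_brute_force_on_random_micro_instances(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            universe, peaks, bounds = random_micro_instance(rng)
            lam = int(rng.integers(0, 5000))
            mode = "edges" if rng.random() < 0.5 else "center"
            fast = genes_near_peaks(peaks, lam, universe, mode=mode, bounds=bounds)
            slow = brute_genes_near_peaks(peaks, lam, universe, mode=mode, bounds=bounds)
            assert fast == slow


class TestAdjustBH:
    def _results(self, ps):
        return [
            EnrichmentResult("ps", f"c{i}", 100, 100, 10, 10, 1, 1.0, p)
            for i, p in enumerate(ps)
        ]

    def test_single_test_unchanged(self):
        (r,) = adjust_bh(self._results([0.03]))
        assert r.p_adj == pytest.approx(0.03)

    def test_identical_pvalues_are_a_fixed_point(self):
        out = adjust_bh(self._results([0.2] * 5))
        assert all(r.p_adj == pytest.approx(0.2) for r in out)

    def test_step_up_rule_hand_applied(self):
        out = adjust_bh(self._results([0.01, 0.02, 0.03, 0.04]))
        assert [r.p_adj for r in out] == pytest.approx([0.04] * 4)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        out = adjust_bh(self._results(list(rng.random(50))))
        assert all(r.p_adj >= r.p - 1e-15 and r.p_adj <= 1.0 for r in out)


class TestPegsScan:
    def _setup(self):
        rng = np.random.default_rng(2)
        genes = {
            f"g{i}": {("chr1", int(p), "+")}
            for i, p in enumerate(rng.integers(0, 100_000, size=60))
        }
        universe = make_universe(genes)
        peaks = PeakSet(
            "peaks",
            [Peak("chr1", int(s), int(s) + 50) for s in rng.integers(0, 100_000, 8)],
        )
        bounds = {"chr1": 100_000}
        return universe, peaks, bounds

    def test_cardinality_one_result_per_cell(self):
        universe, peaks, bounds = self._setup()
        clusters = [
            GeneCluster("a", {"g0", "g1", "g2"}),
            GeneCluster("b", {"g3", "g4"}),
        ]
        ladder = DistanceLadder(DEFAULT_LADDER)
        results = pegs_scan([peaks], clusters, ladder, universe, bounds)
        assert len(results) == 22
        assert all(r.N == 60 for r in results)

    def test_n_and_k_nondecreasing_in_lambda(self):
        universe, peaks, bounds = self._setup()
        cluster = GeneCluster("a", {f"g{i}" for i in range(20)})
        results = pegs_scan(
            [peaks], [cluster], DistanceLadder((10, 100, 1000, 10_000, 100_000)),
            universe, bounds,
        )
        ns = [r.n for r in results]
        ks = [r.k for r in results]
        assert ns == sorted(ns) and ks == sorted(ks)

    def test_cluster_equal_to_near_set_gives_maximal_overlap(self):
        universe, peaks, bounds = self._setup()
        near = genes_near_peaks(peaks, 500, universe, bounds=bounds)
        cluster = GeneCluster("exact", near)
        results = pegs_scan([peaks], [cluster], DistanceLadder((500,)), universe, bounds)
        (r,) = results
        assert r.k == r.K == len(near) and r.k == min(r.K, r.n)
        assert r.p == pytest.approx(
            float(brute_hypergeom_upper_tail(r.N, r.K, r.n, r.k)), abs=1e-12
        )

    def test_members_absent_from_universe_dropped_from_K_and_k(self):
        universe, peaks, bounds = self._setup()
        cluster = GeneCluster("a", {"g0", "g1", "NOT_A_GENE"})
        (r, *_) = pegs_scan([peaks], [cluster], DistanceLadder((100,)), universe, bounds)
        assert r.K == 2

    def test_fully_absent_cluster_skipped_scan_continues(self, caplog):
        universe, peaks, bounds = self._setup()
        clusters = [GeneCluster("ghost", {"X", "Y"}), GeneCluster("ok", {"g0"})]
        results = pegs_scan([peaks], clusters, DistanceLadder((100,)), universe, bounds)
        assert {r.cluster_name for r in results} == {"ok"}
        with pytest.raises(ValueError):
            pegs_scan([peaks], [clusters[0]], DistanceLadder((100,)), universe, bounds)

    def test_results_invariant_to_peak_and_gene_order(self):
        universe, peaks, bounds = self._setup()
        cluster = GeneCluster("a", {f"g{i}" for i in range(15)})
        ladder = DistanceLadder((100, 10_000))
        base = pegs_scan([peaks], [cluster], ladder, universe, bounds)
        shuffled_peaks = PeakSet("peaks", peaks.peaks[::-1])
        shuffled_universe = make_universe(
            dict(sorted(universe.genes.items(), reverse=True))
        )
        other = pegs_scan([shuffled_peaks], [cluster], ladder, shuffled_universe, bounds)
        assert [(r.n, r.k, r.p) for r in base] == [(r.n, r.k, r.p) for r in other]

    def test_neglog10_matrix_shape(self):
        universe, peaks, bounds = self._setup()
        clusters = [GeneCluster("a", {"g0", "g1"}), GeneCluster("b", {"g2", "g3"})]
        results = pegs_scan([peaks], clusters, DistanceLadder((10, 100)), universe, bounds)
        matrix = neglog10p_matrix(results, "peaks")
        assert matrix.shape == (2, 2)


def test_distance_ladder_validation_and_parsing():
    with pytest.raises(ValueError):
        DistanceLadder(())
    with pytest.raises(ValueError):
        DistanceLadder((100, 100))
    with pytest.raises(ValueError):
        DistanceLadder((-1, 100))
    assert tuple(DistanceLadder.parse("100,500, 1000")) == (100, 500, 1000)
    assert tuple(DistanceLadder()) == DEFAULT_LADDER
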