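"""KS comparisons, Bonferroni, fold change and hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nirvspipe.core import NirvsLocus
from nirvspipe.stats import (
    StatsConfig,
    bonferroni_threshold,
    compare_locus,
    enrichment_report,
    hypergeometric_enrichment,
    ks_two_sample,
    locus_attribute,
    sg_reference,
    volcano_table,
)


def brute_force_ks_d(x, y):
    """Sup of |ECDF_x - ECDF_y| over the pooled breakpoints."""
    x, y = np.sort(x), np.sort(y)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0, 0, 0], [1, 1, 1])
        assert d == 1.0

    def test_interleaved_example(self):
        d, _ = ks_two_sample([1, 2], [1.5, 2.5])
        assert d == pytest.approx(0.5)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_d_matches_brute_force(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(1, 50)))
            y = rng.normal(loc=rng.uniform(-1, 1), size=int(rng.integers(1, 50)))
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)


class TestSgReference:
    def test_median_of_three(self):
        table = pd.DataFrame({"S1": [0.001, 0.007, 0.020]}, index=["g1", "g2", "g3"])
        ref = sg_reference(table, ["g1", "g2", "g3"])
        assert ref["S1"] == pytest.approx(0.007)

    def test_constant_when_sgs_identical(self):
        table = pd.DataFrame(
            {"S1": [0.004, 0.004], "S2": [0.004, 0.004]}, index=["g1", "g2"]
        )
        ref = sg_reference(table, ["g1", "g2"])
        assert (ref == 0.004).all()

    def test_random_table_matches_direct_medians(self, rng):
        table = pd.DataFrame(
            rng.uniform(0, 0.02, size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"S{i}" for i in range(4)],
        )
        ref = sg_reference(table, [f"g{i}" for i in range(6)])
        for col in table.columns:
            assert ref[col] == pytest.approx(np.median(table[col]))

    def test_all_missing_sample_errors(self):
        table = pd.DataFrame({"S1": [np.nan, np.nan], "S2": [0.1, 0.2]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="S1"):
            sg_reference(table, ["g1", "g2"])


class TestCompareLocus:
    def test_fold_change_of_two(self):
        locus = [0.0142] * 8
        ref = [0.0071] * 8
        row = compare_locus("L", locus, ref, StatsConfig(n_tests=1))
        assert row.fold_change == pytest.approx(2.0)
        assert row.log2_fold_change == pytest.approx(1.0)

    def test_identical_distributions(self):
        values = [0.002, 0.004, 0.006, 0.008]
        row = compare_locus("L", values, values, StatsConfig(n_tests=1))
        assert row.log2_fold_change == pytest.approx(0.0)
        assert row.d_statistic == 0.0

    def test_all_zero_locus_gives_sentinel(self):
        row = compare_locus("L", [0.0, 0.0, 0.0], [0.01, 0.02, 0.03], StatsConfig())
        assert row.fold_change == 0.0
        assert row.log2_fold_change == float("-inf")

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            compare_locus("L", [0.01, 0.02], [0.0, 0.0, 0.0], StatsConfig())

    def test_scale_equivariance(self, rng):
        """Multiplying every LoP by c > 0 leaves D, p and log2FC unchanged."""
        locus = rng.uniform(0.001, 0.02, size=10)
        ref = rng.uniform(0.001, 0.02, size=10)
        base = compare_locus("L", locus, ref, StatsConfig(n_tests=5))
        for c in (0.1, 3.0, 1e4):
            scaled = compare_locus("L", locus * c, ref * c, StatsConfig(n_tests=5))
            assert scaled.d_statistic == pytest.approx(base.d_statistic)
            assert scaled.p_value == pytest.approx(base.p_value)
            assert scaled.log2_fold_change == pytest.approx(base.log2_fold_change)


class TestBonferroni:
    def test_ninety_nine_tests(self):
        threshold = bonferroni_threshold(StatsConfig(alpha=0.05, n_tests=99))
        assert threshold == pytest.approx(0.05 / 99)
        assert -math.log10(threshold) == pytest.approx(3.297, abs=5e-4)

    @pytest.mark.parametrize("m,expected", [(1, 0.05), (2, 0.025)])
    def test_small_m(self, m, expected):
        assert bonferroni_threshold(StatsConfig(alpha=0.05, n_tests=m)) == pytest.approx(expected)


def enumeration_hypergeom_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_worked_example(self):
        # N=10, K=5, n=4, k=4: C(5,4)/C(10,4) = 5/210
        p = hypergeometric_enrichment({f"l{i}": i < 5 for i in range(10)},
                                      [f"l{i}" for i in range(4)], True)
        assert p == pytest.approx(5 / 210)

    def test_k_zero_gives_one(self):
        universe = {f"l{i}": i < 3 for i in range(8)}
        # subset holds no member at the level: P(X >= 0) = 1
        assert hypergeometric_enrichment(universe, ["l5"], True) == pytest.approx(1.0)

    def test_subset_equals_universe(self):
        universe = {f"l{i}": i % 2 == 0 for i in range(6)}
        assert hypergeometric_enrichment(universe, universe, True) == pytest.approx(1.0)

    def test_subset_outside_universe_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"a": 1}, ["b"], 1)

    def test_matches_enumeration(self, rng):
        for _ in range(30):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"l{i}": i < K for i in range(N)}
            subset = [f"l{i}" for i in rng.choice(N, size=n, replace=False)]
            k = sum(1 for s in subset if universe[s])
            expected = enumeration_hypergeom_tail(N, K, n, k)
            assert hypergeometric_enrichment(universe, subset, True) == pytest.approx(expected)


class TestEnrichmentReport:
    def _loci(self):
        return [
            NirvsLocus("a", "c", 0, 400, viral_family="Flavivirus", viral_orf="NS5", context="exon"),
            NirvsLocus("b", "c", 500, 1001, viral_family="Rhabdovirus", viral_orf="RdRP", context="exon"),
            NirvsLocus("d", "c", 1100, 1600, viral_family="Rhabdovirus",
                       viral_orf="nucleocapsid", context="piRNA_cluster"),
            NirvsLocus("e", "c", 1700, 1900, viral_family="Flavivirus", viral_orf="NS5",
                       context="intergenic"),
        ]

    def test_length_partition_covers_all_loci(self):
        loci = self._loci()
        levels = [locus_attribute(l, "length") for l in loci]
        assert set(levels) <= {"short", "long"}
        # exactly 500 bp counts as short
        assert locus_attribute(loci[2], "length") == "short"
        assert locus_attribute(loci[1], "length") == "long"

    def test_report_counts_sum(self):
        loci = self._loci()
        report = enrichment_report(loci, ["b", "d"])
        for attr, sub in report.groupby("attribute"):
            assert sub["K"].sum() == len(loci)
            assert sub["k"].sum() == 2
        assert ((report["p_value"] >= 0) & (report["p_value"] <= 1)).all()


def test_volcano_table_roundtrip():
    rng = np.random.default_rng(7)
    index = [f"sg{i}" for i in range(5)] + [f"L{i}" for i in range(4)]
    table = pd.DataFrame(rng.uniform(0.001, 0.02, size=(9, 6)), index=index,
                         columns=[f"S{i}" for i in range(6)])
    out = volcano_table(table, [f"sg{i}" for i in range(5)])
    assert list(out.index) == [f"L{i}" for i in range(4)]
    assert set(out.columns) >= {"log2_fold_change", "neg_log10_p", "significant"}
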