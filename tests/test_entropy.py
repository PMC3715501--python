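"""Unit tests for contingency tables and entropy statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rigscan import GenotypeDataset
from rigscan.entropy import (
    ContingencyTable,
    build_contingency_table,
    conditional_entropy,
    decode_joint_genotype,
    encode_joint_genotype,
    g_statistic,
    relative_information_gain,
    scan_combinations,
    shannon_entropy,
)
from rigscan.exceptions import (
    CombinationLimitError,
    DegenerateDistributionError,
    EmptyDataError,
    InvalidGenotypeError,
    SingleClassError,
)

from conftest import naive_scan, random_dataset


class TestJointGenotypeEncoding:
    @pytest.mark.parametrize(
        "codes,index", [((0,), 0), ((2, 1), 7), ((1, 0, 2), 11), ((2, 2), 8)]
    )
    def test_mixed_radix_convention(self, codes, index):
        assert encode_joint_genotype(codes) == index

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_roundtrip_bijective(self, k):
        seen = set()
        for codes in itertools.product((0, 1, 2), repeat=k):
            idx = encode_joint_genotype(codes)
            assert decode_joint_genotype(idx, k) == codes
            seen.add(idx)
        assert seen == set(range(3**k))

    def test_invalid_code_rejected(self):
        with pytest.raises(InvalidGenotypeError):
            encode_joint_genotype((0, 3))


class TestContingencyTable:
    def test_hand_tallied_counts(self, toy6):
        table = build_contingency_table(toy6, (0, 1))
        expected = np.zeros((9, 2), dtype=int)
        expected[0] = (1, 0)  # (0,0): one case
        expected[1] = (1, 0)  # (0,1): one case
        expected[4] = (1, 1)  # (1,1): one case, one control
        expected[6] = (1, 1)  # (2,0): one case, one control
        np.testing.assert_array_equal(table.counts, expected)
        assert table.n_total == 6

    def test_column_sums_conserved(self, toy6):
        table = build_contingency_table(toy6, (1, 0))
        assert table.counts[:, 0].sum() == toy6.n_cases
        assert table.counts[:, 1].sum() == toy6.n_controls

    def test_constant_genotypes_fill_row_zero(self):
        ds = GenotypeDataset(
            genotypes=np.zeros((10, 2), dtype=np.int8),
            phenotype=np.array([1] * 5 + [0] * 5, dtype=np.int8),
        )
        table = build_contingency_table(ds, (0, 1))
        assert table.counts[0].tolist() == [5, 5]
        assert table.counts[1:].sum() == 0

    def test_missing_excluded_per_combination(self, toy6):
        g = toy6.genotypes.copy()
        g[0, 1] = -1  # missing second SNP for sample 0
        ds = toy6.with_phenotype(toy6.phenotype)
        ds.genotypes = g
        pair = build_contingency_table(ds, (0, 1))
        assert pair.n_total == 5
        single = build_contingency_table(ds, (0,))
        assert single.n_total == 6  # SNP 0 fully observed

    def test_all_missing_raises(self):
        ds = GenotypeDataset(
            genotypes=np.full((4, 1), -1, dtype=np.int8),
            phenotype=np.array([1, 0, 1, 0], dtype=np.int8),
        )
        with pytest.raises(EmptyDataError):
            build_contingency_table(ds, (0,))

    def test_duplicate_indices_rejected(self, toy6):
        with pytest.raises(ValueError):
            build_contingency_table(toy6, (0, 0))


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((50, 50), 1.0),
            ((100, 0), 0.0),
            ((75, 25), 0.8112781244591328),  # -(3/4)log2(3/4)-(1/4)log2(1/4)
            ((1, 1, 1, 1), 2.0),
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon_entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateDistributionError):
            shannon_entropy((0, 0, 0))


class TestConditionalEntropy:
    def _table(self, rows):
        counts = np.zeros((3, 2), dtype=int)
        counts[: len(rows)] = rows
        return ContingencyTable((0,), counts)

    def test_uniform_rows_give_one_bit(self):
        assert conditional_entropy(self._table([(30, 30), (20, 20)])) == pytest.approx(1.0)

    def test_deterministic_rows_give_zero(self):
        assert conditional_entropy(self._table([(40, 0), (0, 60)])) == pytest.approx(0.0)

    def test_weighted_row_entropies(self):
        # both rows carry H2(0.75) = 0.81128 bits, equal weights
        val = conditional_entropy(self._table([(30, 10), (10, 30)]))
        assert val == pytest.approx(0.8112781244591328, abs=1e-12)

    def test_empty_rows_contribute_nothing(self):
        a = conditional_entropy(self._table([(30, 10), (10, 30)]))
        counts = np.zeros((9, 2), dtype=int)
        counts[2] = (30, 10)
        counts[7] = (10, 30)
        b = conditional_entropy(ContingencyTable((0, 1), counts))
        assert a == pytest.approx(b, abs=1e-15)


class TestRelativeInformationGain:
    def _table(self, rows, k=1):
        counts = np.zeros((3**k, 2), dtype=int)
        counts[: len(rows)] = rows
        return ContingencyTable(tuple(range(k)), counts)

    def test_frozen_example(self):
        r = relative_information_gain(self._table([(30, 10), (10, 30)]))
        assert r.h_y == pytest.approx(1.0)
        assert r.ig == pytest.approx(0.18872187554086717, abs=1e-12)
        assert r.r0 == pytest.approx(0.18872187554086717, abs=1e-12)

    def test_proportional_rows_zero(self):
        r = relative_information_gain(self._table([(30, 20), (60, 40), (15, 10)]))
        assert r.r0 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_determination_one(self):
        r = relative_information_gain(self._table([(40, 0), (0, 60)]))
        assert r.r0 == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            relative_information_gain(self._table([(40, 0), (20, 0)]))


class TestGStatistic:
    def test_proportional_table_zero(self):
        counts = np.array([[30, 20], [60, 40], [15, 10]])
        g = g_statistic(ContingencyTable((0,), counts))
        assert g.g2 == pytest.approx(0.0, abs=1e-9)
        assert g.df == 2

    def test_matches_scipy_log_likelihood(self, rng=np.random.default_rng(5)):
        """Independent oracle: scipy's G-test on the same tables."""
        for _ in range(50):
            counts = rng.integers(1, 30, size=(9, 2))
            table = ContingencyTable((0, 1), counts)
            ours = g_statistic(table)
            ref = stats.chi2_contingency(
                counts, lambda_="log-likelihood", correction=False
            )
            assert ours.g2 == pytest.approx(ref.statistic, abs=1e-9)

    def test_identity_with_information_gain(self, rng=np.random.default_rng(6)):
        for _ in range(200):
            counts = rng.integers(0, 25, size=(9, 2))
            if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
                continue
            table = ContingencyTable((0, 1), counts)
            g = g_statistic(table)
            r = relative_information_gain(table)
            n = table.n_total
            assert abs(g.g2 - 2 * n * math.log(2) * r.ig) < 1e-9

    def test_null_distribution_is_chi_square(self):
        """Under independence (k=1, n=10000) G2 follows chi-square df=2."""
        rng = np.random.default_rng(12)
        n = 10_000
        sims = []
        for _ in range(400):
            g = rng.binomial(2, 0.3, size=n)
            y = rng.integers(0, 2, size=n)
            counts = np.zeros((3, 2), dtype=int)
            np.add.at(counts, (g, 1 - y), 1)
            sims.append(g_statistic(ContingencyTable((0,), counts)).g2)
        p = stats.ks_1samp(sims, stats.chi2(df=2).cdf).pvalue
        assert p > 0.01

    def test_sparse_table_flagged(self):
        counts = np.zeros((9, 2), dtype=int)
        counts[0] = (10, 12)
        counts[4] = (3, 1)
        g = g_statistic(ContingencyTable((0, 1), counts))
        assert g.n_nonempty_rows == 2
        assert g.df == 8


class TestScan:
    def test_combination_count(self, xor_dataset):
        results = scan_combinations(xor_dataset, 2)
        assert len(results) == math.comb(4, 2)

    def test_xor_pair_is_perfectly_informative(self, xor_dataset):
        results = scan_combinations(xor_dataset, 2)
        assert results[0].snp_indices == (0, 1)
        assert results[0].r0 == pytest.approx(1.0)

    def test_matches_naive_per_table_scan(self):
        ds = random_dataset(p=8, n=120, seed=3)
        fast = scan_combinations(ds, 2)
        slow = naive_scan(ds, 2)
        assert [r.snp_indices for r in fast] == [r.snp_indices for r in slow]
        np.testing.assert_allclose(
            [r.r0 for r in fast], [r.r0 for r in slow], atol=1e-12
        )

    def test_matches_naive_with_missing_data(self):
        ds = random_dataset(p=6, n=100, seed=4)
        g = ds.genotypes.copy()
        mask = np.random.default_rng(8).random(g.shape) < 0.05
        g[mask] = -1
        ds.genotypes = g
        fast = scan_combinations(ds, 2)
        slow = naive_scan(ds, 2)
        assert [r.snp_indices for r in fast] == [r.snp_indices for r in slow]
        np.testing.assert_allclose(
            [r.r0 for r in fast], [r.r0 for r in slow], atol=1e-12
        )

    def test_order_out_of_range(self, xor_dataset):
        with pytest.raises(ValueError):
            scan_combinations(xor_dataset, 0)
        with pytest.raises(ValueError):
            scan_combinations(xor_dataset, 5)

    def test_safety_limit_names_count(self):
        ds = random_dataset(p=10, n=40, seed=1)
        with pytest.raises(CombinationLimitError, match="120"):
            scan_combinations(ds, 3, max_combinations=100)

    def test_top_n_truncates(self, xor_dataset):
        assert len(scan_combinations(xor_dataset, 2, top_n=3)) == 3
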