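"""Correlation, difference-adjacency and dissimilarity computations,
checked against hand calculations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffcoex import (
    ExpressionDataset,
    compute_correlations,
    difference_adjacency,
    difference_adjacency_multi,
    difference_adjacency_strict,
    no_tom_dissimilarity,
    signed_square,
    tom_dissimilarity,
)
from diffcoex.network import CorrelationSet, DifferenceAdjacency

from conftest import make_dataset, pair_correlation_set, random_correlation_set


# ---------------------------------------------------------------------------
# correlations


class TestComputeCorrelations:
    def test_duplicated_gene_has_unit_correlation(self):
        data = make_dataset(n_genes=4, seed=3)
        values = data.values.copy()
        values.loc["g_dup"] = values.loc["g0"]
        dup = ExpressionDataset(values, data.conditions)
        cors = compute_correlations(dup, method="pearson")
        i = dup.gene_ids.get_loc("g0")
        j = dup.gene_ids.get_loc("g_dup")
        for k in cors.conditions:
            assert cors.matrix(k)[i, j] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_symmetric_unit_diagonal_bounded(self, small_dataset, method):
        cors = compute_correlations(small_dataset, method=method)
        assert cors.conditions == small_dataset.condition_labels
        for k in cors.conditions:
            m = cors.matrix(k)
            np.testing.assert_allclose(m, m.T)
            np.testing.assert_allclose(np.diag(m), 1.0)
            assert np.abs(m).max() <= 1.0

    def test_pearson_matches_textbook_formula(self):
        # independent oracle: covariance / (std_i std_j), computed longhand
        data = make_dataset(n_genes=4, samples=(6, 6), seed=11)
        cors = compute_correlations(data, method="pearson")
        for k in data.condition_labels:
            x = data.values[data.samples_of(k)].to_numpy()
            p = x.shape[0]
            expected = np.eye(p)
            for i in range(p):
                for j in range(p):
                    xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                    expected[i, j] = (xi * xj).sum() / np.sqrt(
                        (xi**2).sum() * (xj**2).sum()
                    )
            np.testing.assert_allclose(cors.matrix(k), expected, atol=1e-12)

    def test_spearman_is_pearson_on_ranks(self, small_dataset):
        from scipy.stats import rankdata

        ranked = ExpressionDataset(
            pd.DataFrame(
                np.column_stack(
                    [
                        rankdata(
                            small_dataset.values[small_dataset.samples_of(k)], axis=1
                        )
                        for k in small_dataset.condition_labels
                    ]
                ),
                index=small_dataset.gene_ids,
                columns=small_dataset.sample_ids,
            ),
            small_dataset.conditions,
        )
        sp = compute_correlations(small_dataset, method="spearman")
        pe = compute_correlations(ranked, method="pearson")
        for k in sp.conditions:
            np.testing.assert_allclose(sp.matrix(k), pe.matrix(k), atol=1e-12)

    def test_zero_variance_gene_rejected_with_name(self, small_dataset):
        values = small_dataset.values.copy()
        values.loc["g2", small_dataset.samples_of("c1")] = 5.0
        flat = ExpressionDataset(values, small_dataset.conditions)
        with pytest.raises(ValueError, match="g2"):
            compute_correlations(flat)

    def test_zero_variance_gene_droppable(self, small_dataset):
        values = small_dataset.values.copy()
        values.loc["g2", small_dataset.samples_of("c1")] = 5.0
        flat = ExpressionDataset(values, small_dataset.conditions)
        with pytest.warns(UserWarning, match="g2"):
            cors = compute_correlations(flat, drop_zero_variance=True)
        assert "g2" not in cors.genes

    def test_non_finite_values_rejected_with_location(self, small_dataset):
        values = small_dataset.values.copy()
        values.iloc[1, 2] = np.nan
        with pytest.raises(ValueError, match="g1"):
            ExpressionDataset(values, small_dataset.conditions)

    def test_condition_with_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            make_dataset(samples=(6, 2))


# ---------------------------------------------------------------------------
# signed square / difference adjacency


@pytest.mark.parametrize(
    "c,expected", [(0.0, 0.0), (-0.5, -0.25), (1.0, 1.0), (-1.0, -1.0), (0.3, 0.09)]
)
def test_signed_square_values(c, expected):
    assert signed_square(c) == pytest.approx(expected, abs=1e-15)


@given(st.floats(-1, 1))
@settings(deadline=None, max_examples=50)
def test_signed_square_is_odd_and_contracting(c):
    s = signed_square(c)
    assert signed_square(-c) == pytest.approx(-s, abs=1e-15)
    assert abs(s) <= abs(c) + 1e-15
    # sign is preserved unless c² underflows to zero
    assert s == 0.0 or np.sign(s) == np.sign(c)


class TestDifferenceAdjacency:
    def test_maximal_change(self):
        d = difference_adjacency(pair_correlation_set(1.0, -1.0), beta=1)
        assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("beta", [1, 2, 6])
    def test_no_change_gives_zero(self, beta):
        d = difference_adjacency(pair_correlation_set(0.7, 0.7), beta=beta)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_entry(self):
        # (1/2 |0.9² − 0.1²|)² = (0.4)² = 0.16
        d = difference_adjacency(pair_correlation_set(0.9, 0.1), beta=2)
        assert d.values[0, 1] == pytest.approx(0.16, abs=1e-12)

    def test_requires_two_conditions(self):
        with pytest.raises(ValueError, match="exactly 2"):
            difference_adjacency(random_correlation_set(n_conditions=3), beta=1)
        with pytest.raises(ValueError):
            difference_adjacency(random_correlation_set(n_conditions=3), beta=1)

    @pytest.mark.parametrize("beta", [0, -1, 1.5])
    def test_invalid_beta_rejected(self, beta):
        with pytest.raises(ValueError, match="beta"):
            difference_adjacency(pair_correlation_set(0.5, 0.1), beta=beta)

    def test_monotone_in_prethreshold_change(self):
        # larger |s1 - s2| never decreases d, for fixed beta
        changes = [0.0, 0.1, 0.3, 0.8, 1.0]
        vals = [
            difference_adjacency(pair_correlation_set(np.sqrt(x), 0.0), beta=3).values[
                0, 1
            ]
            for x in changes
        ]
        assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))


class TestMultiCondition:
    def test_reduces_to_two_condition_form(self):
        for seed in range(100):
            cors = random_correlation_set(p=5, n_conditions=2, seed=seed)
            for beta in (1, 2, 6):
                d2 = difference_adjacency(cors, beta=beta).values
                dm = difference_adjacency_multi(cors, beta=beta).values
                assert np.abs(d2 - dm).max() < 1e-12

    def test_identical_conditions_give_zero(self):
        cors = random_correlation_set(p=5, n_conditions=1, seed=4)
        m = cors.matrix("c1")
        three = CorrelationSet(cors.genes, {"a": m, "b": m.copy(), "c": m.copy()}, "pearson")
        d = difference_adjacency_multi(three, beta=2)
        assert np.abs(d.values).max() == pytest.approx(0.0, abs=1e-15)

    def test_three_condition_hand_value(self):
        # signed-squared values (1, 0, -1): consensus 0,
        # d = sqrt((1/(2*2)) * (1 + 0 + 1)) = sqrt(0.5)
        genes = pd.Index(["g0", "g1"])
        mats = {
            "a": np.array([[1.0, 1.0], [1.0, 1.0]]),
            "b": np.array([[1.0, 0.0], [0.0, 1.0]]),
            "c": np.array([[1.0, -1.0], [-1.0, 1.0]]),
        }
        d = difference_adjacency_multi(CorrelationSet(genes, mats, "pearson"), beta=1)
        assert d.values[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            difference_adjacency_multi(random_correlation_set(n_conditions=1), beta=1)


class TestStrictVariant:
    def test_maximal_change_any_beta(self):
        for beta in (1, 2, 5):
            d = difference_adjacency_strict(pair_correlation_set(1.0, -1.0), beta=beta)
            assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_beta2_equals_standard_beta1(self):
        for seed in range(20):
            cors = random_correlation_set(p=6, seed=seed)
            strict = difference_adjacency_strict(cors, beta=2).values
            std = difference_adjacency(cors, beta=1).values
            np.testing.assert_allclose(strict, std, atol=1e-14)

    def test_hand_computed_entry(self):
        # 1/2 |0.9^4 − 0.3^4| = 1/2 |0.6561 − 0.0081| = 0.324
        d = difference_adjacency_strict(pair_correlation_set(0.9, 0.3), beta=4)
        assert d.values[0, 1] == pytest.approx(0.324, abs=1e-12)


# ---------------------------------------------------------------------------
# dissimilarities


def brute_force_tom(d: np.ndarray) -> np.ndarray:
    """Naive triple-loop topological-overlap dissimilarity oracle."""
    p = d.shape[0]
    t = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            num = sum(d[i, k] * d[k, j] for k in range(p) if k not in (i, j))
            ki = sum(d[i, k] for k in range(p) if k != i)
            kj = sum(d[j, k] for k in range(p) if k != j)
            t[i, j] = 1.0 - (num + d[i, j]) / (min(ki, kj) + 1.0 - d[i, j])
    return t


def random_adjacency(p, seed):
    rng = np.random.default_rng(seed)
    d = rng.uniform(0, 1, (p, p))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DifferenceAdjacency(pd.Index([f"g{i}" for i in range(p)]), d, 1)


class TestTomDissimilarity:
    def test_empty_network_is_maximally_dissimilar(self):
        D = DifferenceAdjacency(pd.Index(list("abc")), np.zeros((3, 3)), 1)
        t = tom_dissimilarity(D).values
        off = t[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)
        np.testing.assert_allclose(np.diag(t), 0.0)

    def test_complete_network_is_maximally_similar(self):
        # all off-diagonal d = 1: t_12 = 1 - (1 + 1)/(min(2,2) + 1 - 1) = 0
        d = np.ones((3, 3)) - np.eye(3)
        D = DifferenceAdjacency(pd.Index(list("abc")), d, 1)
        np.testing.assert_allclose(tom_dissimilarity(D).values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("p,seed", [(5, 0), (20, 1), (30, 2)])
    def test_matches_bruteforce_oracle(self, p, seed):
        D = random_adjacency(p, seed)
        t = tom_dissimilarity(D).values
        assert np.abs(t - brute_force_tom(D.values)).max() < 1e-10

    def test_bounded_and_symmetric(self):
        t = tom_dissimilarity(random_adjacency(15, 7)).values
        assert t.min() >= 0.0 and t.max() <= 1.0
        np.testing.assert_allclose(t, t.T)


class TestNoTomDissimilarity:
    def test_complement(self):
        D = random_adjacency(6, 3)
        t = no_tom_dissimilarity(D).values
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(t[off], 1.0 - D.values[off], atol=1e-15)
        np.testing.assert_allclose(np.diag(t), 0.0)


# ---------------------------------------------------------------------------
# invariants


@given(st.integers(0, 10_000), st.integers(1, 12))
@settings(deadline=None, max_examples=60)
def test_adjacency_and_dissimilarity_bounded(seed, beta):
    cors = random_correlation_set(p=5, seed=seed)
    for build in (difference_adjacency, difference_adjacency_strict):
        d = build(cors, beta=beta)
        assert d.values.min() >= 0.0 and d.values.max() <= 1.0
        assert np.all(np.diag(d.values) == 0.0)
        for diss in (tom_dissimilarity, no_tom_dissimilarity):
            t = diss(d)
            assert t.values.min() >= 0.0 and t.values.max() <= 1.0
            assert np.all(np.diag(t.values) == 0.0)


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=25)
def test_larger_beta_never_increases_adjacency(seed):
    cors = random_correlation_set(p=6, seed=seed)
    prev = difference_adjacency(cors, beta=1).values
    for beta in range(2, 13):
        cur = difference_adjacency(cors, beta=beta).values
        assert np.all(cur <= prev + 1e-15)
        prev = cur


def test_gene_permutation_equivariance():
    data = make_dataset(n_genes=7, seed=5)
    perm = np.random.default_rng(0).permutation(data.n_genes)
    shuffled = ExpressionDataset(data.values.iloc[perm], data.conditions)

    for ds, tag in ((data, "orig"), (shuffled, "perm")):
        cors = compute_correlations(ds, method="pearson")
        D = difference_adjacency(cors, beta=2)
        T = tom_dissimilarity(D)
        if tag == "orig":
            base_c, base_d, base_t = cors, D, T
    ix = np.ix_(perm, perm)
    for k in base_c.conditions:
        np.testing.assert_allclose(cors.matrix(k), base_c.matrix(k)[ix], atol=1e-12)
    np.testing.assert_allclose(D.values, base_d.values[ix], atol=1e-12)
    np.testing.assert_allclose(T.values, base_t.values[ix], atol=1e-12)
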