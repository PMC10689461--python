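import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from bileflow.differential import (
    classify_volcano,
    mann_whitney,
    permutation_fdr,
    student_t_per_protein,
)
from bileflow.io_model import BileflowError, IntensityMatrix
from conftest import random_log2_matrix


def _matrix(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"s{j}" for j in range(arr.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=cols),
        scale="log2",
    )


def _labels(matrix, n_a):
    return pd.Series(
        ["A"] * n_a + ["B"] * (len(matrix.sample_ids) - n_a), index=matrix.sample_ids
    )


def oracle_t(a, b):
    """Textbook pooled-variance two-sample t, written independently."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (m2 - m1) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), n1 + n2 - 2)


class TestStudentT:
    def test_identical_groups_give_t0_p1(self):
        m = _matrix([[1.0, 2.0, 1.0, 2.0]])
        tab = student_t_per_protein(m, _labels(m, 2))
        assert tab["t"].iloc[0] == 0 and tab["p"].iloc[0] == 1

    def test_separated_groups_give_large_t(self):
        m = _matrix([[0.0, 0.001, 1.0, 1.001]])
        tab = student_t_per_protein(m, _labels(m, 2))
        assert abs(tab["t"].iloc[0]) > 100 and tab["p"].iloc[0] < 1e-3

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(20, 1, (20, 10)))
        tab = student_t_per_protein(m, _labels(m, 5))
        for i in range(20):
            row = m.values[i]
            t_ref, p_ref = oracle_t(row[:5], row[5:])
            assert tab["t"].iloc[i] == pytest.approx(t_ref, abs=1e-10)
            assert tab["p"].iloc[i] == pytest.approx(p_ref, abs=1e-10)
            assert tab["log2fc"].iloc[i] == pytest.approx(
                row[5:].mean() - row[:5].mean(), abs=1e-12
            )

    def test_zero_variance_row_flagged(self):
        m = _matrix([[1.0, 1.0, 1.0, 1.0]])
        tab = student_t_per_protein(m, _labels(m, 2))
        assert tab["degenerate"].iloc[0] and tab["p"].iloc[0] == 1


def oracle_permutation_q(X, n_a):
    """Independent brute-force SAM q over all label splits (naive loops)."""
    n = X.shape[1]

    def tstat(cols_a):
        out = []
        for row in X:
            a = [row[j] for j in cols_a]
            b = [row[j] for j in range(n) if j not in cols_a]
            out.append(abs(oracle_t(a, b)[0]))
        return out

    obs = tstat(set(range(n_a)))
    null = [tstat(set(c)) for c in combinations(range(n), n_a)]
    qs = []
    for ti in obs:
        r = sum(1 for tj in obs if tj >= ti)
        e = sum(sum(1 for tj in perm if tj >= ti) for perm in null) / len(null)
        qs.append(min(1.0, e / r))
    # monotone non-increasing in |t|
    order = sorted(range(len(obs)), key=lambda i: -obs[i])
    running = 0.0
    out = [0.0] * len(obs)
    for i in order:
        running = max(running, qs[i])
        out[i] = running
    return np.array(out), np.array(obs)


class TestPermutationFDR:
    def test_exhaustive_enumeration_matches_brute_force_exactly(self):
        """3v3 with 20 distinct splits: module q == naive enumeration q."""
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (50, 6))
        X[:5, 3:] += 2.5  # a few real effects
        m = _matrix(X)
        q = permutation_fdr(m, _labels(m, 3), n_perm=250, seed=0)
        q_ref, _ = oracle_permutation_q(X, 3)
        assert np.allclose(q.to_numpy(), q_ref, atol=1e-12)

    def test_null_matrix_saturates_q(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(0, 1, (200, 12)))
        q = permutation_fdr(m, _labels(m, 6), n_perm=100, seed=3)
        assert np.median(q) > 0.8

    def test_planted_extreme_markers_take_minimum_q(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (100, 10))
        X[:3, 5:] += 50  # perfectly separated markers
        m = _matrix(X)
        q = permutation_fdr(m, _labels(m, 5), n_perm=100, seed=4)
        assert (q.iloc[:3] <= q.min() + 1e-15).all()

    def test_q_monotone_nonincreasing_in_abs_t(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(0, 1, (80, 10)))
        labels = _labels(m, 5)
        tab = student_t_per_protein(m, labels)
        q = permutation_fdr(m, labels, n_perm=50, seed=5)
        order = np.argsort(-tab["t"].abs().to_numpy())
        assert (np.diff(q.to_numpy()[order]) >= -1e-15).all()

    def test_single_class_labels_rejected(self):
        m = _matrix(np.ones((3, 4)))
        with pytest.raises(BileflowError):
            permutation_fdr(m, pd.Series("A", index=m.sample_ids), 10, 0)


class TestVolcano:
    @pytest.mark.parametrize(
        "lfc,p,q,expected",
        [
            (2.0, 0.01, 0.01, "up"),
            (1.0, 0.01, 0.01, "ns"),  # strict "more than 2-fold"
            (-3.0, 0.2, 0.5, "ns"),
            (-1.5, 0.01, 0.04, "down"),
            (1.5, 0.05, 0.01, "ns"),  # strict p < threshold
        ],
    )
    def test_classification(self, lfc, p, q, expected):
        got = classify_volcano(np.array([lfc]), np.array([p]), np.array([q]))
        assert got.iloc[0] == expected

    def test_classes_partition_proteins(self):
        rng = np.random.default_rng(6)
        n = 500
        cls = classify_volcano(
            rng.normal(0, 2, n), rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        )
        counts = cls.value_counts()
        assert counts.sum() == n


class TestMannWhitney:
    def test_complete_separation_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/C(6,3)

    def test_identical_samples_p_near_one(self):
        u, p = mann_whitney([1, 2, 3, 4] * 4, [1, 2, 3, 4] * 4)
        assert p > 0.95

    def test_matches_monte_carlo_permutation_distribution(self):
        """8v8 asymptotic p within 0.005 of a 1e5-shuffle permutation p."""
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 1.0, 8)
        y = rng.normal(0.8, 1.0, 8)
        x[0] = y[0]  # introduce a tie to force the corrected approximation
        _, p = mann_whitney(x, y)
        pooled = np.concatenate([x, y])
        from scipy.stats import rankdata

        def ustat(perm):
            ranks = rankdata(pooled[perm])
            return abs(ranks[:8].sum() - 8 * 9 / 2 - 32)

        obs = ustat(np.arange(16))
        n_mc = 100_000
        perms = rng.permuted(np.tile(np.arange(16), (n_mc, 1)), axis=1)
        ranks = rankdata(pooled[perms], axis=1)
        null = np.abs(ranks[:, :8].sum(axis=1) - 8 * 9 / 2 - 32)
        p_mc = (null >= obs - 1e-9).mean()
        assert p == pytest.approx(p_mc, abs=0.005)
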