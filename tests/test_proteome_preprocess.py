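import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from bileflow.io_model import BileflowError, IntensityMatrix
from bileflow.proteome_preprocess import (
    ImputationSpec,
    combat_adjust,
    derive_presence_threshold,
    impute_downshifted_normal,
    log2_transform,
    presence_profile,
    timepoint_groups,
    valid_value_filter,
    zscore_rows,
)
from conftest import random_log2_matrix


def _matrix(values, scale="log2", cols=None):
    arr = np.asarray(values, dtype=float)
    cols = cols or [f"s{j}" for j in range(arr.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=cols),
        scale=scale,
    )


class TestLog2:
    def test_elementwise_and_missing_preserved(self):
        m = _matrix([[8.0, np.nan]], scale="raw")
        out = log2_transform(m)
        assert out.data.iloc[0, 0] == 3.0
        assert np.isnan(out.data.iloc[0, 1])
        assert out.scale == "log2"

    def test_double_transform_guard(self):
        with pytest.raises(BileflowError, match="raw-scale"):
            log2_transform(_matrix([[1.0]], scale="log2"))


class TestPresenceAndFilter:
    def test_fraction_and_median(self):
        m = _matrix([[1, np.nan, 2, np.nan], [1, 2, 3, 4]])
        prof = presence_profile(m, {"g": m.sample_ids})
        assert prof.overall.tolist() == [0.5, 1.0]
        assert prof.median == 0.75

    def test_fully_observed_matrix(self):
        m = _matrix(np.ones((3, 4)))
        prof = presence_profile(m, {"g": m.sample_ids})
        assert (prof.overall == 1).all() and prof.median == 1.0

    def test_median_matches_brute_force_on_mnar_cohort(self, small_cohort):
        m = small_cohort.combined_matrix
        groups = timepoint_groups(small_cohort.metadata, m.sample_ids)
        prof = presence_profile(m, groups)
        brute = np.median(
            [np.mean(~np.isnan(row)) for row in m.values]
        )
        assert prof.median == pytest.approx(brute, abs=0)

    def test_threshold_is_inclusive_per_group(self):
        # p0: fractions (0.5, 0.4) -> kept at 0.40; p1: (0.5, 0.2) -> dropped
        g1 = [[1, 2], [1, 2]]
        g2 = [[1, 1, np.nan, np.nan, 3], [1] + [np.nan] * 4]
        m = _matrix(np.hstack([g1, g2]))
        groups = {"a": m.sample_ids[:2], "b": m.sample_ids[2:]}
        kept = valid_value_filter(m, groups, 0.40)
        assert kept.protein_ids == ["p0"]

    def test_hand_counted_survivors(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(20, 1, (10, 6))
        vals[3, :4] = np.nan  # presence 1/3 overall
        vals[7, 5] = np.nan
        m = _matrix(vals)
        groups = {"a": m.sample_ids[:3], "b": m.sample_ids[3:]}
        kept = valid_value_filter(m, groups, 0.5)
        assert len(kept.protein_ids) == 9 and "p3" not in kept.protein_ids

    def test_filter_monotone_in_threshold(self, small_cohort):
        m = small_cohort.combined_matrix
        groups = timepoint_groups(small_cohort.metadata, m.sample_ids)
        counts = [
            len(valid_value_filter(m, groups, t).protein_ids)
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_derive_mode_rounds_median_down_to_5_percent(self):
        m = _matrix([[1, np.nan, 2, np.nan], [1, 2, 3, np.nan]])
        prof = presence_profile(m, {"g": m.sample_ids})  # median 0.625
        assert derive_presence_threshold(prof) == 0.60

    def test_empty_group_rejected(self, tiny_matrix):
        m = log2_transform(tiny_matrix)
        with pytest.raises(BileflowError, match="empty"):
            presence_profile(m, {"a": m.sample_ids, "b": []})


class TestImputation:
    def test_complete_matrix_unchanged(self):
        m = _matrix([[1.0, 2.0], [3.0, 4.0]])
        out = impute_downshifted_normal(m, ImputationSpec(seed=0))
        assert out.data.equals(m.data)

    def test_observed_cells_untouched_and_seed_reproducible(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(20, 1, (50, 4))
        vals[rng.uniform(size=vals.shape) < 0.3] = np.nan
        m = _matrix(vals)
        out1 = impute_downshifted_normal(m, ImputationSpec(seed=9))
        out2 = impute_downshifted_normal(m, ImputationSpec(seed=9))
        obs = ~np.isnan(vals)
        assert np.array_equal(out1.values[obs], vals[obs])
        assert np.array_equal(out1.values, out2.values)
        assert not np.isnan(out1.values).any()

    def test_moments_match_downshifted_normal(self):
        """1e5 imputed cells in a mu=20, sd=1 scope land on
        Normal(20 - 1.8, 0.3^2) within 1%."""
        rng = np.random.default_rng(3)
        n_obs, n_miss = 100_000, 100_000
        obs = rng.normal(0, 1, n_obs)
        obs = (obs - obs.mean()) / obs.std(ddof=1) + 20.0  # exact mu=20, sd=1
        col = np.concatenate([obs, np.full(n_miss, np.nan)])
        m = _matrix(col[:, None], cols=["s0"])
        out = impute_downshifted_normal(m, ImputationSpec(seed=4))
        imputed = out.values[n_obs:, 0]
        assert imputed.mean() == pytest.approx(18.2, abs=0.01)
        assert imputed.std(ddof=1) == pytest.approx(0.3, abs=0.01)

    def test_sparse_scope_rejected(self):
        m = _matrix([[1.0, np.nan], [np.nan, np.nan]])
        with pytest.raises(BileflowError, match="observed"):
            impute_downshifted_normal(m, ImputationSpec(seed=0))


def _offset_fixture(n_proteins=30, n_per_batch=5, d=1.3):
    """Two batches with a pure additive per-protein offset: every protein
    shares the within-batch sample pattern (scaled per protein), so the
    standardized batch effects are uniform across proteins."""
    pattern = np.linspace(-1.5, 1.5, n_per_batch)
    rng = np.random.default_rng(8)
    mu = rng.normal(20, 2, n_proteins)
    s = rng.uniform(0.5, 2.0, n_proteins)
    left = mu[:, None] + s[:, None] * pattern[None, :]
    right = mu[:, None] + s[:, None] * (pattern[None, :] + d)
    m = _matrix(np.hstack([left, right]))
    batches = pd.Series(
        ["A"] * n_per_batch + ["B"] * n_per_batch, index=m.sample_ids
    )
    return m, batches


class TestCombat:
    def test_single_batch_is_noop(self):
        m = random_log2_matrix(np.random.default_rng(0))
        out = combat_adjust(m, pd.Series("A", index=m.sample_ids))
        assert np.allclose(out.values, m.values)

    def test_additive_offsets_removed(self):
        m, batches = _offset_fixture()
        out = combat_adjust(m, batches)
        a = out.data.loc[:, batches == "A"].mean(axis=1)
        b = out.data.loc[:, batches == "B"].mean(axis=1)
        assert np.abs(a - b).max() < 1e-6
        # grand means preserved
        assert np.allclose(out.data.mean(axis=1), m.data.mean(axis=1))

    def test_second_application_preserves_means(self):
        """The EB estimator renormalizes residual variance on a second
        pass, but the batch-effect content is stable: per-protein batch
        means stay equal and grand means are untouched."""
        m, batches = _offset_fixture()
        once = combat_adjust(m, batches)
        twice = combat_adjust(once, batches)
        a = twice.data.loc[:, batches == "A"].mean(axis=1)
        b = twice.data.loc[:, batches == "B"].mean(axis=1)
        assert np.abs(a - b).max() < 1e-6
        assert np.allclose(twice.data.mean(axis=1), once.data.mean(axis=1))

    def test_unshrunk_variant_idempotent_on_random_data(self):
        rng = np.random.default_rng(1)
        m = random_log2_matrix(rng, n_proteins=40, n_samples=12)
        batches = pd.Series(["A"] * 6 + ["B"] * 6, index=m.sample_ids)
        once = combat_adjust(m, batches, shrink=False)
        twice = combat_adjust(once, batches, shrink=False)
        assert np.abs(once.values - twice.values).max() < 1e-6

    def test_singleton_batch_rejected(self):
        m = random_log2_matrix(np.random.default_rng(2), n_samples=5)
        batches = pd.Series(["A"] * 4 + ["B"], index=m.sample_ids)
        with pytest.raises(BileflowError, match="fewer than 2"):
            combat_adjust(m, batches)

    def test_matches_reference_implementation(self, tmp_path):
        """Cross-check the empirical-Bayes adjustment against the
        R sva::ComBat reference on a random two-batch matrix."""
        rng = np.random.default_rng(42)
        G, n1, n2 = 40, 6, 8
        X = rng.normal(20, 2, (G, n1 + n2))
        X[:, n1:] += rng.normal(0.8, 0.5, (G, 1))
        m = _matrix(X)
        batches = pd.Series(["A"] * n1 + ["B"] * n2, index=m.sample_ids)
        out = combat_adjust(m, batches)
        m.data.to_csv(tmp_path / "in.tsv", sep="\t")
        batches.to_frame("batch").to_csv(tmp_path / "batch.tsv", sep="\t")
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(sva))
            dat <- as.matrix(read.table("{tmp_path}/in.tsv", sep="\\t",
                                        header=TRUE, row.names=1))
            batch <- read.table("{tmp_path}/batch.tsv", sep="\\t",
                                header=TRUE, row.names=1)$batch
            res <- ComBat(dat=dat, batch=batch)
            write.table(res, "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE,
                        col.names=NA)
            """
        )
        subprocess.run(
            ["Rscript", "-e", rscript], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)
        assert np.abs(ref.to_numpy() - out.values).max() < 1e-6


class TestZScore:
    def test_row_values_and_convention(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        out = zscore_rows(m)
        assert np.allclose(out.values, [[-1.0, 0.0, 1.0]])  # ddof=1 SD

    def test_constant_row_becomes_zero_with_warning(self, caplog):
        m = _matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        with caplog.at_level("WARNING", logger="bileflow"):
            out = zscore_rows(m)
        assert np.all(out.values[0] == 0)
        assert "constant" in caplog.text

    def test_rows_have_zero_mean_unit_sd(self):
        m = random_log2_matrix(np.random.default_rng(7), 20, 8)
        out = zscore_rows(m)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-12
        assert np.abs(out.values.std(axis=1, ddof=1) - 1).max() < 1e-12
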