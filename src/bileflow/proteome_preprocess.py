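"""Intensity-matrix preprocessing: log2, valid-value filtering,
downshifted-normal imputation, empirical-Bayes batch correction, row
z-scoring.

The stages mirror the standard DIA proteomics workflow for matrices with
missing-not-at-random dropout: proteins are kept only when quantified in
a sufficient fraction of samples at every timepoint; remaining missing
cells are drawn from a normal distribution shifted into the low-intensity
tail of the observed distribution (width and downshift expressed in
multiples of the observed SD); batch effects are removed with the
parametric ComBat location/scale model; rows are z-scored for heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import BileflowError, CohortMetadata, IntensityMatrix, TIMEPOINTS

logger = logging.getLogger("bileflow")


# ---------------------------------------------------------------------------
# log2
# ---------------------------------------------------------------------------


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2 of a raw-scale matrix; missing cells preserved."""
    if matrix.scale != "raw":
        raise BileflowError(
            f"log2_transform expects a raw-scale matrix, got scale={matrix.scale!r} "
            "(double-transform guard)"
        )
    vals = matrix.values
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise BileflowError(
            f"nonpositive intensity at ({matrix.protein_ids[r]!r}, "
            f"{matrix.sample_ids[c]!r}); cannot log2-transform"
        )
    return IntensityMatrix(np.log2(matrix.data), scale="log2")


# ---------------------------------------------------------------------------
# Presence / valid-value filtering
# ---------------------------------------------------------------------------


@dataclass
class PresenceProfile:
    """Per-protein fraction of quantified cells, overall and per group."""

    overall: pd.Series
    per_group: pd.DataFrame
    median: float  # cohort median of the overall per-protein fractions

    @property
    def median_percent(self) -> float:
        return 100.0 * self.median


def timepoint_groups(
    meta: CohortMetadata, sample_ids: Sequence[str]
) -> dict[str, list[str]]:
    """Partition the given samples by perfusion timepoint."""
    sub = meta.samples.loc[list(sample_ids)]
    return {
        tp: list(sub.index[sub["timepoint"] == tp])
        for tp in TIMEPOINTS
        if (sub["timepoint"] == tp).any()
    }


def _check_groups(matrix: IntensityMatrix, groups: Mapping[str, Sequence[str]]) -> None:
    seen: list[str] = []
    for name, sids in groups.items():
        if len(sids) == 0:
            raise BileflowError(f"group {name!r} is empty")
        unknown = [s for s in sids if s not in matrix.data.columns]
        if unknown:
            raise BileflowError(f"group {name!r} references unknown samples {unknown}")
        seen.extend(sids)
    if len(seen) != len(set(seen)):
        raise BileflowError("groups must not overlap")
    if set(seen) != set(matrix.sample_ids):
        raise BileflowError("groups must partition the matrix samples")


def presence_profile(
    matrix: IntensityMatrix, groups: Mapping[str, Sequence[str]]
) -> PresenceProfile:
    """Fraction of non-missing cells per protein, overall and per group."""
    _check_groups(matrix, groups)
    present = matrix.data.notna()
    overall = present.mean(axis=1)
    per_group = pd.DataFrame(
        {name: present[list(sids)].mean(axis=1) for name, sids in groups.items()}
    )
    return PresenceProfile(overall, per_group, float(overall.median()))


def derive_presence_threshold(profile: PresenceProfile) -> float:
    """Round the cohort median presence down to the nearest 5%."""
    return np.floor(profile.median * 20.0) / 20.0


def valid_value_filter(
    matrix: IntensityMatrix,
    groups: Mapping[str, Sequence[str]],
    threshold: float = 0.40,
) -> IntensityMatrix:
    """Keep proteins quantified in at least ``threshold`` of the samples of
    EVERY group (boundary inclusive)."""
    if not 0 < threshold <= 1:
        raise BileflowError(f"threshold must be in (0, 1], got {threshold}")
    profile = presence_profile(matrix, groups)
    keep = (profile.per_group >= threshold).all(axis=1)
    return IntensityMatrix(matrix.data.loc[keep].copy(), matrix.scale)


# ---------------------------------------------------------------------------
# Downshifted-normal imputation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImputationSpec:
    """Parameters for missing-value imputation from a downshifted normal.

    Each missing cell is drawn from Normal(mu - downshift*sd, (width*sd)^2)
    where mu and sd are the mean and SD (ddof=1) of the observed values in
    the chosen scope (one column for ``per_sample``, everything for
    ``whole_matrix``).
    """

    width: float = 0.3
    downshift: float = 1.8
    scope: str = "per_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise BileflowError("imputation width must be > 0")
        if self.downshift < 0:
            raise BileflowError("imputation downshift must be >= 0")
        if self.scope not in ("per_sample", "whole_matrix"):
            raise BileflowError(f"unknown imputation scope {self.scope!r}")


def impute_downshifted_normal(
    matrix: IntensityMatrix, spec: ImputationSpec = ImputationSpec()
) -> IntensityMatrix:
    """Replace missing cells with draws from the downshifted normal.

    Observed cells are never altered; identical spec (incl. seed) gives
    identical output.
    """
    if matrix.scale != "log2":
        raise BileflowError("imputation expects a log2-scale matrix")
    rng = np.random.default_rng(spec.seed)
    data = matrix.data.copy()
    vals = data.to_numpy()
    if spec.scope == "whole_matrix":
        obs = vals[~np.isnan(vals)]
        if obs.size < 2:
            raise BileflowError("whole-matrix scope has < 2 observed values")
        mu, sd = obs.mean(), obs.std(ddof=1)
        mask = np.isnan(vals)
        vals[mask] = rng.normal(mu - spec.downshift * sd, spec.width * sd, mask.sum())
    else:
        for j, sid in enumerate(matrix.sample_ids):
            col = vals[:, j]
            obs = col[~np.isnan(col)]
            miss = np.isnan(col)
            if not miss.any():
                continue
            if obs.size < 2:
                raise BileflowError(
                    f"sample {sid!r} has {obs.size} observed values; "
                    "cannot estimate imputation distribution"
                )
            mu, sd = obs.mean(), obs.std(ddof=1)
            col[miss] = rng.normal(mu - spec.downshift * sd, spec.width * sd, miss.sum())
    out = pd.DataFrame(vals, index=data.index, columns=data.columns)
    return IntensityMatrix(out, scale=matrix.scale)


# ---------------------------------------------------------------------------
# ComBat batch correction (parametric empirical Bayes, Johnson et al. 2007)
# ---------------------------------------------------------------------------


def _it_solve(z_batch, g_hat, g_bar, t2, a_prior, b_prior, conv=1e-4):
    """Iterative joint posterior-mode solution for one batch's location and
    scale effects (vectors over proteins)."""
    n = z_batch.shape[1]
    g_old = g_hat.copy()
    d_old = z_batch.var(axis=1, ddof=1)
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            (np.abs(g_new - g_old) / np.abs(g_old)).max(),
            (np.abs(d_new - d_old) / np.abs(d_old)).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(
    matrix: IntensityMatrix,
    batches: Mapping[str, str] | pd.Series,
    shrink: bool = True,
) -> IntensityMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per protein the data are standardized against the batch-size-weighted
    grand mean and pooled variance; per-batch location and scale effects
    are estimated, shrunk toward their across-protein priors (normal for
    location, inverse-gamma for scale), removed, and the data
    back-transformed.  Protein-wise grand means are preserved.  A single
    batch is a no-op; a batch with fewer than 2 samples is an error.

    ``shrink=False`` disables the empirical-Bayes pooling and removes the
    plain per-protein batch effects instead; that variant equalizes
    per-protein batch means exactly and is idempotent, at the price of
    more variance in the effect estimates.
    """
    if matrix.data.isna().any().any():
        raise BileflowError("combat_adjust requires a complete (imputed) matrix")
    b = pd.Series(batches)
    missing = [s for s in matrix.sample_ids if s not in b.index]
    if missing:
        raise BileflowError(f"no batch label for samples {missing}")
    b = b.loc[matrix.sample_ids]
    levels = sorted(b.unique())
    if len(levels) == 1:
        return matrix.copy()
    counts = b.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise BileflowError(
            f"batches with fewer than 2 samples: {sorted(small.index)}"
        )
    X = matrix.values.astype(float)
    n_total = X.shape[1]
    idx = {lev: np.flatnonzero((b == lev).to_numpy()) for lev in levels}

    batch_means = np.column_stack([X[:, idx[lev]].mean(axis=1) for lev in levels])
    weights = np.array([len(idx[lev]) / n_total for lev in levels])
    grand_mean = batch_means @ weights
    fitted = np.zeros_like(X)
    for k, lev in enumerate(levels):
        fitted[:, idx[lev]] = batch_means[:, [k]]
    # EB path follows the reference divisor-N pooled variance; the plain
    # path uses the unbiased pooled divisor, which makes it idempotent
    # (for the unshrunk estimator the standardization scale cancels, so
    # this choice does not otherwise change the output)
    denom = n_total if shrink else n_total - len(levels)
    var_pooled = ((X - fitted) ** 2).sum(axis=1) / denom
    if (var_pooled <= 0).any():
        raise BileflowError("zero within-batch variance; cannot standardize")
    sd_pooled = np.sqrt(var_pooled)

    Z = (X - grand_mean[:, None]) / sd_pooled[:, None]
    Xadj = np.empty_like(Z)
    for k, lev in enumerate(levels):
        zb = Z[:, idx[lev]]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        if not shrink:
            g_star, d_star = g_hat, d_hat
        elif s2 < 1e-12 or t2 < 1e-12:
            # degenerate prior (effects identical across proteins): the
            # posterior collapses onto the plain estimates
            g_star = g_hat if t2 < 1e-12 else (
                (t2 * len(idx[lev]) * g_hat + d_hat * g_bar)
                / (t2 * len(idx[lev]) + d_hat)
            )
            d_star = d_hat
        else:
            a_prior = (2.0 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            g_star, d_star = _it_solve(zb, g_hat, g_bar, t2, a_prior, b_prior)
        Xadj[:, idx[lev]] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
    Xadj = Xadj * sd_pooled[:, None] + grand_mean[:, None]
    out = pd.DataFrame(Xadj, index=matrix.data.index, columns=matrix.data.columns)
    return IntensityMatrix(out, scale=matrix.scale)


# ---------------------------------------------------------------------------
# Row z-scoring
# ---------------------------------------------------------------------------


def zscore_rows(matrix: IntensityMatrix) -> IntensityMatrix:
    """Per-protein z-score (sample SD, ddof=1); constant rows become zero."""
    if matrix.data.isna().any().any():
        raise BileflowError("zscore_rows requires a complete matrix")
    vals = matrix.values.astype(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        logger.warning("%d constant rows z-scored to zero", int(const.sum()))
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    z[const, :] = 0.0
    out = pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns)
    return IntensityMatrix(out, scale="z")
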