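"""Tissue-transcript integration: RIN QC, median-of-ratios count
normalization, and per-gene protein-transcript regression.

Baseline liver-biopsy RNA-seq counts are filtered on RNA integrity
(RIN strictly greater than the threshold), normalized with the
median-of-ratios size-factor estimator, and related to bile protein
intensities by ordinary least squares within each BDI-stratum /
timepoint group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import BileflowError

logger = logging.getLogger("bileflow")


def rin_filter(rin: pd.Series, threshold: float = 7.0) -> list[str]:
    """Samples retained for sequencing: RIN strictly above threshold.

    Missing RIN values are excluded with a warning.
    """
    vals = rin.astype(float)
    missing = vals.index[vals.isna()]
    if len(missing):
        logger.warning("samples with missing RIN excluded: %s", list(missing))
    ok = vals.dropna()
    bad = ok[(ok < 1) | (ok > 10)]
    if len(bad):
        raise BileflowError(f"RIN values outside [1, 10]: {bad.to_dict()}")
    return list(ok.index[ok > threshold])


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each sample, the size factor is the median over genes (nonzero in
    every sample) of count / geometric-mean-across-samples.  Normalized
    counts are count / size factor.
    """
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise BileflowError("counts must be nonnegative")
    allpos = (X > 0).all(axis=1)
    if not allpos.any():
        raise BileflowError(
            "no gene has nonzero counts in every sample; consider a "
            "pseudo-reference over nonzero genes"
        )
    ref = X[allpos]
    geo = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    factors = np.median(ref / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / median_ratio_size_factors(counts)


def simple_linear_regression(x, y) -> dict[str, float]:
    """OLS of y on x: slope, intercept, R^2, two-tailed p from the
    slope's t test (equivalently the regression F test)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise BileflowError("x and y must pair up")
    if x.size < 3:
        raise BileflowError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise BileflowError("zero variance in the predictor")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(x.size),
    }


def protein_transcript_regression(
    norm_counts: pd.DataFrame,
    intensities: pd.DataFrame,
    groups: dict[str, list[str]],
    genes: list[str] | None = None,
    log10_protein: bool = True,
) -> pd.DataFrame:
    """Per-gene OLS of protein intensity on transcript count, per group.

    ``norm_counts``: genes x livers (normalized counts); ``intensities``:
    proteins x livers (log2 intensities, one column per liver for the
    timepoint under study); ``groups``: group name -> liver ids (e.g. the
    BDI strata).  The protein axis is converted to log10 of the linear
    intensity by default.  Pairs with fewer than 3 livers are skipped
    with a warning.
    """
    if genes is None:
        genes = [g for g in norm_counts.index if g in intensities.index]
    rows = []
    for group, livers in groups.items():
        livers = [l for l in livers if l in norm_counts.columns and l in intensities.columns]
        for gene in genes:
            if gene not in norm_counts.index or gene not in intensities.index:
                logger.warning("gene %r absent from counts or intensities; skipped", gene)
                continue
            x = norm_counts.loc[gene, livers].to_numpy(dtype=float)
            y = intensities.loc[gene, livers].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            if keep.sum() < 3:
                logger.warning("gene %r in group %r has n<3; skipped", gene, group)
                continue
            x, y = x[keep], y[keep]
            if log10_protein:
                # intensities arrive on log2 scale; convert to log10
                y = y * np.log10(2.0)
            if np.ptp(x) == 0:
                logger.warning("gene %r in group %r: constant predictor; skipped", gene, group)
                continue
            fit = simple_linear_regression(x, y)
            rows.append({"gene": gene, "group": group, **fit})
    return pd.DataFrame(rows)
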