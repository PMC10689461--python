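"""Two-group differential abundance with permutation-based FDR.

Per protein, a pooled-variance two-sample Student t test on the log2
matrix gives the fold change, t statistic and two-tailed p.  Multiple
testing is handled SAM-style: group labels are shuffled (or, when few
enough, all distinct label assignments are enumerated exhaustively) to
build a null distribution of |t|, and each protein's q-value is the
estimated false-discovery rate of the threshold sitting at its own |t|,
enforced monotone non-increasing in |t|.  The Mann-Whitney test used for
clinical group comparisons is exposed alongside.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import BileflowError, IntensityMatrix

logger = logging.getLogger("bileflow")


def _group_masks(labels: pd.Series, group_a: str | None, group_b: str | None):
    levels = sorted(labels.unique())
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise BileflowError(
                f"labels must have exactly two levels, got {levels}; "
                "or pass group_a/group_b explicitly"
            )
        group_a, group_b = levels
    mask_a = (labels == group_a).to_numpy()
    mask_b = (labels == group_b).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise BileflowError(f"empty group among ({group_a!r}, {group_b!r})")
    if not (mask_a | mask_b).all():
        raise BileflowError("labels contain samples outside the two groups")
    return mask_a, mask_b, group_a, group_b


def _pooled_t(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray):
    """Vectorized pooled-variance two-sample t over matrix rows.

    Returns (t, log2fc) with log2fc = mean(B) - mean(A).  Rows with zero
    pooled variance get t = NaN.
    """
    a, b = X[:, mask_a], X[:, mask_b]
    n1, n2 = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1) if n1 > 1 else np.zeros(X.shape[0])
    v2 = b.var(axis=1, ddof=1) if n2 > 1 else np.zeros(X.shape[0])
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / se
    t[se == 0] = np.nan
    return t, mb - ma


def student_t_per_protein(
    matrix: IntensityMatrix,
    labels: pd.Series,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Pooled-variance Student t per protein.

    Returns a DataFrame with ``log2fc`` (mean of ``group_b`` minus mean of
    ``group_a``), ``t``, two-tailed ``p`` (df = n1+n2-2) and a
    ``degenerate`` flag for zero-pooled-variance rows (p set to 1).
    """
    if matrix.data.isna().any().any():
        raise BileflowError("differential testing requires a complete matrix")
    labels = labels.loc[matrix.sample_ids]
    mask_a, mask_b, group_a, group_b = _group_masks(labels, group_a, group_b)
    n1, n2 = int(mask_a.sum()), int(mask_b.sum())
    if n1 < 2 or n2 < 2:
        raise BileflowError("each group needs at least 2 samples")
    t, lfc = _pooled_t(matrix.values, mask_a, mask_b)
    df = n1 + n2 - 2
    degenerate = np.isnan(t)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(np.where(degenerate, 0, t)), df))
    return pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p, "degenerate": degenerate},
        index=matrix.data.index,
    )


def _distinct_assignments(n: int, n1: int) -> int:
    return math.comb(n, n1)


def permutation_fdr(
    matrix: IntensityMatrix,
    labels: pd.Series,
    n_perm: int = 250,
    seed: int = 0,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.Series:
    """SAM-style permutation q-values on |t|.

    For each observed |t|_i, q_i = min(1, E_i / R_i) where R_i is the
    number of observed |t| >= |t|_i and E_i is the mean (over label
    permutations) number of null |t| >= |t|_i; q is then enforced
    monotone non-increasing in |t|.  When the number of distinct label
    assignments C(n, n1) does not exceed ``n_perm``, all assignments are
    enumerated instead of sampled.
    """
    if n_perm < 1:
        raise BileflowError("n_perm must be >= 1")
    if matrix.data.isna().any().any():
        raise BileflowError("permutation FDR requires a complete matrix")
    labels = labels.loc[matrix.sample_ids]
    mask_a, mask_b, *_ = _group_masks(labels, group_a, group_b)
    X = matrix.values
    n = X.shape[1]
    n1 = int(mask_a.sum())
    t_obs, _ = _pooled_t(X, mask_a, mask_b)
    abs_obs = np.abs(np.where(np.isnan(t_obs), 0.0, t_obs))

    null_stats = []
    if _distinct_assignments(n, n1) <= n_perm:
        perms = list(combinations(range(n), n1))
    else:
        # the observed labeling is always part of the sampled null so the
        # tail counts can never be underestimated to zero
        rng = np.random.default_rng(seed)
        perms = [tuple(np.flatnonzero(mask_a))] + [
            tuple(rng.permutation(n)[:n1]) for _ in range(n_perm - 1)
        ]
    for comb in perms:
        pa = np.zeros(n, dtype=bool)
        pa[list(comb)] = True
        t_null, _ = _pooled_t(X, pa, ~pa)
        null_stats.append(np.abs(np.where(np.isnan(t_null), 0.0, t_null)))
    n_used = len(perms)
    null_flat = np.sort(np.concatenate(null_stats))

    # R_i: observed |t| >= |t|_i; E_i: mean over permutations of null |t| >= |t|_i
    asc = np.sort(abs_obs)
    r = len(abs_obs) - np.searchsorted(asc, abs_obs, side="left")
    e = (len(null_flat) - np.searchsorted(null_flat, abs_obs, side="left")) / n_used
    q_raw = np.minimum(1.0, e / r)
    # monotone non-increasing in |t|: running max walking down the sorted order
    order = np.argsort(-abs_obs, kind="stable")
    q_sorted = np.maximum.accumulate(q_raw[order])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pd.Series(q, index=matrix.data.index, name="q")


def classify_volcano(
    log2fc: pd.Series | np.ndarray,
    p: pd.Series | np.ndarray,
    q: pd.Series | np.ndarray | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.Series:
    """Classify proteins as up / down / ns.

    ``up`` requires log2fc strictly above log2(fc_threshold) ("more than
    2-fold") and p strictly below p_threshold; when q-values are given
    they must additionally be <= q_threshold.  ``down`` is symmetric.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise BileflowError("thresholds must be positive")
    lfc = np.asarray(log2fc, dtype=float)
    pv = np.asarray(p, dtype=float)
    ok = pv < p_threshold
    if q is not None:
        ok &= np.asarray(q, dtype=float) <= q_threshold
    lim = np.log2(fc_threshold)
    cls = np.where(ok & (lfc > lim), "up", np.where(ok & (lfc < -lim), "down", "ns"))
    index = log2fc.index if isinstance(log2fc, pd.Series) else None
    return pd.Series(cls, index=index, name="volcano_class")


def differential_table(
    matrix: IntensityMatrix,
    labels: pd.Series,
    group_a: str | None = None,
    group_b: str | None = None,
    n_perm: int = 250,
    seed: int = 0,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full differential table: t test + permutation q + volcano class."""
    tab = student_t_per_protein(matrix, labels, group_a, group_b)
    tab["q"] = permutation_fdr(matrix, labels, n_perm, seed, group_a, group_b)
    tab["volcano_class"] = classify_volcano(
        tab["log2fc"], tab["p"], tab["q"], fc_threshold, p_threshold, q_threshold
    )
    return tab


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact p by enumeration when n1+n2 <= 12 and there are no ties;
    tie-corrected normal approximation with continuity correction
    otherwise.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise BileflowError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
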