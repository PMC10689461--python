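"""Per-protein ROC-AUC discrimination of biliary viability, averaged
across histology-stratum / timepoint comparisons.

Each protein's intensity is scored for how well it separates livers with
high vs low biliary viability within four comparisons — low-BDI livers
at 30 and 150 min, and high-BDI livers at 30 and 150 min — using the
rank-based AUC (the probability that a random high-viability sample
exceeds a random low-viability one, ties counting one half; identical to
U / (n1*n2)).  Proteins are ranked by the arithmetic mean AUC over the
comparisons where both classes are present.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_model import BileflowError, CohortMetadata, IntensityMatrix

logger = logging.getLogger("bileflow")

#: (name, bdi stratum, timepoint) roster of the default comparisons.
DEFAULT_COMPARISONS = (
    ("lowBDI_T30", "low", "T30"),
    ("lowBDI_T150", "low", "T150"),
    ("highBDI_T30", "high", "T30"),
    ("highBDI_T150", "high", "T150"),
)


def roc_auc(values, labels, positive: str = "high") -> float:
    """Rank-based ROC-AUC with the positive class on top.

    AUC = P(random positive > random negative) + 0.5 P(tie), computed
    from midranks; equals the Mann-Whitney U statistic divided by n1*n2.
    Raises when only one class is present.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise BileflowError("AUC undefined: both classes must be present")
    ranks = rankdata(values)  # midranks for ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_matrix(X: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """Row-wise rank AUC for every protein at once."""
    n_pos = int(pos_mask.sum())
    n_neg = X.shape[1] - n_pos
    ranks = rankdata(X, axis=1)
    u = ranks[:, pos_mask].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def stratified_mean_auc(
    matrix: IntensityMatrix,
    meta: CohortMetadata,
    comparisons=DEFAULT_COMPARISONS,
    positive: str = "high",
    fold: bool = False,
    top_k: int | None = None,
) -> pd.DataFrame:
    """AUC per protein per stratum comparison, plus mean AUC and rank.

    ``matrix`` is the complete (imputed) matrix containing the samples of
    all relevant timepoints.  For every comparison the samples of that
    timepoint whose livers fall in the given BDI stratum and carry a
    known viability class are scored; a comparison missing one class is
    dropped from the mean with a warning.  ``fold=True`` ranks by
    max(AUC, 1-AUC) instead of the directional AUC.  Ties in mean AUC are
    broken by protein id; ``top_k`` truncates the ranked table.
    """
    if matrix.data.isna().any().any():
        raise BileflowError("AUC ranking expects a complete (imputed) matrix")
    cols: dict[str, np.ndarray] = {}
    for name, stratum, timepoint in comparisons:
        samples = meta.samples_at(timepoint)
        livers = meta.livers.loc[samples["liver_id"]]
        ok = (
            (livers["bdi_class"].to_numpy() == stratum)
            & np.isin(livers["viability_class"].to_numpy(), ("high", "low"))
        )
        sids = list(samples.index[ok])
        if not sids:
            logger.warning("comparison %s has no samples; dropped", name)
            continue
        classes = meta.sample_labels(sids, "viability_class").to_numpy()
        pos_mask = classes == positive
        if pos_mask.all() or not pos_mask.any():
            logger.warning("comparison %s is single-class; dropped", name)
            continue
        X = matrix.data[sids].to_numpy()
        cols[name] = _auc_matrix(X, pos_mask)
    if not cols:
        raise BileflowError("no comparison contained both viability classes")
    table = pd.DataFrame(cols, index=matrix.data.index)
    scored = table if not fold else np.maximum(table, 1.0 - table)
    table["mean_auc"] = scored.mean(axis=1)
    # descending mean AUC, ties broken by protein id for determinism
    table.index.name = "protein"
    table = (
        table.reset_index()
        .sort_values(["mean_auc", "protein"], ascending=[False, True], kind="stable")
        .set_index("protein")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    if top_k is not None:
        table = table.head(top_k)
    return table
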