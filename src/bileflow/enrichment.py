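"""Over-representation analysis against user-supplied gene sets.

A self-contained hypergeometric test with Benjamini-Hochberg adjustment:
for each gene set, the upper-tail probability P(X >= overlap) of drawing
at least the observed overlap when |query| ids are sampled without
replacement from the background.  Sets are intersected with the
background before testing; the recommended background is the set of
proteins surviving the valid-value filter (the tested universe), so
enrichment is conditioned on detectability.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_model import BileflowError

logger = logging.getLogger("bileflow")


def hypergeom_ora(
    query: Iterable[str],
    background: Iterable[str],
    sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against gene sets.

    Returns one row per tested set: overlap, sizes, upper-tail p
    (P(X >= overlap)) and BH-adjusted q, sorted by q then p.  Sets with
    empty background intersection are skipped.
    """
    query = set(query)
    background = set(background)
    stray = sorted(query - background)
    if stray:
        raise BileflowError(f"query ids not in background: {stray}")
    n_bg = len(background)
    n_query = len(query)
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & background
        if not in_bg:
            logger.warning("set %r has empty background intersection; skipped", name)
            continue
        overlap = len(query & in_bg)
        # P(X >= overlap) for X ~ Hypergeom(N=n_bg, K=|set|, n=|query|)
        p = float(hypergeom.sf(overlap - 1, n_bg, len(in_bg), n_query))
        p = min(p, 1.0)
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "query_size": n_query,
                "set_size": len(in_bg),
                "background_size": n_bg,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "overlap", "query_size", "set_size", "background_size", "p", "q"]
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["q", "p", "set"], kind="stable").reset_index(drop=True)
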