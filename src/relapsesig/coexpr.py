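"""mRNA co-expression partners of signature lncRNAs.

For each lncRNA, candidate mRNAs are ranked by Pearson correlation with the
lncRNA's expression profile and the top fraction (default 1%) of positively
ranked partners is retained; the union across lncRNAs gives the partner
list feeding downstream functional annotation (which is outside this
package).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["pearson_partners", "union_partners"]


def pearson_partners(
    lnc_expression: pd.Series, mrna_matrix: pd.DataFrame, fraction: float = 0.01
) -> pd.DataFrame:
    """Top-fraction mRNA partners of one lncRNA by Pearson correlation.

    The partner count is ``ceil(fraction * n_candidate_mrnas)``; candidates
    are ranked by r descending (ties broken by mRNA id) so the selection
    favours positive co-expression.  Zero-variance series are excluded with
    a warning since their correlation is undefined.

    Returns a DataFrame with columns ``mrna_id``, ``r`` and ``rank``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    common = mrna_matrix.columns.intersection(lnc_expression.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples to correlate")
    x = lnc_expression.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("lncRNA profile has zero variance; correlation undefined")
    M = mrna_matrix.loc[:, common].to_numpy(dtype=float)
    sd = M.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"excluding {int(degenerate.sum())} zero-variance mRNA(s) from "
            "correlation ranking",
            RuntimeWarning,
            stacklevel=2,
        )
    ids = mrna_matrix.index.to_numpy()[~degenerate]
    M = M[~degenerate]
    xc = x - x.mean()
    Mc = M - M.mean(axis=1, keepdims=True)
    r = (Mc @ xc) / (np.linalg.norm(Mc, axis=1) * np.linalg.norm(xc))
    n_keep = math.ceil(fraction * len(ids))
    order = sorted(range(len(ids)), key=lambda i: (-r[i], str(ids[i])))[:n_keep]
    return pd.DataFrame(
        {
            "mrna_id": ids[order],
            "r": r[order],
            "rank": np.arange(1, n_keep + 1),
        }
    )


def union_partners(partner_sets: Iterable[pd.DataFrame]) -> list[str]:
    """Deduplicated, sorted union of partner mRNA ids across lncRNAs."""
    sets = list(partner_sets)
    if not sets:
        raise ValueError("need at least one partner set")
    ids: set[str] = set()
    for frame in sets:
        ids.update(frame["mrna_id"].astype(str))
    return sorted(ids)
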