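"""Differential screening of relapse vs relapse-free expression.

Per-gene two-sample t-tests (pooled-variance Student by default, Welch via
flag), family-wise Bonferroni correction with a strict ``p_adj < alpha``
call, and the unsupervised sample clustering (Euclidean distance, complete
linkage) used to show class structure, plus its chi-square association with
the relapse labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "two_class_ttest",
    "bonferroni_adjust",
    "select_differential",
    "differential_expression",
    "hierarchical_cluster",
    "cluster_class_association",
]


def _check_labels(matrix: pd.DataFrame, labels: pd.Series) -> pd.Series:
    labels = pd.Series(labels).reindex(matrix.columns)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"class labels missing for samples: {missing}")
    labels = labels.astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need at least 2 samples per class, got {n_pos} relapse / {n_neg} relapse-free"
        )
    return labels


def two_class_ttest(
    matrix: pd.DataFrame, labels: pd.Series, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sided t-test of every gene between relapse and relapse-free samples.

    ``labels`` is boolean/0-1 per sample with True = relapse; t is positive
    when the relapse class mean is higher.  ``equal_var=True`` gives the
    pooled-variance Student test; ``False`` the Welch variant.  Degenerate
    genes with zero variance in both classes and equal means are assigned
    t=0, p=1 (never significant).

    Returns a DataFrame indexed by gene with columns ``t`` and ``p``.
    """
    labels = _check_labels(matrix, labels)
    pos = matrix.loc[:, labels.to_numpy()].to_numpy()
    neg = matrix.loc[:, (~labels).to_numpy()].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(pos, neg, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(pos.mean(axis=1), neg.mean(axis=1))
    t = np.where(degenerate & equal_means, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    # zero pooled variance but distinct means: perfectly separated gene
    t = np.where(degenerate & ~equal_means, np.sign(pos.mean(axis=1) - neg.mean(axis=1)) * np.inf, t)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    return pd.DataFrame({"t": t, "p": p}, index=matrix.index)


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni family-wise adjustment: ``min(1, m * p)`` for m tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def differential_expression(
    matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.01,
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-test + Bonferroni in one table: gene, t, p, p_adj, significant."""
    result = two_class_ttest(matrix, labels, equal_var=equal_var)
    result["p_adj"] = bonferroni_adjust(result["p"].to_numpy())
    result["significant"] = result["p_adj"] < alpha
    return result


def select_differential(results: pd.DataFrame, alpha: float = 0.01) -> list[str]:
    """Genes with adjusted p strictly below alpha, best p first (ties by id)."""
    if "p_adj" not in results.columns:
        raise ValueError("results must carry a p_adj column (run differential_expression)")
    hits = results[results["p_adj"] < alpha]
    return sorted(hits.index, key=lambda gid: (hits.at[gid, "p"], str(gid)))


def hierarchical_cluster(matrix: pd.DataFrame, k: int = 2) -> pd.Series:
    """Agglomerative clustering of samples: Euclidean distance, complete linkage.

    The dendrogram is cut into ``k`` groups and the groups are labelled with
    Roman numerals in order of first appearance along the sample axis, so
    the labelling is deterministic for a given column order.  When merge
    distances tie, SciPy's deterministic ordering (by observation index)
    decides, which this function inherits.
    """
    n = matrix.shape[1]
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} samples")
    distances = pdist(matrix.to_numpy().T, metric="euclidean")
    tree = hierarchy.linkage(distances, method="complete")
    flat = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    romans = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    relabel: dict[int, str] = {}
    for raw in flat:
        if raw not in relabel:
            relabel[raw] = romans[len(relabel)] if len(relabel) < len(romans) else str(len(relabel) + 1)
    return pd.Series([relabel[c] for c in flat], index=matrix.columns, name="cluster")


def cluster_class_association(
    assignment: pd.Series, labels: pd.Series, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square association between cluster labels and classes.

    Returns ``(chi2, p)`` from the contingency table of cluster vs class;
    no continuity correction by default (available via ``correction``).
    """
    labels = pd.Series(labels).reindex(assignment.index)
    if labels.isna().any():
        raise ValueError("class labels missing for some clustered samples")
    table = pd.crosstab(assignment, labels)
    if (table.sum(axis=1) == 0).any() or table.shape[0] < 2:
        raise ValueError("chi-square test needs at least two non-empty clusters")
    result = stats.chi2_contingency(table.to_numpy(), correction=correction)
    return float(result.statistic), float(result.pvalue)
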