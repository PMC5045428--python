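"""Signal-to-noise weighted-voting classification with repeated cross-validation.

The classifier ranks genes by the absolute signal-to-noise statistic

    S_i = (mu_relapse,i - mu_nonrelapse,i) / (sigma_relapse,i + sigma_nonrelapse,i)

keeps the top N, and classifies a sample by summing per-gene votes

    V_i = S_i * (e_i - b_i),        b_i = (mu_relapse,i + mu_nonrelapse,i) / 2

calling relapse when the total vote is positive.  The optimal N is chosen
from the learning-error curve of stratified 5-fold cross-validation
repeated 100 times (``averageerror_N`` = misclassified patients per
repeat), and the final signature is the top-N genes by frequency of
appearance in the per-training-fold rankings.

Usage follows the model/results idiom::

    model = WeightedVoting(expression, labels)
    res = model.fit(n_genes=9)           # VotingResults with (S, b) table
    cv = model.cross_validate(seed=7)    # CrossValidationResult
    opn = cv.select_optimal_n()
    signature = cv.select_signature(opn)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeightedVoting",
    "VotingResults",
    "CrossValidationResult",
    "SignatureSelection",
    "signal_to_noise",
    "class_boundary",
    "classification_metrics",
    "stratified_folds",
]

_EPS = 1e-12


def _as_bool_labels(matrix: pd.DataFrame, labels) -> np.ndarray:
    labels = pd.Series(labels).reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError(
            f"labels missing for samples: {labels.index[labels.isna()].tolist()}"
        )
    y = labels.astype(bool).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 samples in each class")
    return y


def _s2n_arrays(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(S, b) per gene row of X given boolean labels y (True = relapse)."""
    pos, neg = X[:, y], X[:, ~y]
    mu_pos, mu_neg = pos.mean(axis=1), neg.mean(axis=1)
    sd_pos = pos.std(axis=1, ddof=1)
    sd_neg = neg.std(axis=1, ddof=1)
    denom = sd_pos + sd_neg
    if np.any(denom == 0):
        warnings.warn(
            "gene(s) with zero within-class SD in both classes; "
            "adding epsilon to the signal-to-noise denominator",
            RuntimeWarning,
            stacklevel=3,
        )
        denom = denom + _EPS
    s = (mu_pos - mu_neg) / denom
    b = (mu_pos + mu_neg) / 2.0
    return s, b


def signal_to_noise(matrix: pd.DataFrame, labels) -> pd.Series:
    """Per-gene signal-to-noise statistic, positive when relapse mean is higher.

    Class SDs use the n-1 denominator.  Genes with zero SD in both classes
    get an epsilon denominator (with a warning) rather than an infinity.
    """
    y = _as_bool_labels(matrix, labels)
    s, _ = _s2n_arrays(matrix.to_numpy(), y)
    return pd.Series(s, index=matrix.index, name="s2n")


def class_boundary(matrix: pd.DataFrame, labels) -> pd.Series:
    """Per-gene classification boundary: midpoint of the two class means."""
    y = _as_bool_labels(matrix, labels)
    _, b = _s2n_arrays(matrix.to_numpy(), y)
    return pd.Series(b, index=matrix.index, name="boundary")


def _rank_order(s: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting genes by |S| descending, ties by gene id ascending."""
    return np.lexsort((gene_ids, -np.abs(s)))


class WeightedVoting:
    """Weighted-voting classifier of relapse status from expression.

    Parameters
    ----------
    expression:
        Gene-by-sample DataFrame (candidate genes only, typically the
        differentially expressed set).
    labels:
        Per-sample relapse indicator (True/1 = relapse), aligned to the
        expression columns.
    """

    def __init__(self, expression: pd.DataFrame, labels) -> None:
        if expression.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        self.expression = expression
        self.labels = pd.Series(
            _as_bool_labels(expression, labels), index=expression.columns, name="relapse"
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, n_genes: int | None = None) -> "VotingResults":
        """Estimate (S, b) on all samples and keep the top ``n_genes`` by |S|."""
        n_total = self.expression.shape[0]
        if n_genes is None:
            n_genes = n_total
        if not 1 <= n_genes <= n_total:
            raise ValueError(f"n_genes must lie in [1, {n_total}]")
        X = self.expression.to_numpy()
        y = self.labels.to_numpy()
        s, b = _s2n_arrays(X, y)
        order = _rank_order(s, self.expression.index.to_numpy())[:n_genes]
        params = pd.DataFrame(
            {
                "s2n": s[order],
                "boundary": b[order],
                "rank": np.arange(1, n_genes + 1),
            },
            index=self.expression.index[order],
        )
        return VotingResults(model=self, params=params)

    # -- cross-validation --------------------------------------------------

    def cross_validate(
        self,
        n_folds: int = 5,
        n_repeats: int = 100,
        seed: int = 0,
        stratified: bool = True,
        max_n: int | None = None,
    ) -> "CrossValidationResult":
        """Repeated k-fold learning-error curve over model sizes N = 1..G.

        Every repeat draws a fresh random partition of the samples into
        ``n_folds`` folds (stratified by class by default so each training
        fold contains both classes).  For each held-out fold a model is
        built on the remaining folds at every size N and the held-out
        misclassifications are counted; ``error_curve[N]`` is the total
        across all folds divided by ``n_repeats`` (i.e. misclassified
        patients per repeat).  Per-repeat RNG streams are spawned from the
        master seed, so results are reproducible.
        """
        X = self.expression.to_numpy()
        y = self.labels.to_numpy()
        gene_ids = self.expression.index.to_numpy()
        n_genes, n_samples = X.shape
        if n_folds < 2 or n_folds > n_samples:
            raise ValueError("n_folds must lie in [2, n_samples]")
        if stratified and min(y.sum(), (~y).sum()) < n_folds:
            raise ValueError(
                "each class needs at least n_folds samples for stratified folds"
            )
        n_top = n_genes if max_n is None else min(max_n, n_genes)

        errors = np.zeros(n_top)
        rankings: list[np.ndarray] = []
        partitions: list[np.ndarray] = []
        streams = np.random.SeedSequence(seed).spawn(n_repeats)
        for ss in streams:
            rng = np.random.default_rng(ss)
            fold_of = stratified_folds(y, n_folds, rng, stratified=stratified)
            partitions.append(fold_of)
            for fold in range(n_folds):
                test = fold_of == fold
                train = ~test
                s, b = _s2n_arrays(X[:, train], y[train])
                order = _rank_order(s, gene_ids)
                rankings.append(gene_ids[order])
                votes = s[order, None] * (X[np.ix_(order, np.flatnonzero(test))] - b[order, None])
                total = np.cumsum(votes[:n_top], axis=0)
                predicted = total > 0  # tie at exactly 0 -> relapse-free
                errors += (predicted != y[test][None, :]).sum(axis=1)

        curve = pd.Series(
            errors / n_repeats,
            index=pd.RangeIndex(1, n_top + 1, name="N"),
            name="averageerror",
        )
        return CrossValidationResult(
            model=self,
            error_curve=curve,
            fold_rankings=rankings,
            partitions=partitions,
            n_folds=n_folds,
            n_repeats=n_repeats,
            seed=seed,
        )


@dataclass
class VotingResults:
    """A fitted top-N weighted-voting model.

    ``params`` is ordered by |S| descending with columns ``s2n``,
    ``boundary`` and ``rank``.
    """

    model: WeightedVoting
    params: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.params.index)

    def decision_scores(self, expression: pd.DataFrame) -> pd.Series:
        """Total vote per sample column of ``expression``."""
        missing = self.params.index.difference(expression.index)
        if len(missing) > 0:
            raise ValueError(f"expression lacks model genes: {missing.tolist()}")
        sub = expression.loc[self.params.index]
        votes = self.params["s2n"].to_numpy()[:, None] * (
            sub.to_numpy() - self.params["boundary"].to_numpy()[:, None]
        )
        return pd.Series(votes.sum(axis=0), index=expression.columns, name="total_vote")

    def votes(self, sample_expression: pd.Series) -> pd.Series:
        """Per-gene votes V_i = S_i (e_i - b_i) for one sample."""
        frame = sample_expression.to_frame(name=sample_expression.name or "sample")
        missing = self.params.index.difference(frame.index)
        if len(missing) > 0:
            raise ValueError(f"sample lacks model genes: {missing.tolist()}")
        e = frame.loc[self.params.index].iloc[:, 0]
        return self.params["s2n"] * (e - self.params["boundary"])

    def predict(self, expression: pd.DataFrame) -> pd.Series:
        """Predicted relapse indicator per sample (tie at 0 -> relapse-free)."""
        return (self.decision_scores(expression) > 0).rename("relapse_predicted")

    def summary(self) -> str:
        lines = [
            "Weighted-voting classifier",
            f"  genes: {len(self.params)}  samples: {self.model.expression.shape[1]}",
            "",
            self.params.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


@dataclass
class SignatureSelection:
    """Frequency-based final gene selection over the CV training folds."""

    optimal_n: int
    frequencies: pd.Series  # per gene: appearances in the top-N of a fold ranking
    mean_rank: pd.Series
    selected: list[str]


@dataclass
class CrossValidationResult:
    """Learning-error curve and per-fold rankings of repeated k-fold CV."""

    model: WeightedVoting
    error_curve: pd.Series
    fold_rankings: list[np.ndarray] = field(repr=False)
    partitions: list[np.ndarray] = field(repr=False)
    n_folds: int = 5
    n_repeats: int = 100
    seed: int = 0

    def select_optimal_n(self, tolerance: float = 1.0) -> int:
        """Smallest N whose average error is within ``tolerance`` of the minimum.

        ``tolerance`` is in expected misclassified patients per repeat; 0
        returns the first N attaining the exact minimum.
        """
        if tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        curve = self.error_curve
        threshold = curve.min() + tolerance
        return int(curve.index[curve.to_numpy() <= threshold][0])

    def select_signature(self, optimal_n: int) -> SignatureSelection:
        """Top-``optimal_n`` genes by frequency in the fold rankings' top-N.

        For each of the ``n_folds * n_repeats`` training-fold rankings, a
        gene scores one appearance when it sits in that ranking's top
        ``optimal_n`` by |S|.  Ties in frequency are broken by mean rank
        across folds (better first), then gene id.
        """
        gene_ids = self.model.expression.index
        if not 1 <= optimal_n <= len(gene_ids):
            raise ValueError(f"optimal_n must lie in [1, {len(gene_ids)}]")
        counts = pd.Series(0, index=gene_ids, dtype=int)
        rank_sum = pd.Series(0.0, index=gene_ids)
        for ranking in self.fold_rankings:
            counts[ranking[:optimal_n]] += 1
            rank_sum[ranking] += np.arange(1, len(ranking) + 1)
        mean_rank = rank_sum / len(self.fold_rankings)
        order = sorted(
            gene_ids, key=lambda gid: (-counts[gid], mean_rank[gid], str(gid))
        )
        return SignatureSelection(
            optimal_n=optimal_n,
            frequencies=counts.rename("frequency"),
            mean_rank=mean_rank.rename("mean_rank"),
            selected=list(order[:optimal_n]),
        )


def stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator, stratified: bool = True
) -> np.ndarray:
    """Random fold assignment; fold sizes differ by at most one.

    With ``stratified=True`` each class is shuffled separately and the two
    shuffled blocks are dealt round-robin, so per-class fold counts also
    differ by at most one.
    """
    n = len(y)
    if stratified:
        order = np.concatenate(
            [rng.permutation(np.flatnonzero(y)), rng.permutation(np.flatnonzero(~y))]
        )
    else:
        order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % n_folds
    return fold_of


def classification_metrics(
    truth, predicted, scores=None
) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity and (optionally) ROC AUC.

    Relapse (True) is the positive class: sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).  When ``scores`` (total votes) are given, the
    AUC is the rank statistic of scores against truth; it is reported as
    None when the truth contains a single class.
    """
    truth = np.asarray(truth, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predictions must align")
    tp = int(np.sum(truth & predicted))
    fn = int(np.sum(truth & ~predicted))
    tn = int(np.sum(~truth & ~predicted))
    fp = int(np.sum(~truth & predicted))
    metrics: dict[str, float | None] = {
        "accuracy": (tp + tn) / truth.size,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
    }
    if scores is not None:
        if truth.all() or not truth.any():
            metrics["auc"] = None
        else:
            from sklearn.metrics import roc_auc_score

            metrics["auc"] = float(roc_auc_score(truth, np.asarray(scores, dtype=float)))
    return metrics
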