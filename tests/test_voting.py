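"""Weighted-voting classifier: hand-computed examples, invariants, and an
independent straight-line cross-validation oracle."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relapsesig.cohort import SimulationConfig, simulate_cohort
from relapsesig.voting import (
    WeightedVoting,
    class_boundary,
    classification_metrics,
    signal_to_noise,
    stratified_folds,
)


def _frame(rows, samples=None, genes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# straight-line oracle: pure-python weighted-voting CV, shared partitions
# ---------------------------------------------------------------------------

def oracle_cv_errors(matrix: pd.DataFrame, labels: pd.Series, partitions, n_top):
    """Recompute per-N CV error counts with plain loops and stdlib stats."""
    genes = list(matrix.index)
    errors = [0.0] * n_top
    for fold_of in partitions:
        for fold in sorted(set(fold_of)):
            train = [s for s, f in zip(matrix.columns, fold_of) if f != fold]
            test = [s for s, f in zip(matrix.columns, fold_of) if f == fold]
            params = {}
            for gene in genes:
                pos = [matrix.at[gene, s] for s in train if labels[s]]
                neg = [matrix.at[gene, s] for s in train if not labels[s]]
                mu_p, mu_n = statistics.mean(pos), statistics.mean(neg)
                sd_p, sd_n = statistics.stdev(pos), statistics.stdev(neg)
                params[gene] = ((mu_p - mu_n) / (sd_p + sd_n), (mu_p + mu_n) / 2)
            ranking = sorted(genes, key=lambda g: (-abs(params[g][0]), g))
            for n in range(1, n_top + 1):
                top = ranking[:n]
                for s in test:
                    total = sum(
                        params[g][0] * (matrix.at[g, s] - params[g][1]) for g in top
                    )
                    predicted = total > 0
                    if predicted != bool(labels[s]):
                        errors[n - 1] += 1
    return errors


class TestSignalToNoise:
    def test_hand_formula(self):
        """relapse {2,4} vs relapse-free {0,2}: S = 2 / (2*sqrt(2))."""
        m = _frame([[2.0, 4.0, 0.0, 2.0]])
        labels = pd.Series([1, 1, 0, 0], index=m.columns)
        s = signal_to_noise(m, labels)
        assert s["g0"] == pytest.approx(2 / (2 * math.sqrt(2)), abs=1e-6)
        assert s["g0"] == pytest.approx(0.7071, abs=1e-4)

    def test_identical_distributions_zero(self):
        m = _frame([[1.0, 2.0, 1.0, 2.0]])
        labels = pd.Series([1, 1, 0, 0], index=m.columns)
        assert signal_to_noise(m, labels)["g0"] == pytest.approx(0.0)

    def test_label_swap_negates_s_keeps_ranking(self):
        rng = np.random.default_rng(0)
        m = _frame(rng.normal(size=(6, 10)))
        labels = pd.Series([1] * 5 + [0] * 5, index=m.columns)
        a = signal_to_noise(m, labels)
        b = signal_to_noise(m, 1 - labels)
        assert np.allclose(a, -b)
        assert list(a.abs().sort_values().index) == list(b.abs().sort_values().index)

    def test_zero_denominator_epsilon_rule_warns(self):
        m = _frame([[1.0, 1.0, 0.0, 0.0]])
        labels = pd.Series([1, 1, 0, 0], index=m.columns)
        with pytest.warns(RuntimeWarning, match="epsilon"):
            s = signal_to_noise(m, labels)
        assert np.isfinite(s["g0"])


class TestBoundary:
    def test_midpoint_and_symmetry(self):
        m = _frame([[2.0, 4.0, 0.0, 2.0]])
        labels = pd.Series([1, 1, 0, 0], index=m.columns)
        b = class_boundary(m, labels)
        assert b["g0"] == pytest.approx(2.0)  # means 3 and 1
        assert class_boundary(m, 1 - labels)["g0"] == pytest.approx(2.0)

    def test_equal_means(self):
        m = _frame([[1.0, 3.0, 2.0, 2.0]])
        labels = pd.Series([1, 1, 0, 0], index=m.columns)
        assert class_boundary(m, labels)["g0"] == pytest.approx(2.0)


class TestFit:
    def test_full_model_contains_all_genes(self, eight_sample_matrix):
        matrix, labels = eight_sample_matrix
        res = WeightedVoting(matrix, labels).fit()
        assert set(res.genes) == set(matrix.index)

    def test_top_n_ordering(self):
        rng = np.random.default_rng(5)
        m = _frame(rng.normal(size=(3, 20)))
        m.iloc[0, :10] += 3.0  # strongest
        m.iloc[1, :10] += 1.0
        labels = pd.Series([1] * 10 + [0] * 10, index=m.columns)
        res = WeightedVoting(m, labels).fit(n_genes=2)
        s = signal_to_noise(m, labels)
        expected = list(s.abs().sort_values(ascending=False).index[:2])
        assert res.genes == expected

    def test_tied_s_broken_by_gene_id(self):
        base = [3.0, 5.0, 0.0, 2.0]
        m = _frame([base, base], genes=["gB", "gA"])
        labels = pd.Series([1, 1, 0, 0], index=m.columns)
        res = WeightedVoting(m, labels).fit()
        assert res.genes == ["gA", "gB"]

    def test_n_out_of_range(self, eight_sample_matrix):
        matrix, labels = eight_sample_matrix
        with pytest.raises(ValueError):
            WeightedVoting(matrix, labels).fit(n_genes=99)


class TestClassify:
    def test_vote_hand_example(self):
        """S=0.7071, b=2, e=4 -> V = 1.4142 and a relapse call."""
        m = _frame([[2.0, 4.0, 0.0, 2.0]])
        labels = pd.Series([1, 1, 0, 0], index=m.columns)
        res = WeightedVoting(m, labels).fit()
        sample = pd.Series({"g0": 4.0}, name="new")
        votes = res.votes(sample)
        assert votes["g0"] == pytest.approx(1.4142, abs=1e-4)
        frame = sample.to_frame("new").reindex(m.index)
        assert bool(res.predict(frame)["new"])

    def test_tie_at_zero_predicts_relapse_free(self):
        m = _frame([[2.0, 4.0, 0.0, 2.0]])
        labels = pd.Series([1, 1, 0, 0], index=m.columns)
        res = WeightedVoting(m, labels).fit()
        at_boundary = pd.DataFrame({"x": [2.0]}, index=["g0"])
        assert res.decision_scores(at_boundary)["x"] == pytest.approx(0.0)
        assert not bool(res.predict(at_boundary)["x"])

    def test_negating_s_flips_nontied_predictions(self, eight_sample_matrix):
        matrix, labels = eight_sample_matrix
        res = WeightedVoting(matrix, labels).fit()
        flipped = WeightedVoting(matrix, 1 - labels).fit()
        a = res.decision_scores(matrix)
        b = flipped.decision_scores(matrix)
        assert np.allclose(a, -b)

    def test_scale_covariance(self, eight_sample_matrix):
        matrix, labels = eight_sample_matrix
        res = WeightedVoting(matrix, labels).fit()
        scaled = res.params.copy()
        scaled["s2n"] *= 3.0
        doubled = type(res)(model=res.model, params=scaled)
        assert np.allclose(
            doubled.decision_scores(matrix), 3.0 * res.decision_scores(matrix)
        )
        pd.testing.assert_series_equal(doubled.predict(matrix), res.predict(matrix))

    def test_missing_gene_rejected(self, eight_sample_matrix):
        matrix, labels = eight_sample_matrix
        res = WeightedVoting(matrix, labels).fit()
        with pytest.raises(ValueError, match="gA"):
            res.decision_scores(matrix.drop(index="gA"))


class TestFolds:
    def test_partition_properties(self):
        rng = np.random.default_rng(1)
        y = np.array([True] * 33 + [False] * 88)
        fold_of = stratified_folds(y, 5, rng)
        sizes = np.bincount(fold_of, minlength=5)
        assert sizes.sum() == 121
        assert sizes.max() - sizes.min() <= 1
        for fold in range(5):
            assert y[fold_of == fold].sum() >= 1  # both classes everywhere
            assert (~y[fold_of == fold]).sum() >= 1


class TestCrossValidation:
    def test_separable_gene_zero_errors(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(10, 0.1, 10), rng.normal(-10, 0.1, 10)])
        m = _frame([values])
        labels = pd.Series([1] * 10 + [0] * 10, index=m.columns)
        cv = WeightedVoting(m, labels).cross_validate(n_folds=5, n_repeats=5, seed=0)
        assert (cv.error_curve < 1e-12).all()

    def test_null_labels_error_near_chance(self):
        rng = np.random.default_rng(7)
        m = _frame(rng.normal(size=(10, 60)))
        labels = pd.Series(rng.permutation([1] * 20 + [0] * 40), index=m.columns)
        cv = WeightedVoting(m, labels).cross_validate(n_folds=5, n_repeats=20, seed=1)
        chance = 60 * min(labels.mean(), 1 - labels.mean())
        # with no signal, errors hover around the minority rate
        assert cv.error_curve.min() > 0.5 * chance
        assert cv.error_curve.max() < 60 - 0.5 * chance

    def test_matches_straight_line_oracle(self, eight_sample_matrix):
        """Exact equality with an independent pure-python recomputation."""
        matrix, labels = eight_sample_matrix
        cv = WeightedVoting(matrix, labels).cross_validate(
            n_folds=2, n_repeats=2, seed=3
        )
        expected = oracle_cv_errors(matrix, labels, cv.partitions, n_top=3)
        assert np.array_equal(
            cv.error_curve.to_numpy() * cv.n_repeats, np.asarray(expected)
        )

    def test_reproducible_from_seed(self, eight_sample_matrix):
        matrix, labels = eight_sample_matrix
        a = WeightedVoting(matrix, labels).cross_validate(n_folds=2, n_repeats=3, seed=9)
        b = WeightedVoting(matrix, labels).cross_validate(n_folds=2, n_repeats=3, seed=9)
        pd.testing.assert_series_equal(a.error_curve, b.error_curve)
        assert all(np.array_equal(x, y) for x, y in zip(a.partitions, b.partitions))


class TestOptimalN:
    @pytest.mark.parametrize(
        "curve, tolerance, expected",
        [
            ([10, 5, 3, 3, 3], 0.0, 3),
            ([10, 4, 3.2, 3.1, 3.05], 0.5, 3),
            ([2, 2, 2, 2], 0.0, 1),
        ],
    )
    def test_scan_rule(self, curve, tolerance, expected, eight_sample_matrix):
        matrix, labels = eight_sample_matrix
        cv = WeightedVoting(matrix, labels).cross_validate(n_folds=2, n_repeats=1, seed=0)
        cv.error_curve = pd.Series(
            curve, index=pd.RangeIndex(1, len(curve) + 1, name="N")
        )
        assert cv.select_optimal_n(tolerance) == expected


class TestSignatureSelection:
    def test_dominant_gene_always_selected(self, eight_sample_matrix):
        matrix, labels = eight_sample_matrix  # gA carries all the signal
        cv = WeightedVoting(matrix, labels).cross_validate(n_folds=2, n_repeats=10, seed=2)
        sel = cv.select_signature(1)
        assert sel.selected == ["gA"]
        assert sel.frequencies["gA"] == len(cv.fold_rankings)

    def test_recovers_informative_genes_from_noise(self):
        cohort = simulate_cohort(
            SimulationConfig(n_patients=121, n_genes=60, n_informative=9,
                             effect_size=2.0, seed=23)
        )
        model = WeightedVoting(cohort.expression, cohort.annotation["relapse"])
        cv = model.cross_validate(n_folds=5, n_repeats=20, seed=23, max_n=15)
        sel = cv.select_signature(9)
        assert len(set(sel.selected) & set(cohort.informative_genes)) >= 8

    def test_frequency_tie_broken_by_mean_rank(self, eight_sample_matrix):
        matrix, labels = eight_sample_matrix
        cv = WeightedVoting(matrix, labels).cross_validate(n_folds=2, n_repeats=5, seed=4)
        sel = cv.select_signature(2)
        freq, rank = sel.frequencies, sel.mean_rank
        order = sorted(matrix.index, key=lambda g: (-freq[g], rank[g], g))
        assert sel.selected == order[:2]


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        truth = np.array([1, 1, 0, 0], dtype=bool)
        metrics = classification_metrics(truth, truth, scores=[4, 3, 2, 1])
        assert metrics == {
            "accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0, "auc": 1.0
        }

    def test_published_style_confusion_table(self):
        """TP=30 FN=3 TN=72 FP=16 over 33 relapse / 88 relapse-free."""
        truth = np.array([True] * 33 + [False] * 88)
        predicted = np.array([True] * 30 + [False] * 3 + [True] * 16 + [False] * 72)
        metrics = classification_metrics(truth, predicted)
        assert metrics["sensitivity"] == pytest.approx(0.909, abs=5e-4)
        assert metrics["specificity"] == pytest.approx(0.818, abs=5e-4)
        assert metrics["accuracy"] == pytest.approx(0.843, abs=5e-4)

    def test_constant_score_auc_half(self):
        truth = np.array([1, 0, 1, 0], dtype=bool)
        metrics = classification_metrics(truth, truth, scores=[1.0] * 4)
        assert metrics["auc"] == pytest.approx(0.5)

    def test_single_class_auc_undefined(self):
        truth = np.ones(4, dtype=bool)
        metrics = classification_metrics(truth, truth, scores=[1, 2, 3, 4])
        assert metrics["auc"] is None


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_s2n_antisymmetry_property(seed):
    rng = np.random.default_rng(seed)
    m = _frame(rng.normal(size=(4, 12)))
    labels = pd.Series(rng.permutation([1] * 6 + [0] * 6), index=m.columns)
    assert np.allclose(signal_to_noise(m, labels), -signal_to_noise(m, 1 - labels))
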