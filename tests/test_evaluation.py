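"""Agreement statistics, group comparison and ROC cut-off selection."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

import cescore as cs
from cescore.evaluation import ConfusionMatrix, format_p

# Per-score frame counts as printed for the algorithm and the clinicians
ALGO_COUNTS = (3227, 17876, 16264, 9354, 4659)
CLIN_COUNTS = (3761, 16696, 14723, 4603, 11597)


def embed(block):
    """Place a small count block into the top-left of a 5x5 matrix."""
    m = np.zeros((5, 5), dtype=int)
    b = np.asarray(block)
    m[: b.shape[0], : b.shape[1]] = b
    return ConfusionMatrix(counts=m)


def test_mean_score_from_distribution_examples():
    assert cs.mean_score_from_distribution(ALGO_COUNTS) == pytest.approx(2.89, abs=0.005)
    assert round(cs.mean_score_from_distribution(ALGO_COUNTS), 1) == 2.9
    assert cs.mean_score_from_distribution(CLIN_COUNTS) == pytest.approx(3.07, abs=0.005)
    assert round(cs.mean_score_from_distribution(CLIN_COUNTS), 1) == 3.1
    assert cs.mean_score_from_distribution([7, 7, 7, 7, 7]) == pytest.approx(3.0)
    with pytest.raises(ValueError):
        cs.mean_score_from_distribution([0, 0, 0, 0, 0])


def test_top1_accuracy_examples():
    assert cs.top1_accuracy(embed(np.diag([3, 1, 4, 1, 5]))) == 1.0
    off = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
    assert cs.top1_accuracy(ConfusionMatrix(counts=off)) == 0.0
    assert cs.top1_accuracy(embed([[10, 0], [5, 5]])) == pytest.approx(0.75)


def test_kappa_perfect_and_independent():
    assert cs.cohen_kappa(embed(np.diag([2, 3, 4, 5, 6]))).kappa == pytest.approx(1.0)
    # exact independence: counts = outer(row, col) / total
    row = np.array([10, 20, 30, 20, 20])
    col = np.array([30, 10, 20, 20, 20])
    counts = np.outer(row, col)  # total = 100 * 100
    res = cs.cohen_kappa(ConfusionMatrix(counts=counts))
    assert res.kappa == pytest.approx(0.0, abs=1e-12)


def test_kappa_hand_computed_two_class_block():
    res = cs.cohen_kappa(embed([[20, 5], [10, 15]]))
    assert res.po == pytest.approx(0.7)
    assert res.pe == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.4)
    assert res.underestimation == pytest.approx(10 / 50)
    assert res.overestimation == pytest.approx(5 / 50)
    assert res.misclassification == pytest.approx(res.underestimation + res.overestimation)


def test_kappa_matches_sklearn_on_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(25):
        ref = rng.integers(1, 6, size=300)
        pred = np.clip(ref + rng.integers(-2, 3, size=300), 1, 5)
        cm = ConfusionMatrix.from_pairs(ref, pred)
        ours = cs.cohen_kappa(cm).kappa
        theirs = cohen_kappa_score(ref, pred)
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_kappa_invariant_under_simultaneous_permutation():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 50, size=(5, 5))
    perm = rng.permutation(5)
    k1 = cs.cohen_kappa(ConfusionMatrix(counts=counts)).kappa
    k2 = cs.cohen_kappa(ConfusionMatrix(counts=counts[np.ix_(perm, perm)])).kappa
    assert k1 == pytest.approx(k2, abs=1e-12)


def test_kappa_undefined_for_degenerate_marginals():
    m = np.zeros((5, 5), dtype=int)
    m[2, 2] = 10
    with pytest.raises(ZeroDivisionError):
        cs.cohen_kappa(ConfusionMatrix(counts=m))


def test_confusion_matrix_validation():
    with pytest.raises(ValueError):
        ConfusionMatrix(counts=np.zeros((4, 4)))
    with pytest.raises(ValueError):
        ConfusionMatrix(counts=np.zeros((5, 5)))
    with pytest.raises(ValueError):
        ConfusionMatrix.from_pairs([1, 2], [1, 6])


def test_compare_groups_basics():
    res = cs.compare_groups({"A": [4.0, 4.0], "C": [2.0, 2.0]})
    assert res.groups["A"].mean == pytest.approx(4.0)
    assert res.groups["C"].mean == pytest.approx(2.0)
    ident = cs.compare_groups({"A": [3.0, 3.0], "B": [3.0, 3.0]})
    assert ident.f_statistic == pytest.approx(0.0)
    single = cs.compare_groups({"A": [3.0], "B": [2.0, 2.5]})
    assert single.groups["A"].sd is None and single.groups["A"].ci95 is None
    with pytest.raises(ValueError):
        cs.compare_groups({"A": [1.0], "B": []})


def test_compare_groups_recovers_simulated_means():
    rng = np.random.default_rng(2)
    truth = {"A": 3.9, "B": 3.2, "C": 2.5}
    sds = {"A": 0.3, "B": 0.5, "C": 0.5}
    groups = {
        g: rng.normal(mu, sds[g], size=20).tolist() for g, mu in truth.items()
    }
    res = cs.compare_groups(groups)
    for g, mu in truth.items():
        se = sds[g] / np.sqrt(20)
        assert abs(res.groups[g].mean - mu) <= 2 * se
    assert res.p_value < 0.001
    assert format_p(res.p_value) == "<0.001"


def test_roc_perfect_separation_and_midpoint_cutoff():
    res = cs.roc_analysis(
        [(3.4, True), (3.8, True), (3.1, True), (2.4, False), (2.8, False)]
    )
    assert res.auc == pytest.approx(1.0)
    assert res.cutoff == pytest.approx(2.95)
    assert res.cutoff_sensitivity == pytest.approx(1.0)
    assert res.cutoff_specificity == pytest.approx(1.0)


def test_roc_null_labels_give_chance_auc():
    rng = np.random.default_rng(3)
    scores = rng.uniform(1, 5, size=2000)
    labels = rng.uniform(size=2000) < 0.5
    res = cs.roc_analysis(scores=scores, adequate=labels)
    assert res.auc == pytest.approx(0.5, abs=0.05)


def _pair_statistic(scores, labels):
    """Mann-Whitney concordant-pair fraction with 1/2 credit for ties."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_trapezoidal_auc_equals_pair_statistic_and_sklearn():
    rng = np.random.default_rng(4)
    for trial in range(30):
        n = int(rng.integers(4, 50))
        labels = np.zeros(n, dtype=bool)
        labels[: int(rng.integers(1, n))] = True
        rng.shuffle(labels)
        # coarse grid scores produce plenty of ties
        scores = np.round(rng.uniform(1, 5, size=n) + labels * rng.uniform(0, 2), 1)
        res = cs.roc_analysis(scores=scores, adequate=labels)
        assert res.auc == pytest.approx(_pair_statistic(scores, labels), abs=1e-9)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)


def test_youden_cutoff_matches_exhaustive_search():
    rng = np.random.default_rng(5)
    for trial in range(30):
        n = int(rng.integers(5, 40))
        labels = np.zeros(n, dtype=bool)
        labels[: max(1, n // 3)] = True
        rng.shuffle(labels)
        scores = np.round(rng.uniform(1, 5, size=n) + labels * 0.8, 1)
        res = cs.roc_analysis(scores=scores, adequate=labels)
        # brute force over every distinct threshold
        best_j, best_t = -2.0, None
        for t in sorted(np.unique(scores)):  # ascending: lower threshold wins ties
            sens = (scores[labels] >= t).mean()
            spec = (scores[~labels] < t).mean()
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        lower = scores[scores < best_t]
        expected_cut = (best_t + lower.max()) / 2 if lower.size else best_t
        assert res.cutoff == pytest.approx(expected_cut, abs=1e-12)
        assert res.cutoff_sensitivity + res.cutoff_specificity - 1 == pytest.approx(best_j, abs=1e-12)


def test_roc_rejects_single_class():
    with pytest.raises(ValueError):
        cs.roc_analysis([(3.0, True), (2.0, True)])
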