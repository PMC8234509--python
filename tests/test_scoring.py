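"""Score bins, argmax rule, label smoothing, and the rule-based estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cescore as cs
from cescore.preprocessing import stack_channels
from cescore.scoring import RuleThresholds, smooth_labels

from conftest import make_labelled_frames


@pytest.mark.parametrize(
    "fraction, score",
    [
        (0.10, 1),
        (0.95, 5),
        (0.249999, 1),
        (0.25, 2),
        (0.50, 3),
        (0.75, 4),
        (0.90, 4),  # score 5 requires strictly >90% visible
        (0.900001, 5),
        (0.0, 1),
        (1.0, 5),
    ],
)
def test_fraction_to_score_bins_and_boundaries(fraction, score):
    assert cs.fraction_to_score(fraction) == score


def test_fraction_to_score_rejects_out_of_range():
    with pytest.raises(ValueError):
        cs.fraction_to_score(-0.01)
    with pytest.raises(ValueError):
        cs.fraction_to_score(1.01)


@given(st.floats(0, 1), st.floats(0, 1))
@settings(deadline=None)
def test_fraction_to_score_is_monotone(a, b):
    lo, hi = sorted([a, b])
    assert cs.fraction_to_score(lo) <= cs.fraction_to_score(hi)


@pytest.mark.parametrize(
    "probs, score",
    [
        ((0.1, 0.6, 0.1, 0.1, 0.1), 2),
        ((0.2, 0.2, 0.2, 0.2, 0.2), 1),  # tie goes to the lower score
        ((0.0, 0.0, 0.49, 0.51, 0.0), 4),
    ],
)
def test_assign_score_takes_argmax_with_low_tie_break(probs, score):
    assert cs.assign_score(cs.ScoreDistribution(np.array(probs))) == score


def test_assign_score_inverts_one_hot():
    for k in range(1, 6):
        probs = np.zeros(5)
        probs[k - 1] = 1.0
        assert cs.assign_score(cs.ScoreDistribution(probs)) == k


def test_score_distribution_validation():
    with pytest.raises(ValueError):
        cs.ScoreDistribution(np.array([0.5, 0.5, 0.5, -0.5, 0.0]))
    with pytest.raises(ValueError):
        cs.ScoreDistribution(np.array([0.3, 0.3, 0.3, 0.3, 0.3]))


def test_smoothing_zero_gives_one_hot():
    t = smooth_labels([1, 3, 5], 0.0)
    assert np.array_equal(t, np.eye(5)[[0, 2, 4]])


def test_smoothing_targets_interior_and_edge():
    t = smooth_labels([3], 0.1)[0]
    assert t == pytest.approx([0.0, 0.1, 0.8, 0.1, 0.0])
    t5 = smooth_labels([5], 0.1)[0]
    assert t5 == pytest.approx([0.0, 0.0, 0.0, 0.1, 0.9])
    t1 = smooth_labels([1], 0.1)[0]
    assert t1 == pytest.approx([0.9, 0.1, 0.0, 0.0, 0.0])
    assert np.allclose(smooth_labels([1, 2, 3, 4, 5], 0.2).sum(axis=1), 1.0)


def test_train_config_validation():
    with pytest.raises(ValueError):
        cs.TrainConfig(initial_lr=0.0)
    with pytest.raises(ValueError):
        cs.TrainConfig(adjacent_smoothing=0.5)


def test_rule_estimator_extremes():
    clean, _ = cs.render_frame(cs.SyntheticFrameSpec(visible_fraction=1.0, seed=1))
    assert cs.estimate_visible_fraction(stack_channels(clean)) >= 0.97
    dirty, _ = cs.render_frame(cs.SyntheticFrameSpec(visible_fraction=0.0, seed=1))
    assert cs.estimate_visible_fraction(stack_channels(dirty)) <= 0.05


def test_rule_estimator_tracks_ground_truth_fraction():
    """Mean absolute error <= 0.10 over frames spanning the full range."""
    rng = np.random.default_rng(0)
    errors = []
    for i in range(200):
        vf = float(rng.uniform(0, 1))
        frame, gt = cs.render_frame(cs.SyntheticFrameSpec(visible_fraction=vf, seed=20_000 + i))
        est = cs.estimate_visible_fraction(stack_channels(frame))
        errors.append(abs(est - gt.true_visible_fraction))
    assert float(np.mean(errors)) <= 0.10


def test_rule_thresholds_are_tunable():
    frame, _ = cs.render_frame(cs.SyntheticFrameSpec(visible_fraction=0.5, seed=2))
    stack = stack_channels(frame)
    default = cs.estimate_visible_fraction(stack)
    # absurd thresholds classify nothing as occluded
    lax = RuleThresholds(bubble_gray=1.1, bile_b=1.1, debris_gray=-0.1)
    assert cs.estimate_visible_fraction(stack, lax) == 1.0
    assert default < 1.0


def test_train_classifier_input_validation(tiny_model):
    _, stacks, _ = tiny_model
    with pytest.raises(ValueError):
        cs.train_classifier([], [])
    with pytest.raises(ValueError):
        cs.train_classifier(stacks[:4], [3, 3, 3, 3])  # single class
    with pytest.raises(ValueError):
        cs.train_classifier(stacks[:2], [0, 3])  # label out of range


def test_predict_is_a_distribution_and_deterministic(tiny_model):
    model, stacks, _ = tiny_model
    d1 = cs.predict(model, stacks[0])
    d2 = cs.predict(model, stacks[0])
    assert d1.probs.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.array_equal(d1.probs, d2.probs)


def test_model_round_trips_through_disk(tmp_path, tiny_model):
    model, stacks, _ = tiny_model
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = cs.ScoringModel.load(path)
    p_orig = cs.predict_batch(model, stacks[:8])
    p_loaded = cs.predict_batch(loaded, stacks[:8])
    assert np.array_equal(p_orig, p_loaded)
    assert loaded.config == model.config


def test_training_is_reproducible_under_fixed_seed():
    stacks, labels, _ = make_labelled_frames(6, seed0=70_000, image_size=32)
    config = cs.TrainConfig(
        initial_epochs=2, fine_tune_epochs=1, channels=(4, 6, 8), seed=3
    )
    m1 = cs.train_classifier(stacks, labels, config)
    m2 = cs.train_classifier(stacks, labels, config)
    p1 = cs.predict_batch(m1, stacks)
    p2 = cs.predict_batch(m2, stacks)
    assert np.array_equal(p1, p2)
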