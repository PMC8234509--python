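"""Per-frame cleansing scoring.

The 5-point cleansing score reflects the proportion of small-bowel mucosa
visible in a frame (the rest being obscured by air bubbles, bile or
debris):

=====  =======================
score  mucosa visible
=====  =======================
1      < 25 %
2      25 – 50 %
3      50 – 75 %
4      75 – 90 %
5      > 90 %
=====  =======================

Two scorers are provided:

* a **rule-based** estimator that classifies each pixel of the
  preprocessed channel stack as bubble, bile, debris or visible mucosa
  with fixed channel thresholds, and
* a small trainable **convolutional classifier**
  (:func:`train_classifier` / :func:`predict`) that outputs a softmax
  probability for each score; the score with the highest probability is
  assigned to the frame, ties broken toward the lower (worse) score.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import SmallCNN
from .preprocessing import ChannelStack

__all__ = [
    "CleansingScore",
    "ScoreDistribution",
    "RuleThresholds",
    "TrainConfig",
    "ScoringModel",
    "fraction_to_score",
    "estimate_visible_fraction",
    "assign_score",
    "smooth_labels",
    "train_classifier",
    "predict",
    "predict_batch",
]

SCORES = (1, 2, 3, 4, 5)

#: Lower edges of the visible-fraction bins for scores 2, 3 and 4.  A
#: fraction of exactly 0.90 still scores 4 — score 5 requires strictly
#: more than 90 % visible mucosa.
_BIN_EDGES = np.array([0.25, 0.50, 0.75])
_S5_THRESHOLD = 0.90


def fraction_to_score(visible_fraction):
    """Map a visible-mucosa fraction in [0, 1] to a cleansing score 1-5.

    Accepts a scalar or array.  Boundaries: 0.25 -> 2, 0.50 -> 3,
    0.75 -> 4, 0.90 -> 4 (score 5 is strictly > 0.90).
    """
    f = np.asarray(visible_fraction, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("visible fraction must lie in [0, 1]")
    score = 1 + np.digitize(f, _BIN_EDGES, right=False)
    score = np.where(f > _S5_THRESHOLD, 5, score)
    if np.isscalar(visible_fraction) or np.ndim(visible_fraction) == 0:
        return int(score)
    return score.astype(int)


# backwards-friendly alias used in type hints / docs
CleansingScore = int


@dataclass(frozen=True)
class ScoreDistribution:
    """Softmax probability vector over the five cleansing scores."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (5,):
            raise ValueError(f"probs must have shape (5,), got {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "probs", p)

    def __getitem__(self, score: int) -> float:
        """Probability of a score in 1..5."""
        if score not in SCORES:
            raise KeyError(score)
        return float(self.probs[score - 1])


def assign_score(dist: ScoreDistribution) -> int:
    """The score with the highest probability; ties go to the lower score.

    The lower score flags worse cleansing, so a tie is resolved
    conservatively.
    """
    return int(np.argmax(dist.probs)) + 1


@dataclass(frozen=True)
class RuleThresholds:
    """Channel thresholds of the rule-based pixel classifier.

    A pixel is *bubble* when it is bright and nearly achromatic
    (``gray > bubble_gray`` and ``hsv_s < bubble_sat``), *bile* when the
    yellow–blue channel is high (``lab_b > bile_b``) and *debris* when it
    is dark (``gray < debris_gray``).  Everything else counts as visible
    mucosa.
    """

    bubble_gray: float = 0.75
    bubble_sat: float = 0.25
    bile_b: float = 0.65
    debris_gray: float = 0.20


def occluder_masks(
    stack: ChannelStack, thresholds: RuleThresholds = RuleThresholds()
) -> dict[str, np.ndarray]:
    """Per-pixel boolean masks for bubble / bile / debris."""
    t = thresholds
    return {
        "bubble": (stack.gray > t.bubble_gray) & (stack.hsv_s < t.bubble_sat),
        "bile": stack.lab_b > t.bile_b,
        "debris": stack.gray < t.debris_gray,
    }


def estimate_visible_fraction(
    stack: ChannelStack,
    thresholds: RuleThresholds = RuleThresholds(),
    mask: np.ndarray | None = None,
) -> float:
    """Fraction of pixels classified as unobscured mucosa.

    ``mask`` optionally restricts the computation (e.g. to the inscribed
    circle of a real capsule frame).
    """
    m = occluder_masks(stack, thresholds)
    occluded = m["bubble"] | m["bile"] | m["debris"]
    if mask is not None:
        occluded = occluded[mask]
    return float(1.0 - occluded.mean())


@dataclass
class TrainConfig:
    """Training hyper-parameters of the convolutional scorer.

    Training runs in two phases: it starts at ``initial_lr`` and the full
    network is then fine-tuned at ``fine_tune_lr``.  ``adjacent_smoothing``
    implements the allowance for uncertainty between two adjacent scores:
    each neighbouring score receives probability mass ``s`` in the training
    target and the true score keeps the remainder (``1 - 2s`` in the
    interior, ``1 - s`` at scores 1 and 5).
    """

    initial_lr: float = 0.001
    fine_tune_lr: float = 0.00001
    initial_epochs: int = 10
    fine_tune_epochs: int = 5
    batch_size: int = 32
    adjacent_smoothing: float = 0.1
    seed: int = 0
    head_only_initial: bool = False
    channels: tuple[int, int, int] = (16, 32, 64)

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.fine_tune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if not 0 <= self.adjacent_smoothing < 0.5:
            raise ValueError("adjacent_smoothing must lie in [0, 0.5)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def smooth_labels(labels: Sequence[int], smoothing: float) -> np.ndarray:
    """Adjacent-score soft targets, shape (n, 5).

    With smoothing ``s`` the target for score k puts ``s`` on each
    existing neighbour (k-1, k+1) and the rest on k itself, so edge
    scores keep ``1 - s`` and interior scores ``1 - 2s``.  ``s = 0``
    yields one-hot targets.
    """
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty label set")
    if np.any(y < 1) or np.any(y > 5):
        raise ValueError("labels must lie in 1..5")
    n = y.size
    t = np.zeros((n, 5))
    idx = np.arange(n)
    t[idx, y - 1] = 1.0
    if smoothing > 0:
        t[idx, y - 1] -= smoothing * ((y > 1).astype(float) + (y < 5))
        has_lo = y > 1
        t[idx[has_lo], y[has_lo] - 2] = smoothing
        has_hi = y < 5
        t[idx[has_hi], y[has_hi]] = smoothing
    return t


@dataclass
class ScoringModel:
    """A trained 5-class scorer: network weights plus provenance."""

    net: SmallCNN
    config: TrainConfig
    image_size: int

    def save(self, path: str | Path) -> None:
        """Serialize to ``path`` (.npz) with a JSON sidecar (.json)."""
        path = Path(path)
        self.net.save(path)
        cfg = asdict(self.config)
        cfg["channels"] = list(self.config.channels)
        sidecar = {
            "format": "cescore-model-v1",
            "architecture": self.net.describe(),
            "class_order": list(SCORES),
            "image_size": self.image_size,
            "train_config": cfg,
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScoringModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if sidecar.get("format") != "cescore-model-v1":
            raise ValueError(f"{path}: not a cescore model artifact")
        cfg = dict(sidecar["train_config"])
        cfg["channels"] = tuple(cfg["channels"])
        return cls(
            net=SmallCNN.load(path),
            config=TrainConfig(**cfg),
            image_size=int(sidecar["image_size"]),
        )


def _stacks_to_tensor(stacks: Sequence[ChannelStack]) -> np.ndarray:
    """(N, 3, H, W) float32 tensor in channel order (gray, hsv_s, lab_b)."""
    return np.stack(
        [s.as_array().transpose(2, 0, 1) for s in stacks]
    ).astype(np.float32)


def train_classifier(
    stacks: Sequence[ChannelStack],
    labels: Sequence[int],
    config: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> ScoringModel:
    """Train the small convolutional 5-class scorer.

    Phase 1 starts training at ``config.initial_lr``; phase 2 fine-tunes
    the full network at ``config.fine_tune_lr``.  The optimizer is
    RMSProp and the loss categorical cross-entropy against
    adjacent-smoothed targets.  Training is deterministic under a fixed
    seed on fixed hardware.
    """
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty training set")
    if np.any(y < 1) or np.any(y > 5):
        raise ValueError("labels must lie in 1..5")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if len(stacks) != y.size:
        raise ValueError("stacks and labels must have equal length")

    x = _stacks_to_tensor(stacks)
    t = smooth_labels(y, config.adjacent_smoothing)
    rng = np.random.default_rng(config.seed)
    net = SmallCNN(
        in_channels=3,
        channels=config.channels,
        n_classes=5,
        rng=rng,
    )
    net.fit(
        x,
        t,
        lr=config.initial_lr,
        epochs=config.initial_epochs,
        batch_size=config.batch_size,
        rng=rng,
        head_only=config.head_only_initial,
        verbose=verbose,
    )
    net.fit(
        x,
        t,
        lr=config.fine_tune_lr,
        epochs=config.fine_tune_epochs,
        batch_size=config.batch_size,
        rng=rng,
        head_only=False,
        verbose=verbose,
    )
    return ScoringModel(net=net, config=config, image_size=x.shape[-1])


def predict_batch(model: ScoringModel, stacks: Sequence[ChannelStack]) -> np.ndarray:
    """Softmax probabilities for many frames, shape (n, 5)."""
    x = _stacks_to_tensor(stacks)
    if x.shape[-1] != model.image_size:
        raise ValueError(
            f"model expects {model.image_size}x{model.image_size} input, "
            f"got {x.shape[-1]}x{x.shape[-1]}"
        )
    return model.net.predict_proba(x)


def predict(model: ScoringModel, stack: ChannelStack) -> ScoreDistribution:
    """Softmax score distribution for one frame."""
    probs = predict_batch(model, [stack])[0]
    return ScoreDistribution(probs=probs)
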