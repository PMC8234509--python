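import numpy as np
import pytest
from hypothesis import settings

import cescore as cs

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from cescore.preprocessing import stack_channels

#: visible-fraction bins of the five cleansing scores
SCORE_BINS = [(0.0, 0.25), (0.25, 0.50), (0.50, 0.75), (0.75, 0.90), (0.90, 1.0)]


def make_labelled_frames(n_per_class, seed0, image_size=64):
    """Render n_per_class frames per score bin; labels are the achieved bins."""
    rng = np.random.default_rng(seed0)
    stacks, labels, truths = [], [], []
    i = 0
    for lo, hi in SCORE_BINS:
        for _ in range(n_per_class):
            vf = float(rng.uniform(lo, hi))
            frame, gt = cs.render_frame(
                cs.SyntheticFrameSpec(
                    visible_fraction=vf, image_size=image_size, seed=seed0 + i
                )
            )
            i += 1
            stacks.append(stack_channels(frame))
            labels.append(gt.true_score)
            truths.append(gt)
    return stacks, np.array(labels), truths


@pytest.fixture(scope="session")
def tiny_model():
    """A quickly trained scorer at 32x32 for mechanics tests (not accuracy)."""
    stacks, labels, _ = make_labelled_frames(24, seed0=50_000, image_size=32)
    config = cs.TrainConfig(
        initial_epochs=3,
        fine_tune_epochs=1,
        channels=(8, 12, 16),
        seed=7,
    )
    model = cs.train_classifier(stacks, labels, config)
    return model, stacks, labels
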