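"""Synthetic capsule-endoscopy frames with known ground truth.

No public capsule-endoscopy dataset with per-frame cleansing labels
exists, so every downstream stage of this package is exercised on
generated frames: a reddish-pink textured mucosa background partially
covered by the three occluder kinds that reduce mucosal visibility in
real examinations —

* **bubbles**: bright, nearly achromatic discs with a lighter rim,
* **bile**: yellow-green translucent irregular patches (high Lab-b),
* **debris**: dark brown irregular blobs.

Occluders are placed greedily (largest first) until the occluded-pixel
budget implied by the requested visible fraction is met; overlap is
allowed and the budget is measured on the *union* occlusion mask.  The
ground-truth visible fraction of record is computed from that final
union mask, not from the request, and the ground-truth score follows
the 5-point visibility bins.

Whole cases follow a cleanliness trajectory along the frame sequence
(constant, linear, piecewise-linear or reflected random walk), emulating
the slow drift of preparation quality along the small bowel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .preprocessing import Frame
from .scoring import fraction_to_score

__all__ = [
    "SyntheticFrameSpec",
    "SyntheticCaseSpec",
    "GroundTruth",
    "render_frame",
    "generate_case",
    "write_case",
    "TRAJECTORY_TYPES",
]

OCCLUDER_KINDS = ("bubble", "bile", "debris")
TRAJECTORY_TYPES = ("constant", "linear", "piecewise", "random-walk")

#: Mucosa base colour (reddish pink) and low-frequency texture amplitude.
#: Only the *relative* channel statistics matter to the scorers, so the
#: palette is chosen to keep mucosa clear of all rule thresholds.
_MUCOSA_BASE = np.array([195.0, 85.0, 95.0])
_MUCOSA_AMP = np.array([22.0, 14.0, 14.0])


@dataclass(frozen=True)
class SyntheticFrameSpec:
    """Recipe for one synthetic frame."""

    visible_fraction: float
    image_size: int = 64
    occluder_mix: Mapping[str, float] = field(
        default_factory=lambda: {"bubble": 1 / 3, "bile": 1 / 3, "debris": 1 / 3}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.visible_fraction <= 1.0:
            raise ValueError(
                f"visible_fraction must lie in [0, 1], got {self.visible_fraction}"
            )
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        mix = dict(self.occluder_mix)
        unknown = set(mix) - set(OCCLUDER_KINDS)
        if unknown:
            raise ValueError(f"unknown occluder kinds: {sorted(unknown)}")
        weights = np.array([mix.get(k, 0.0) for k in OCCLUDER_KINDS], dtype=float)
        if np.any(weights < 0):
            raise ValueError("occluder_mix weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("occluder_mix weights must sum to 1")
        object.__setattr__(self, "occluder_mix", {k: float(w) for k, w in zip(OCCLUDER_KINDS, weights)})


@dataclass(frozen=True)
class GroundTruth:
    """Label of record for one synthetic frame.

    ``true_visible_fraction`` is the fraction of pixels left unoccluded
    by the final union occlusion mask (the achieved, not the requested,
    fraction); ``true_score`` is its 5-point bin.
    """

    frame_index: int
    true_visible_fraction: float
    true_score: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_visible_fraction <= 1.0:
            raise ValueError("true_visible_fraction must lie in [0, 1]")
        if self.true_score != fraction_to_score(self.true_visible_fraction):
            raise ValueError("true_score inconsistent with true_visible_fraction")


@dataclass(frozen=True)
class SyntheticCaseSpec:
    """Recipe for a whole synthetic case (ordered frame sequence)."""

    n_frames: int
    trajectory: Mapping[str, object] = field(
        default_factory=lambda: {"type": "constant", "value": 0.7}
    )
    image_size: int = 64
    occluder_mix: Mapping[str, float] = field(
        default_factory=lambda: {"bubble": 1 / 3, "bile": 1 / 3, "debris": 1 / 3}
    )
    seed: int = 0
    case_id: str = "case"

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("a case needs at least 3 frames (three segments)")
        traj = dict(self.trajectory)
        ttype = traj.get("type")
        if ttype not in TRAJECTORY_TYPES:
            raise ValueError(
                f"trajectory type must be one of {TRAJECTORY_TYPES}, got {ttype!r}"
            )


# ---------------------------------------------------------------------------
# frame rendering


def _smooth_noise(rng: np.random.Generator, size: int, grid: int = 8) -> np.ndarray:
    """Low-frequency noise field in [-1, 1]: coarse grid upsampled smoothly."""
    coarse = rng.uniform(-1.0, 1.0, size=(grid, grid))
    return np.clip(ndimage.zoom(coarse, size / grid, order=3), -1.0, 1.0)


def _mucosa(rng: np.random.Generator, size: int) -> np.ndarray:
    img = np.empty((size, size, 3))
    for c in range(3):
        img[..., c] = _MUCOSA_BASE[c] + _MUCOSA_AMP[c] * _smooth_noise(rng, size)
    return img


def _disc_mask(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _blob_mask(
    rng: np.random.Generator, size: int, cy: float, cx: float, r: float
) -> np.ndarray:
    """Irregular blob: disc with its radius modulated by angular harmonics."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    wobble = np.zeros_like(theta)
    for k in range(2, 5):
        wobble += rng.uniform(0.0, 0.25) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    radius = r * (1.0 + wobble)
    return dy**2 + dx**2 <= radius**2


def _draw_bubble(img, mask_local, rng, size, cy, cx, r):
    base = rng.uniform(198.0, 215.0)
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    rim = mask_local & (dist >= 0.72 * r)
    fill = mask_local & ~rim
    tint = rng.uniform(-3.0, 3.0, size=3)
    img[fill] = np.clip(base + tint + np.array([0.0, 0.0, 5.0]), 196, 228)
    img[rim] = np.clip(base + 28.0 + tint, 225, 248)


def _draw_bile(img, mask_local, rng):
    colour = np.array(
        [rng.uniform(175.0, 195.0), rng.uniform(165.0, 185.0), rng.uniform(30.0, 55.0)]
    )
    alpha = rng.uniform(0.72, 0.85)
    img[mask_local] = (1 - alpha) * img[mask_local] + alpha * colour


def _draw_debris(img, mask_local, rng):
    colour = np.array(
        [rng.uniform(45.0, 72.0), rng.uniform(26.0, 40.0), rng.uniform(15.0, 30.0)]
    )
    n = int(mask_local.sum())
    img[mask_local] = colour + rng.uniform(-6.0, 6.0, size=(n, 3))
    img[mask_local] = np.clip(img[mask_local], 18.0, 80.0)


def render_frame(
    spec: SyntheticFrameSpec, frame_index: int = 0, case_id: str = "case"
) -> tuple[Frame, GroundTruth]:
    """Render one frame and its ground truth.

    The achieved visible fraction is within 0.02 of the request for
    image sizes >= 64 (the greedy placement stops once the union mask is
    within half a percent of the occluded-pixel budget).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _mucosa(rng, size)
    n_px = size * size
    target = int(round((1.0 - spec.visible_fraction) * n_px))
    tol = max(1, int(round(0.005 * n_px)))

    mask = np.zeros((size, size), dtype=bool)
    weights = np.array([spec.occluder_mix[k] for k in OCCLUDER_KINDS])
    max_r = size / 3.0

    guard = 0
    while target - mask.sum() > tol and guard < 20 * n_px:
        guard += 1
        deficit = int(target - mask.sum())
        # centre on an uncovered pixel so every placement makes progress
        flat_uncovered = np.flatnonzero(~mask)
        cy, cx = np.unravel_index(rng.choice(flat_uncovered), mask.shape)
        kind = OCCLUDER_KINDS[rng.choice(len(OCCLUDER_KINDS), p=weights)]
        r = min(max_r, max(1.2, 0.92 * math.sqrt(deficit / math.pi)))
        shape_rng = np.random.default_rng(rng.integers(2**31))
        for _ in range(8):
            if kind == "bubble":
                shape = _disc_mask(size, cy, cx, r)
            else:
                shape = _blob_mask(shape_rng, size, cy, cx, r)
            overshoot = int((mask | shape).sum()) - target
            if overshoot <= tol or r <= 1.3:
                break
            r = max(1.2, r / 1.6)
        mask |= shape
        local = shape
        if kind == "bubble":
            _draw_bubble(img, local, rng, size, cy, cx, r)
        elif kind == "bile":
            _draw_bile(img, local, rng)
        else:
            _draw_debris(img, local, rng)

    if spec.visible_fraction == 0.0 and not mask.all():
        # full occlusion requested: paint the stragglers as debris
        rest = ~mask
        _draw_debris(img, rest, rng)
        mask |= rest

    achieved = float(1.0 - mask.mean())
    frame = Frame(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        case_id=case_id,
        frame_index=frame_index,
    )
    gt = GroundTruth(
        frame_index=frame_index,
        true_visible_fraction=achieved,
        true_score=fraction_to_score(achieved),
    )
    return frame, gt


# ---------------------------------------------------------------------------
# case generation


def _trajectory_fractions(
    trajectory: Mapping[str, object], n: int, rng: np.random.Generator
) -> np.ndarray:
    traj = dict(trajectory)
    ttype = traj["type"]
    if ttype == "constant":
        f = np.full(n, float(traj.get("value", 0.7)))
    elif ttype == "linear":
        f = np.linspace(float(traj.get("start", 1.0)), float(traj.get("end", 0.0)), n)
    elif ttype == "piecewise":
        bp = np.asarray(traj.get("breakpoints", [0.0, 1.0]), dtype=float)
        vals = np.asarray(traj.get("values", [0.9, 0.3]), dtype=float)
        if bp.size != vals.size or bp.size < 2:
            raise ValueError("piecewise trajectory needs matching breakpoints/values")
        pos = np.linspace(0.0, 1.0, n)
        f = np.interp(pos, bp, vals)
    elif ttype == "random-walk":
        start = float(traj.get("start", 0.7))
        step_sd = float(traj.get("step_sd", 0.05))
        steps = rng.normal(0.0, step_sd, size=n - 1)
        f = np.empty(n)
        f[0] = start
        for i in range(1, n):
            f[i] = f[i - 1] + steps[i - 1]
        # reflect into [0, 1]
        f = np.abs(f)
        f = 1.0 - np.abs(1.0 - f)
    else:  # pragma: no cover - caught by spec validation
        raise ValueError(f"unknown trajectory type {ttype!r}")
    return np.clip(f, 0.0, 1.0)


def generate_case(
    spec: SyntheticCaseSpec, out_dir: str | Path | None = None
) -> tuple[list[Frame], list[GroundTruth]]:
    """Generate a whole case; optionally write frames + manifest + truth.

    Per-frame seeds are derived from the case seed, so the case is
    deterministic as a whole and each frame is deterministic on its own.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = _trajectory_fractions(spec.trajectory, spec.n_frames, rng)
    frame_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_frames)
    frames: list[Frame] = []
    truths: list[GroundTruth] = []
    for i, (frac, fseed) in enumerate(zip(fractions, frame_seeds)):
        fspec = SyntheticFrameSpec(
            visible_fraction=float(frac),
            image_size=spec.image_size,
            occluder_mix=spec.occluder_mix,
            seed=int(fseed),
        )
        frame, gt = render_frame(fspec, frame_index=i, case_id=spec.case_id)
        frames.append(frame)
        truths.append(gt)
    if out_dir is not None:
        write_case(frames, truths, out_dir)
    return frames, truths


def write_case(
    frames: Sequence[Frame], truths: Sequence[GroundTruth], out_dir: str | Path
) -> Path:
    """Write PNG frames, a manifest CSV and a ground-truth CSV.

    Layout: ``<out_dir>/<case_id>/frame_XXXXX.png`` plus
    ``manifest.csv`` (case_id, frame_index, filename) and
    ``ground_truth.csv`` (frame_index, true_visible_fraction, true_score).
    Returns the case directory.
    """
    case_id = frames[0].case_id
    case_dir = Path(out_dir) / case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for frame, gt in zip(frames, truths):
        fname = f"frame_{frame.frame_index:05d}.png"
        Image.fromarray(frame.pixels).save(case_dir / fname)
        manifest_rows.append(f"{case_id},{frame.frame_index},{fname}")
        truth_rows.append(
            f"{gt.frame_index},{gt.true_visible_fraction:.6f},{gt.true_score}"
        )
    (case_dir / "manifest.csv").write_text(
        "case_id,frame_index,filename\n" + "\n".join(manifest_rows) + "\n"
    )
    (case_dir / "ground_truth.csv").write_text(
        "frame_index,true_visible_fraction,true_score\n" + "\n".join(truth_rows) + "\n"
    )
    return case_dir
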