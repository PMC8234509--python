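"""Case-level aggregation and clinical grading.

The case-level *final cleansing score* is the arithmetic mean of the
per-frame scores.  For clinical grading the case is split into three
contiguous thirds in time order (proximal, middle, distal small bowel);
each segment receives a grade 1–4 from the fraction of its frames
showing more than 50 % invisible mucosa, and the sum of the three
segmental grades maps to an overall letter grade:

=========  ================================  =============
segmental  frames with >50% invisible        grade
=========  ================================  =============
grade 1    < 5 %
grade 2    5 – 15 %
grade 3    15 – 25 %
grade 4    > 25 %
=========  ================================  =============

Overall: A for sums 3–5, B for 6–8, C for 9–12; preparation is
clinically adequate for grades A and B and inadequate for C.

With only integer scores available, ">50 % invisible mucosa" is
operationalised as score <= 2 (the score bins put the 50 % visibility
boundary exactly between scores 2 and 3); when raw estimated visible
fractions are available a direct ``visible < 0.5`` test can be used
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CaseScoring",
    "GradingResult",
    "final_score",
    "split_segments",
    "invisible_fraction",
    "segmental_grade",
    "overall_grade",
    "grade_case",
]


def _check_scores(scores: Sequence[int]) -> np.ndarray:
    s = np.asarray(scores, dtype=int)
    if s.size == 0:
        raise ValueError("empty score sequence")
    if np.any(s < 1) or np.any(s > 5):
        raise ValueError("scores must lie in 1..5")
    return s


@dataclass(frozen=True)
class CaseScoring:
    """Ordered per-frame scores of one case plus their mean."""

    scores: np.ndarray
    case_id: str = "case"

    def __post_init__(self) -> None:
        s = _check_scores(self.scores)
        if s.size < 3:
            raise ValueError("a case needs at least 3 frames")
        object.__setattr__(self, "scores", s)

    @property
    def n_frames(self) -> int:
        return int(self.scores.size)

    @property
    def final_score(self) -> float:
        return final_score(self.scores)


@dataclass(frozen=True)
class GradingResult:
    """Segmental grades, their sum, the overall letter and adequacy."""

    segmental_grades: tuple[int, int, int]
    grade_sum: int
    overall_grade: str
    adequate: bool
    invisible_fractions: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.grade_sum != sum(self.segmental_grades):
            raise ValueError("grade_sum must equal the sum of segmental grades")


def final_score(scores: Sequence[int]) -> float:
    """Arithmetic mean of per-frame scores (displayed to 1 decimal)."""
    return float(_check_scores(scores).mean())


def split_segments(scores: Sequence[int] | np.ndarray) -> list[np.ndarray]:
    """Split a case into proximal/middle/distal thirds in time order.

    When the frame count is not divisible by 3, the earlier (proximal)
    segments receive the extra frames; the three segments partition the
    case exactly.
    """
    s = np.asarray(scores)
    if s.size < 3:
        raise ValueError("a case needs at least 3 frames to form segments")
    return list(np.array_split(s, 3))


def invisible_fraction(
    segment: Sequence[int] | np.ndarray,
    visible_fractions: np.ndarray | None = None,
) -> float:
    """Fraction of a segment's frames with >50 % invisible mucosa.

    From integer scores this is the fraction of frames scoring 1 or 2;
    if raw visible fractions are supplied they are tested directly
    against 0.5.
    """
    if visible_fractions is not None:
        v = np.asarray(visible_fractions, dtype=float)
        if v.size == 0:
            raise ValueError("empty segment")
        return float((v < 0.5).mean())
    s = _check_scores(segment)
    return float((s <= 2).mean())


def segmental_grade(frac: float) -> int:
    """Grade 1–4 from the fraction of >50%-invisible frames.

    Bins are lower-inclusive; grade 4 is strictly above 25 %
    (<5% -> 1, 5–15% -> 2, 15–25% -> 3, >25% -> 4, with 0.25 itself
    falling in grade 3).
    """
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {frac}")
    if frac < 0.05:
        return 1
    if frac < 0.15:
        return 2
    if frac <= 0.25:
        return 3
    return 4


def overall_grade(segmental_grades: Sequence[int]) -> GradingResult:
    """Letter grade A/B/C and adequacy from three segmental grades."""
    g = tuple(int(x) for x in segmental_grades)
    if len(g) != 3:
        raise ValueError("exactly three segmental grades expected")
    if any(x < 1 or x > 4 for x in g):
        raise ValueError("segmental grades must lie in 1..4")
    total = sum(g)
    if total <= 5:
        letter = "A"
    elif total <= 8:
        letter = "B"
    else:
        letter = "C"
    return GradingResult(
        segmental_grades=g,
        grade_sum=total,
        overall_grade=letter,
        adequate=letter in ("A", "B"),
    )


def grade_case(
    scores: Sequence[int],
    visible_fractions: Sequence[float] | None = None,
) -> GradingResult:
    """Full grading of one case from its ordered per-frame scores.

    ``visible_fractions`` (same length/order as ``scores``) switches the
    >50 %-invisible test from the score-bin proxy to the raw fractions.
    """
    s = _check_scores(scores)
    if s.size < 3:
        raise ValueError("a case needs at least 3 frames")
    if visible_fractions is not None:
        v = np.asarray(visible_fractions, dtype=float)
        if v.size != s.size:
            raise ValueError("visible_fractions length must match scores")
        seg_fracs = [
            invisible_fraction(seg_s, visible_fractions=seg_v)
            for seg_s, seg_v in zip(split_segments(s), split_segments(v))
        ]
    else:
        seg_fracs = [invisible_fraction(seg) for seg in split_segments(s)]
    grades = tuple(segmental_grade(f) for f in seg_fracs)
    result = overall_grade(grades)
    return GradingResult(
        segmental_grades=result.segmental_grades,
        grade_sum=result.grade_sum,
        overall_grade=result.overall_grade,
        adequate=result.adequate,
        invisible_fractions=tuple(float(f) for f in seg_fracs),
    )
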