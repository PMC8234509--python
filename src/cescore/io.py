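"""Readers and writers for the pipeline's on-disk formats.

All interchange formats are plain text: CSV manifests / labels / scores,
JSON case reports and metric reports, PNG frames.  Readers validate
strictly and report the offending row or column, so a malformed file
fails early and loudly rather than corrupting a downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .preprocessing import Frame

__all__ = [
    "CaseReport",
    "read_manifest",
    "load_frames",
    "read_labels",
    "read_scores",
    "write_scores",
    "write_report",
    "read_report",
]

MANIFEST_COLUMNS = ["case_id", "frame_index", "filename"]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a frame manifest (case_id, frame_index, filename).

    Frame indices must be 0-based and contiguous within each case; a gap
    is reported with the missing index.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, MANIFEST_COLUMNS, path)
    if df.empty:
        raise SchemaError(f"{path}: manifest is empty")
    try:
        df["frame_index"] = df["frame_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-integer frame_index ({exc})") from None
    for case_id, grp in df.groupby("case_id", sort=False):
        idx = np.sort(grp["frame_index"].to_numpy())
        expected = np.arange(idx.size)
        if not np.array_equal(idx, expected):
            missing = sorted(set(expected) - set(idx))
            what = f"missing frame_index {missing[0]}" if missing else "duplicate or out-of-range frame_index"
            raise SchemaError(f"{path}: case {case_id!r}: {what}")
    return df[MANIFEST_COLUMNS]


def load_frames(manifest: pd.DataFrame, root: str | Path) -> list[Frame]:
    """Load the PNG/JPEG frames listed in a manifest, in index order."""
    root = Path(root)
    frames = []
    for _, row in manifest.sort_values(["case_id", "frame_index"]).iterrows():
        img = np.asarray(Image.open(root / row["filename"]).convert("RGB"))
        frames.append(
            Frame(pixels=img, case_id=str(row["case_id"]), frame_index=int(row["frame_index"]))
        )
    return frames


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a per-frame label table (frame_index, score in 1..5)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["frame_index", "score"], path)
    bad = df.index[(df["score"] < 1) | (df["score"] > 5) | (df["score"] % 1 != 0)]
    if len(bad):
        row = int(bad[0])
        raise SchemaError(
            f"{path}: row {row + 2}: score {df.loc[row, 'score']!r} outside 1..5"
        )
    df["score"] = df["score"].astype(int)
    return df


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a per-frame score table (frame_index, [p1..p5,] score)."""
    df = read_labels(path)
    probs = [f"p{i}" for i in range(1, 6)]
    if all(p in df.columns for p in probs):
        p = df[probs].to_numpy(dtype=float)
        bad = np.flatnonzero((p < 0).any(axis=1) | (np.abs(p.sum(axis=1) - 1) > 1e-6))
        if bad.size:
            raise SchemaError(
                f"{path}: row {bad[0] + 2}: probabilities do not form a distribution"
            )
    return df


def write_scores(
    path: str | Path,
    frame_indices: Sequence[int],
    scores: Sequence[int],
    probs: np.ndarray | None = None,
    visible_fractions: Sequence[float] | None = None,
) -> None:
    """Write a per-frame score CSV (optionally with p1..p5 and fractions)."""
    data: dict[str, object] = {"frame_index": list(frame_indices)}
    if probs is not None:
        arr = np.asarray(probs, dtype=float)
        for i in range(5):
            data[f"p{i + 1}"] = [f"{v:.6f}" for v in arr[:, i]]
    if visible_fractions is not None:
        data["visible_fraction"] = [f"{v:.6f}" for v in visible_fractions]
    data["score"] = [int(s) for s in scores]
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass(frozen=True)
class CaseReport:
    """The per-case clinical report emitted by the pipeline."""

    case_id: str
    n_frames: int
    final_score: float
    segmental_grades: tuple[int, int, int]
    invisible_fractions: tuple[float, float, float]
    grade_sum: int
    overall_grade: str
    adequate: bool
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1.0 <= self.final_score <= 5.0:
            raise ValueError("final_score must lie in [1, 5]")
        if self.overall_grade not in ("A", "B", "C"):
            raise ValueError("overall_grade must be A, B or C")
        if "scorer" not in self.provenance:
            raise ValueError("provenance must at least name the scorer")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmental_grades"] = list(self.segmental_grades)
        d["invisible_fractions"] = list(self.invisible_fractions)
        d["provenance"] = dict(self.provenance)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "CaseReport":
        d = dict(d)
        d["segmental_grades"] = tuple(d["segmental_grades"])
        d["invisible_fractions"] = tuple(d["invisible_fractions"])
        return cls(**d)


def write_report(report: CaseReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def read_report(path: str | Path) -> CaseReport:
    return CaseReport.from_dict(json.loads(Path(path).read_text()))
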