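"""Contralateral ΔT measurement and the composite thermal score.

The hottest point within the two breast regions is compared against its
mirror site — same row, column reflected about the central axis — on the
contralateral breast.  The thermal score adds the vascularity grade to
that temperature difference in °C; scores of at least 2.5 are called
anomalous, lower scores healthy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import Thermogram
from .segmentation import BreastSegmentation
from .vascularity import VascularAnalysis

__all__ = [
    "DEFAULT_THRESHOLD",
    "VALID_GRADES",
    "ThermalScore",
    "find_hotspot",
    "mirror_site",
    "compute_delta_t",
    "thermal_score",
    "classify",
    "score_thermogram",
]

DEFAULT_THRESHOLD = 2.5
VALID_GRADES = (0, 2, 3, 4)


@dataclass
class ThermalScore:
    """Per-patient scoring result: grade + ΔT and the binary call."""

    grade: int
    delta_t: float
    score: float
    classification: str  # "healthy" | "anomaly"
    threshold: float = DEFAULT_THRESHOLD
    hotspot: Optional[tuple[int, int]] = None
    t_hot: Optional[float] = None
    mirror: Optional[tuple[int, int]] = None
    t_mirror: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "grade": self.grade,
            "delta_t": self.delta_t,
            "score": self.score,
            "classification": self.classification,
            "threshold": self.threshold,
            "hotspot": None if self.hotspot is None else list(self.hotspot),
            "mirror_site": None if self.mirror is None else list(self.mirror),
        }


def find_hotspot(
    t: Thermogram, seg: BreastSegmentation
) -> tuple[int, int, float]:
    """Hottest pixel over the union of the breast masks.

    Ties break toward the smallest row, then the smallest column, so the
    result is deterministic on flat fields.
    """
    union = seg.left_mask | seg.right_mask
    if not union.any():
        raise ValueError("empty breast mask union")
    temp = np.where(union, t.temperature, -np.inf)
    r, c = np.unravel_index(int(np.argmax(temp)), temp.shape)
    return int(r), int(c), float(t.temperature[r, c])


def mirror_site(
    p: tuple[int, int], seg: BreastSegmentation
) -> tuple[int, int]:
    """Mirror-image site on the contralateral breast.

    Same row; column reflected about the central axis and clamped into
    the contralateral rectangle.  A point on the axis maps to itself
    (degenerate; a warning is emitted).
    """
    r, c = p
    if not (seg.left_mask[r, c] or seg.right_mask[r, c]):
        raise ValueError(f"point {p} lies outside both breast masks")
    axis = seg.central_axis
    c_mirror = 2 * axis - c
    if c == axis:
        warnings.warn("hotspot lies on the central axis; mirror site is itself")
        return r, c
    if c < axis:  # left breast -> clamp into right rectangle
        c_mirror = min(max(c_mirror, axis), seg.right_limit)
    else:  # right breast -> clamp into left rectangle
        c_mirror = min(max(c_mirror, seg.left_limit), axis - 1)
    return r, int(c_mirror)


def compute_delta_t(t: Thermogram, seg: BreastSegmentation) -> float:
    """ΔT = temperature at the hotspot minus at its mirror site, >= 0.

    The hotspot is the in-mask global maximum, so the mirror value can
    only exceed it through mask asymmetry after clamping; the clamp at 0
    guards that edge case.
    """
    r, c, t_hot = find_hotspot(t, seg)
    mr, mc = mirror_site((r, c), seg)
    return max(0.0, t_hot - float(t.temperature[mr, mc]))


def thermal_score(
    grade: int,
    delta_t: float,
    threshold: float = DEFAULT_THRESHOLD,
) -> ThermalScore:
    """Compose the thermal score: vascularity grade plus ΔT in °C."""
    if grade not in VALID_GRADES:
        raise ValueError(f"grade must be one of {VALID_GRADES}, got {grade}")
    if not (np.isfinite(delta_t) and delta_t >= 0):
        raise ValueError(f"delta_t must be finite and >= 0, got {delta_t}")
    score = grade + delta_t
    return ThermalScore(
        grade=grade,
        delta_t=float(delta_t),
        score=float(score),
        classification=classify(score, threshold),
        threshold=threshold,
    )


def classify(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Binary screening call: anomaly iff score >= threshold."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return "anomaly" if score >= threshold else "healthy"


def score_thermogram(
    t: Thermogram,
    seg: BreastSegmentation,
    vasc: VascularAnalysis,
    threshold: float = DEFAULT_THRESHOLD,
) -> ThermalScore:
    """Full scoring stage: hotspot, mirror site, ΔT, score, call."""
    if vasc.grade is None:
        raise ValueError("vascular analysis has no grade; run grade_vascularity")
    r, c, t_hot = find_hotspot(t, seg)
    mr, mc = mirror_site((r, c), seg)
    delta_t = max(0.0, t_hot - float(t.temperature[mr, mc]))
    result = thermal_score(vasc.grade, delta_t, threshold)
    result.hotspot = (r, c)
    result.t_hot = t_hot
    result.mirror = (mr, mc)
    result.t_mirror = float(t.temperature[mr, mc])
    return result
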