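"""End-to-end single-patient and cohort analysis.

``analyze_thermogram`` chains the four stages — rendering/IO,
projection-profile segmentation, CIELAB vascularity grading, and
contralateral ΔT scoring — into one call; ``run_cohort`` maps it over
simulated or loaded cases and returns a table ready for the screening
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .io import ColormapSpec, Thermogram
from .phantom import PhantomCase
from .scoring import DEFAULT_THRESHOLD, ThermalScore, score_thermogram
from .segmentation import BreastSegmentation, SegmentationConfig, segment_thermogram
from .vascularity import VascularAnalysis, VascularityConfig, analyze_vascularity

__all__ = ["RunConfig", "PatientResult", "analyze_thermogram", "run_cohort"]


@dataclass
class RunConfig:
    """All pipeline tunables; round-trips losslessly through YAML."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    vascularity: VascularityConfig = field(default_factory=VascularityConfig)
    threshold: float = DEFAULT_THRESHOLD

    def to_dict(self) -> dict:
        seg, vasc = self.segmentation, self.vascularity
        return {
            "hpp_threshold_frac": seg.hpp_threshold_frac,
            "scan_region_frac": seg.scan_region_frac,
            "c_small": seg.c_small,
            "c_large": seg.c_large,
            "edge_threshold": seg.edge_threshold,
            "colormap": {
                "name": seg.colormap.name,
                "t_min": seg.colormap.t_min,
                "t_max": seg.colormap.t_max,
            },
            "t_absent": vasc.t_absent,
            "t_significant": vasc.t_significant,
            "red_percentile": vasc.red_percentile,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cm = d.get("colormap", {})
        seg = SegmentationConfig(
            hpp_threshold_frac=d.get("hpp_threshold_frac", 0.15),
            scan_region_frac=d.get("scan_region_frac", 0.40),
            c_small=d.get("c_small", 0.45),
            c_large=d.get("c_large", 0.35),
            edge_threshold=d.get("edge_threshold", "otsu"),
            colormap=ColormapSpec(
                name=cm.get("name", "thermo_rainbow_v1"),
                t_min=cm.get("t_min", 31.0),
                t_max=cm.get("t_max", 36.0),
            ),
        )
        vasc = VascularityConfig(
            t_absent=d.get("t_absent", 0.01),
            t_significant=d.get("t_significant", 0.10),
            red_percentile=d.get("red_percentile", 2.0),
        )
        return cls(
            segmentation=seg,
            vascularity=vasc,
            threshold=d.get("threshold", DEFAULT_THRESHOLD),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class PatientResult:
    """All per-patient pipeline outputs."""

    patient_id: str
    segmentation: BreastSegmentation
    vascularity: VascularAnalysis
    score: ThermalScore

    def to_dict(self) -> dict:
        d = {"patient_id": self.patient_id}
        d.update(self.score.to_dict())
        d["left_fraction"] = self.vascularity.left_fraction
        d["right_fraction"] = self.vascularity.right_fraction
        d["asymmetry"] = self.vascularity.asymmetry
        d["limits"] = {
            "upper": self.segmentation.upper_limit,
            "lower": self.segmentation.lower_limit,
            "left": self.segmentation.left_limit,
            "right": self.segmentation.right_limit,
            "central_axis": self.segmentation.central_axis,
        }
        return d


def analyze_thermogram(
    t: Thermogram, config: Optional[RunConfig] = None
) -> PatientResult:
    """Run segmentation, vascularity and scoring on one thermogram."""
    config = config or RunConfig()
    if t.rgb is None:
        from .io import render_rgb

        t = render_rgb(t, config.segmentation.colormap)
    seg = segment_thermogram(t, config.segmentation)
    vasc = analyze_vascularity(t.rgb, seg, config.vascularity)
    score = score_thermogram(t, seg, vasc, config.threshold)
    return PatientResult(
        patient_id=t.meta.patient_id,
        segmentation=seg,
        vascularity=vasc,
        score=score,
    )


def run_cohort(
    cases: Sequence[PhantomCase], config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Score every case; returns a screening-ready table.

    Columns: patient_id, grade, delta_t, score, classification,
    truth_label — directly consumable by :func:`stats.evaluate_cohort`.
    """
    config = config or RunConfig()
    records = []
    for case in cases:
        result = analyze_thermogram(case.thermogram, config)
        records.append(
            {
                "patient_id": case.patient_id,
                "grade": result.score.grade,
                "delta_t": result.score.delta_t,
                "score": result.score.score,
                "classification": result.score.classification,
                "truth_label": case.truth.true_label,
            }
        )
    return pd.DataFrame.from_records(records)
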