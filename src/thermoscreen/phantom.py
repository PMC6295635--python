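"""Synthetic frontal breast thermogram phantoms with known ground truth.

The phantom emulates the acquisition conditions of a clinical screening
thermogram: a warm torso silhouette (skin base 33.5 °C) on a cooler
ambient background (24 °C, the controlled room temperature), two breast
regions bounded below by an infra-mammary fold that shows up as a dense
horizontal edge line, an axillary shoulder step, optional focal hotspots
with a configurable peak ΔT, branching vascular trees elevated above
local skin so the shipped palette renders them in the red/orange range,
and Gaussian sensor noise (default 0.07 °C, a typical uncooled
microbolometer sensitivity).

Every geometric feature is recorded in a :class:`PhantomTruth` so each
pipeline stage — fold detection, axis detection, color classification,
ΔT measurement, grading and the end-to-end classifier — can be tested
against known answers without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import draw
from skimage.morphology import disk

from .io import ColormapSpec, Thermogram, ThermogramMeta, render_rgb

__all__ = [
    "HotspotSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
]

#: A vessel pixel is elevated this many °C above local skin; at the
#: default render range it lands in the orange/red part of the palette.
VESSEL_ELEVATION_C = 2.0

#: Vessel "density" d maps to a target coverage of d * this fraction of
#: the half-chest region, so density 1.0 comfortably exceeds the
#: one-third-of-the-breast-area bound of vascularity grade 4.
MAX_VESSEL_COVERAGE = 0.45


@dataclass
class HotspotSpec:
    """A focal Gaussian warm spot on one breast."""

    side: str  # "left" | "right"
    delta_t: float  # peak elevation above local skin, °C
    sigma: float = 6.0  # Gaussian width in pixels
    center: Optional[tuple[int, int]] = None  # defaults to the breast center

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left or right, got {self.side!r}")
        if self.delta_t < 0:
            raise ValueError("hotspot delta_t must be >= 0")


@dataclass
class PhantomSpec:
    """Geometry, thermal and noise parameters of one phantom.

    Defaults place the infra-mammary fold at 75 % of the image height and
    the axilla at 30 %, which is the geometry the projection-profile
    height rule reconstructs under its default coefficients.
    """

    rows: int = 240
    cols: int = 200
    ambient_c: float = 24.0
    skin_base_c: float = 33.5
    fold_row: Optional[int] = None  # default 0.75 * rows
    axilla_row: Optional[int] = None  # default 0.30 * rows
    torso_center_col: Optional[int] = None  # default cols // 2
    torso_half_width: Optional[int] = None  # default 0.30 * cols
    breast_radii: Optional[tuple[int, int]] = None  # (rx, ry) in px
    hotspot: Optional[HotspotSpec] = None
    vascular_density: tuple[float, float] = (0.3, 0.3)  # (left, right) in [0,1]
    vascular_symmetric: bool = True
    fold_depth_c: float = 6.0
    breast_cool_c: float = 0.4
    noise_sd: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_row is None:
            self.fold_row = int(0.75 * self.rows)
        if self.axilla_row is None:
            self.axilla_row = int(0.30 * self.rows)
        if self.torso_center_col is None:
            self.torso_center_col = self.cols // 2
        if self.torso_half_width is None:
            self.torso_half_width = int(0.30 * self.cols)
        if self.breast_radii is None:
            rx = int(0.42 * self.torso_half_width)
            ry = int(0.28 * (self.fold_row - self.axilla_row))
            self.breast_radii = (rx, ry)
        if not (0 < self.axilla_row < self.fold_row < self.rows - 2):
            raise ValueError("require 0 < axilla_row < fold_row < rows - 2")
        if self.torso_center_col - self.torso_half_width < 1 or (
            self.torso_center_col + self.torso_half_width >= self.cols - 1
        ):
            raise ValueError("torso geometry outside image")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for d in self.vascular_density:
            if not (0.0 <= d <= 1.0):
                raise ValueError("vascular densities must be in [0, 1]")

    @property
    def breast_centers(self) -> dict[str, tuple[int, int]]:
        """(row, col) centers of the two breast ellipses."""
        row = (self.axilla_row + 2 * self.fold_row) // 3
        dx = self.torso_half_width // 2
        return {
            "left": (row, self.torso_center_col - dx),
            "right": (row, self.torso_center_col + dx),
        }


@dataclass
class PhantomTruth:
    """Ground truth recorded while drawing the phantom."""

    fold_row: int
    axilla_row: int
    center_col: int
    left_breast_mask: np.ndarray
    right_breast_mask: np.ndarray
    left_vessel_mask: np.ndarray
    right_vessel_mask: np.ndarray
    true_grade: int
    true_delta_t: float
    true_label: str  # "healthy" | "anomaly"


@dataclass
class PhantomCase:
    """One simulated patient in a cohort."""

    patient_id: str
    thermogram: Thermogram
    truth: PhantomTruth


def _mirror_mask(mask: np.ndarray, center_col: int) -> np.ndarray:
    """Reflect a boolean mask about a column."""
    out = np.zeros_like(mask)
    src = np.arange(mask.shape[1])
    dst = 2 * center_col - src
    ok = (dst >= 0) & (dst < mask.shape[1])
    out[:, dst[ok]] = mask[:, src[ok]]
    return out


def _vessel_tree(
    region: np.ndarray,
    seed_points: np.ndarray,
    target_frac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random branching polylines dilated to ~3 px width.

    Branches start at random seed points (inside the breast ellipse) and
    random-walk across the half-chest region until the dilated tree
    covers ``target_frac`` of it.
    """
    skel = np.zeros_like(region)
    area = int(region.sum())
    target = target_frac * area
    if target <= 0 or len(seed_points) == 0:
        return skel
    rows_rc = np.argwhere(region)
    r_lo, c_lo = rows_rc.min(axis=0)
    r_hi, c_hi = rows_rc.max(axis=0)
    for branch in range(1, 601):
        r, c = seed_points[rng.integers(len(seed_points))]
        ang = rng.uniform(0.0, 2.0 * np.pi)
        for _ in range(int(rng.integers(4, 10))):
            length = int(rng.integers(5, 11))
            r2 = int(np.clip(round(r + length * np.sin(ang)), r_lo, r_hi))
            c2 = int(np.clip(round(c + length * np.cos(ang)), c_lo, c_hi))
            rr, cc = draw.line(int(r), int(c), r2, c2)
            skel[rr, cc] = True
            r, c = r2, c2
            ang += rng.normal(0.0, 0.7)
        if branch <= 2 or branch % 8 == 0:
            if (ndimage.binary_dilation(skel, structure=disk(1)) & region).sum() >= target:
                break
    return ndimage.binary_dilation(skel, structure=disk(1)) & region


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.ellipse(center[0], center[1], radii[1], radii[0], shape=shape)
    mask[rr, cc] = True
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[Thermogram, PhantomTruth]:
    """Draw one phantom; deterministic for a given spec (incl. seed).

    Assembly: ambient field + smoothed torso plateau + slightly cooler
    breast mounds + a cold infra-mammary crease at ``fold_row`` + a
    thermal elevation layer (pointwise max of the hotspot Gaussian and
    the vessel elevation, so a vessel running under a hotspot never
    overshoots the intended peak) + Gaussian noise.  The RGB rendering
    spans skin_base ± 2.5 °C so skin sits mid-palette (green) and
    elevated structures reach the orange/red end.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols
    c0 = spec.torso_center_col
    hw = spec.torso_half_width
    rgrid, cgrid = np.mgrid[0:rows, 0:cols]

    # torso silhouette: shoulders narrower above the axilla
    body = np.zeros((rows, cols), dtype=bool)
    shoulder_row = max(2, spec.axilla_row - int(0.12 * rows))
    body[spec.axilla_row :, abs_le(cgrid[0], c0, hw)] = True
    body[shoulder_row : spec.axilla_row, abs_le(cgrid[0], c0, int(0.55 * hw))] = True

    base = spec.ambient_c + (spec.skin_base_c - spec.ambient_c) * ndimage.gaussian_filter(
        body.astype(float), sigma=1.2
    )

    # breast mounds: gently cooler elliptical Gaussians (no hard edge)
    centers = spec.breast_centers
    rx, ry = spec.breast_radii
    for side in ("left", "right"):
        br, bc = centers[side]
        base -= spec.breast_cool_c * np.exp(
            -(((rgrid - br) / ry) ** 2 + ((cgrid - bc) / rx) ** 2)
        )

    # infra-mammary fold: cold crease spanning both breasts
    fold = np.zeros((rows, cols), dtype=bool)
    span = hw // 2 + rx
    fold[spec.fold_row, c0 - span : c0 + span + 1] = True
    base -= spec.fold_depth_c * ndimage.gaussian_filter(fold.astype(float), sigma=0.7)

    # breast ellipses (truth masks and vessel seed regions)
    breast_masks = {
        side: _ellipse_mask((rows, cols), centers[side], (rx, ry))
        for side in ("left", "right")
    }

    # hotspot bump
    bump = np.zeros((rows, cols))
    hotspot_center = None
    if spec.hotspot is not None and spec.hotspot.delta_t > 0:
        hotspot_center = (
            spec.hotspot.center
            if spec.hotspot.center is not None
            else centers[spec.hotspot.side]
        )
        hr, hc = hotspot_center
        if not (0 <= hr < rows and 0 <= hc < cols):
            raise ValueError("hotspot center outside image")
        bump = spec.hotspot.delta_t * np.exp(
            -((rgrid - hr) ** 2 + (cgrid - hc) ** 2) / (2.0 * spec.hotspot.sigma ** 2)
        )

    # half-chest regions the vascular trees may roam
    chest_rows = (cgrid * 0).astype(bool)
    chest_rows[spec.axilla_row + 3 : spec.fold_row - 2, :] = True
    left_region = chest_rows & body & (cgrid < c0) & (cgrid >= c0 - hw + 3)
    right_region = chest_rows & body & (cgrid >= c0) & (cgrid <= c0 + hw - 3)

    dl, dr = spec.vascular_density
    left_vessels = _vessel_tree(
        left_region,
        np.argwhere(breast_masks["left"]),
        MAX_VESSEL_COVERAGE * dl,
        rng,
    )
    if spec.vascular_symmetric:
        right_vessels = _mirror_mask(left_vessels, c0) & right_region
    else:
        right_vessels = _vessel_tree(
            right_region,
            np.argwhere(breast_masks["right"]),
            MAX_VESSEL_COVERAGE * dr,
            rng,
        )

    # keep the hotspot's contralateral mirror site clean so the measured
    # ΔT reflects the specified peak, not an unlucky vessel crossing
    if hotspot_center is not None:
        hr, hc = hotspot_center
        mirror_clear = ((rgrid - hr) ** 2 + (cgrid - (2 * c0 - hc)) ** 2) <= 6 ** 2
        left_vessels &= ~mirror_clear
        right_vessels &= ~mirror_clear

    vessels = left_vessels | right_vessels
    elevation = np.maximum(bump, VESSEL_ELEVATION_C * vessels)
    temp = base + elevation * body
    if spec.noise_sd > 0:
        temp = temp + rng.normal(0.0, spec.noise_sd, size=temp.shape)

    meta = ThermogramMeta(ambient_temp_c=spec.ambient_c)
    cmap = ColormapSpec(
        t_min=spec.skin_base_c - 2.5, t_max=spec.skin_base_c + 2.5
    )
    thermogram = render_rgb(Thermogram(temperature=temp, meta=meta), cmap)

    true_delta = spec.hotspot.delta_t if spec.hotspot is not None else 0.0
    truth = PhantomTruth(
        fold_row=spec.fold_row,
        axilla_row=spec.axilla_row,
        center_col=c0,
        left_breast_mask=breast_masks["left"],
        right_breast_mask=breast_masks["right"],
        left_vessel_mask=left_vessels,
        right_vessel_mask=right_vessels,
        true_grade=_truth_grade(left_vessels, right_vessels, left_region, right_region),
        true_delta_t=float(true_delta),
        true_label="",
    )
    truth.true_label = (
        "anomaly" if truth.true_grade + truth.true_delta_t >= 2.5 else "healthy"
    )
    return thermogram, truth


def abs_le(col_index: np.ndarray, center: int, half_width: int) -> np.ndarray:
    """Column selector ``|c - center| <= half_width`` (symmetric band)."""
    return np.abs(col_index - center) <= half_width


def _truth_grade(left_v, right_v, left_region, right_region) -> int:
    """Apply the grading rule to the drawn vessel coverage fractions."""
    from .vascularity import GRADE_FULL_ASYMMETRY_FRACTION

    lf = left_v.sum() / max(1, left_region.sum())
    rf = right_v.sum() / max(1, right_region.sum())
    if max(lf, rf) < 0.01:
        return 0
    asym = abs(lf - rf)
    if asym >= GRADE_FULL_ASYMMETRY_FRACTION:
        return 4
    if asym >= 0.10:
        return 3
    return 2


def generate_cohort(
    n_healthy: int,
    n_cancer: int,
    seed: int = 0,
    rows: int = 240,
    cols: int = 200,
    healthy_delta_range: tuple[float, float] = (0.0, 0.8),
    cancer_delta_range: tuple[float, float] = (1.5, 4.0),
) -> list[PhantomCase]:
    """Simulate a screening cohort with known labels.

    Healthy phantoms carry mirror-symmetric moderate vasculature and at
    most a faint focal spot (peak ΔT in ``healthy_delta_range``), keeping
    thermal scores below the 2.5 call threshold; cancer phantoms carry a
    strong hotspot (ΔT in ``cancer_delta_range``) plus markedly
    asymmetric vasculature, placing scores well above it.
    """
    if n_healthy + n_cancer < 1:
        raise ValueError("cohort must contain at least one phantom")
    for lo, hi in (healthy_delta_range, cancer_delta_range):
        if not (0 <= lo <= hi):
            raise ValueError("invalid delta ranges")
    master = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for i in range(n_healthy + n_cancer):
        sub = int(master.integers(0, 2**31 - 1))
        draw_rng = np.random.default_rng(sub)
        cancer = i >= n_healthy
        side = "left" if draw_rng.random() < 0.5 else "right"
        if cancer:
            amp = float(draw_rng.uniform(*cancer_delta_range))
            sigma = float(draw_rng.uniform(5.0, 8.0))
            dens_hot = float(draw_rng.uniform(0.75, 1.0))
            dens_cold = float(draw_rng.uniform(0.0, 0.1))
            density = (
                (dens_hot, dens_cold) if side == "left" else (dens_cold, dens_hot)
            )
            spec = PhantomSpec(
                rows=rows,
                cols=cols,
                hotspot=HotspotSpec(side=side, delta_t=amp, sigma=sigma),
                vascular_density=density,
                vascular_symmetric=False,
                seed=sub,
            )
        else:
            amp = float(draw_rng.uniform(*healthy_delta_range))
            dens = float(draw_rng.uniform(0.15, 0.35))
            spec = PhantomSpec(
                rows=rows,
                cols=cols,
                hotspot=HotspotSpec(side=side, delta_t=amp) if amp > 0 else None,
                vascular_density=(dens, dens),
                vascular_symmetric=True,
                seed=sub,
            )
        thermogram, truth = generate_phantom(spec)
        truth.true_label = "anomaly" if cancer else "healthy"
        thermogram.meta.patient_id = f"P{i + 1:03d}"
        cases.append(
            PhantomCase(
                patient_id=thermogram.meta.patient_id,
                thermogram=thermogram,
                truth=truth,
            )
        )
    return cases
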