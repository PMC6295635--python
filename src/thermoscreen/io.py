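"""Thermogram input/output and pseudo-color rendering.

A thermogram is a matrix of surface temperatures in degrees Celsius,
optionally paired with an 8-bit RGB pseudo-color rendering of the same
scene.  Temperatures travel as plain CSV (one image row per line, full
precision) or as single-channel 16-bit TIFF with a linear scale/offset
recorded in a YAML sidecar; renderings travel as PNG.

The rendering step matters because the vascularity stage of the pipeline
is a *color* analysis: it classifies pixels in CIELAB space.  To make
those results bit-reproducible the package ships a fixed, versioned
rainbow palette (``thermo_rainbow_v1``) rather than deferring to any
camera vendor's palette.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "ThermogramMeta",
    "Thermogram",
    "ColormapSpec",
    "read_thermogram",
    "write_thermogram",
    "render_rgb",
    "COLORMAPS",
]

_VIEWS = ("frontal", "left_lateral", "right_lateral")


@dataclass
class ThermogramMeta:
    """Acquisition metadata carried alongside a temperature matrix.

    ``scale``/``offset`` define the linear map raw -> °C used by the
    16-bit TIFF representation (``temp_c = raw * scale + offset``).
    """

    emissivity: float = 0.97
    ambient_temp_c: float = 24.0
    patient_id: str = ""
    view: str = "frontal"
    scale: float = 0.01
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.emissivity <= 1.0):
            raise ValueError(f"emissivity must be in (0, 1], got {self.emissivity}")
        if self.view not in _VIEWS:
            raise ValueError(f"view must be one of {_VIEWS}, got {self.view!r}")


@dataclass
class Thermogram:
    """Temperature matrix in °C with an optional RGB rendering.

    Matrices are row-major with a top-left origin and 0-based indices.
    """

    temperature: np.ndarray
    rgb: Optional[np.ndarray] = None
    meta: ThermogramMeta = field(default_factory=ThermogramMeta)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        if t.ndim != 2 or t.size == 0:
            raise ValueError("temperature must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(t)):
            r, c = np.argwhere(~np.isfinite(t))[0]
            raise ValueError(f"non-finite temperature at cell ({r}, {c})")
        self.temperature = t
        if self.rgb is not None:
            rgb = np.asarray(self.rgb)
            if rgb.ndim != 3 or rgb.shape[2] != 3:
                raise ValueError("rgb must be rows x cols x 3")
            if rgb.shape[:2] != t.shape:
                raise ValueError(
                    f"rgb dimensions {rgb.shape[:2]} do not match "
                    f"temperature dimensions {t.shape}"
                )
            self.rgb = rgb.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperature.shape

    def copy(self) -> "Thermogram":
        return Thermogram(
            temperature=self.temperature.copy(),
            rgb=None if self.rgb is None else self.rgb.copy(),
            meta=dataclasses.replace(self.meta),
        )


# ---------------------------------------------------------------------------
# Pseudo-color palette
# ---------------------------------------------------------------------------

#: Versioned palette tables.  Each entry is (positions, colors) where
#: positions are fractions of the clip range and colors 8-bit RGB anchors;
#: pixel colors are linear interpolations between anchors.  The hot end of
#: every shipped palette is pure red so that hot (vascular) structures land
#: in the high-a* region of CIELAB.
COLORMAPS: dict[str, tuple[tuple[float, ...], tuple[tuple[int, int, int], ...]]] = {
    "thermo_rainbow_v1": (
        (0.00, 0.15, 0.30, 0.45, 0.55, 0.70, 0.85, 1.00),
        (
            (0, 0, 110),
            (0, 40, 255),
            (0, 180, 255),
            (0, 255, 120),
            (120, 255, 0),
            (255, 255, 0),
            (255, 120, 0),
            (255, 0, 0),
        ),
    ),
}


@dataclass
class ColormapSpec:
    """A palette name plus the temperature clip range it spans."""

    name: str = "thermo_rainbow_v1"
    t_min: float = 31.0
    t_max: float = 36.0

    def __post_init__(self) -> None:
        if self.name not in COLORMAPS:
            raise ValueError(f"unknown colormap {self.name!r}")
        if not (self.t_min < self.t_max):
            raise ValueError(
                f"degenerate clip range: t_min={self.t_min} >= t_max={self.t_max}"
            )

    def lookup(self, frac: np.ndarray) -> np.ndarray:
        """Map fractions in [0, 1] to uint8 RGB via the anchor table."""
        pos, colors = COLORMAPS[self.name]
        pos_arr = np.asarray(pos)
        col_arr = np.asarray(colors, dtype=float)
        frac = np.clip(np.asarray(frac, dtype=float), 0.0, 1.0)
        out = np.empty(frac.shape + (3,), dtype=np.uint8)
        for ch in range(3):
            out[..., ch] = np.rint(
                np.interp(frac, pos_arr, col_arr[:, ch])
            ).astype(np.uint8)
        return out


def render_rgb(t: Thermogram, cmap: Optional[ColormapSpec] = None) -> Thermogram:
    """Return a copy of ``t`` with the RGB rendering filled in.

    Temperatures are clipped to ``[t_min, t_max]``, scaled to [0, 1] and
    looked up in the palette table; the mapping is deterministic and
    monotone in temperature, and clipped-hot pixels take the palette's red
    endpoint color.
    """
    if cmap is None:
        cmap = ColormapSpec()
    frac = (t.temperature - cmap.t_min) / (cmap.t_max - cmap.t_min)
    out = t.copy()
    out.rgb = cmap.lookup(frac)
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path_temp: Path) -> Path:
    return path_temp.with_suffix(path_temp.suffix + ".yaml")


def read_thermogram(
    path_temp: str | os.PathLike,
    path_rgb: Optional[str | os.PathLike] = None,
    meta: Optional[ThermogramMeta] = None,
) -> Thermogram:
    """Read a thermogram from disk.

    ``path_temp`` is either a CSV of reals (one image row per line) or a
    single-channel 16-bit TIFF whose integer values map to °C via
    ``raw * scale + offset``; scale/offset come from ``meta`` or, if a
    ``<file>.yaml`` sidecar exists next to the TIFF, from that sidecar.
    """
    path_temp = Path(path_temp)
    if not path_temp.exists():
        raise FileNotFoundError(f"temperature file not found: {path_temp}")
    meta = meta if meta is not None else ThermogramMeta()

    if path_temp.suffix.lower() in (".tif", ".tiff"):
        sidecar = _sidecar_path(path_temp)
        if sidecar.exists():
            side = yaml.safe_load(sidecar.read_text())
            meta = dataclasses.replace(
                meta,
                scale=float(side.get("scale", meta.scale)),
                offset=float(side.get("offset", meta.offset)),
            )
        raw = tifffile.imread(path_temp)
        if raw.ndim != 2:
            raise ValueError(f"expected single-channel TIFF, got shape {raw.shape}")
        temp = raw.astype(float) * meta.scale + meta.offset
    else:
        temp = np.loadtxt(path_temp, delimiter=",", ndmin=2)

    rgb = None
    if path_rgb is not None:
        path_rgb = Path(path_rgb)
        if not path_rgb.exists():
            raise FileNotFoundError(f"rgb file not found: {path_rgb}")
        rgb = np.asarray(iio.imread(path_rgb))
        if rgb.ndim == 3 and rgb.shape[2] == 4:  # drop alpha
            rgb = rgb[:, :, :3]
    return Thermogram(temperature=temp, rgb=rgb, meta=meta)


def write_thermogram(
    t: Thermogram,
    path_temp: str | os.PathLike,
    path_rgb: Optional[str | os.PathLike] = None,
) -> None:
    """Write a thermogram to disk, losslessly on the CSV path.

    CSV stores full double precision (``%.17g``) so a read/write round
    trip is bitwise exact.  TIFF quantizes to the meta's scale, bounding
    the round-trip error by ``scale / 2``; scale/offset are recorded in a
    YAML sidecar so the file is self-describing.
    """
    path_temp = Path(path_temp)
    if path_temp.suffix.lower() in (".tif", ".tiff"):
        raw = np.rint((t.temperature - t.meta.offset) / t.meta.scale)
        if raw.min() < 0 or raw.max() > np.iinfo(np.uint16).max:
            raise ValueError(
                "temperature range does not fit uint16 at the given scale/offset"
            )
        tifffile.imwrite(path_temp, raw.astype(np.uint16))
        _sidecar_path(path_temp).write_text(
            yaml.safe_dump({"scale": t.meta.scale, "offset": t.meta.offset})
        )
    else:
        np.savetxt(path_temp, t.temperature, delimiter=",", fmt="%.17g")
    if path_rgb is not None:
        if t.rgb is None:
            raise ValueError("thermogram has no rgb rendering to write")
        iio.imwrite(Path(path_rgb), t.rgb)
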