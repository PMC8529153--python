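"""Raw-image to bone-mineral-density calibration.

A CT-style density phantom provides inserts of known density; the mean raw
value over each insert ROI is regressed (ordinary least squares) against the
known densities, yielding an affine map raw -> g/cm3 which is then applied
voxelwise.  A linear response is the standard assumption for this class of
calibration phantom.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .phantom import VoxelImage


@dataclass
class CalibrationMap:
    """Affine raw->density map: density = slope * raw + intercept."""

    slope: float          # (g/cm3) per raw unit
    intercept: float      # g/cm3
    r_squared: float
    n_inserts: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_inserts < 2:
            raise ValueError("need at least 2 inserts")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationMap":
        return cls(**json.loads(Path(path).read_text()))


def extract_insert_statistics(image: VoxelImage,
                              insert_spec: list[dict]) -> list[tuple[float, float]]:
    """Per insert: (mean raw value over voxels whose centers lie inside,
    known density)."""
    xs = [image.voxel_centers(a) for a in range(3)]
    pairs = []
    for i, s in enumerate(insert_spec):
        c = np.asarray(s["center"], dtype=float)
        r = float(s["radius"])
        d2 = ((xs[0][:, None, None] - c[0]) ** 2
              + (xs[1][None, :, None] - c[1]) ** 2
              + (xs[2][None, None, :] - c[2]) ** 2)
        inside = d2 <= r ** 2
        if not inside.any():
            raise ValueError(f"insert {i}: empty ROI (radius below voxel size?)")
        pairs.append((float(image.values[inside].mean()), float(s["density"])))
    return pairs


def fit_calibration(pairs: list[tuple[float, float]]) -> CalibrationMap:
    """OLS of known density on mean raw value."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration pairs")
    raw = np.array([p[0] for p in pairs], dtype=float)
    rho = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(raw) < 1e-12:
        raise ValueError("degenerate calibration input: raw means collinear")
    res = stats.linregress(raw, rho)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return CalibrationMap(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=min(max(r2, 0.0), 1.0), n_inserts=len(pairs))


def apply_calibration(image: VoxelImage, cal: CalibrationMap) -> VoxelImage:
    """Voxelwise affine transform to g/cm3; negative densities clamp to 0."""
    if image.units == "g/cm3":
        raise ValueError("image is already calibrated (units g/cm3); "
                         "refusing to apply a density-unit map twice")
    out = image.copy()
    out.values = np.maximum(cal.slope * image.values + cal.intercept, 0.0)
    out.units = "g/cm3"
    return out


def calibrate_phantom(density_image: VoxelImage,
                      insert_spec: list[dict]) -> tuple[VoxelImage, CalibrationMap]:
    """Convenience: extract ROIs, fit, and apply in one step."""
    pairs = extract_insert_statistics(density_image, insert_spec)
    cal = fit_calibration(pairs)
    return apply_calibration(density_image, cal), cal
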