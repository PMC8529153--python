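"""Density-to-material mapping.

Bone elements receive isotropic linear-elastic properties from their bone
mineral density rho (g/cm3) through power laws; the cortical/trabecular
split sits at 1.68 g/cm3, the density at which the two modulus laws
intersect.  Hardware gets fixed constants (titanium alloy screw, PMMA
cement).  Units are N-mm-MPa-g/cm3 throughout (1 MPa = 1 N/mm2).

    cortical:    E = 3890 * rho^2.39 MPa,  nu = 0.3,  sigma_ys = 141.6 MPa
    trabecular:  E = 6570 * rho^1.37 MPa,  nu = 0.3,
                 log10(sigma_ys) = 1.38 + 1.91 * log10(rho)
    titanium:    E = 110000 MPa, nu = 0.3,   sigma_ys = 930 MPa
    PMMA:        E = 2163 MPa,   nu = 0.375, sigma_ys = 93 MPa

The yield law's logarithm is base 10: at rho = 1 g/cm3 it gives ~24 MPa, a
physiologic trabecular strength, where a natural log would give ~4 MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from . import phantom as ph
from .phantom import VoxelImage

CORTICAL_TRABECULAR_THRESHOLD = 1.68   # g/cm3
SCREW_VOID_DENSITY = 0.94              # g/cm3, bone replacing the longer screw's end
DENSITY_FLOOR = 0.01                   # g/cm3, solver conditioning

CLASS_CORTICAL = "cortical"
CLASS_TRABECULAR = "trabecular"
CLASS_TITANIUM = "titanium"
CLASS_PMMA = "pmma"

TITANIUM = {"E": 110000.0, "nu": 0.3, "yield": 930.0}
PMMA = {"E": 2163.0, "nu": 0.375, "yield": 93.0}


def young_modulus_cortical(rho):
    return 3890.0 * np.asarray(rho, dtype=float) ** 2.39


def young_modulus_trabecular(rho):
    return 6570.0 * np.asarray(rho, dtype=float) ** 1.37


def yield_strength_trabecular(rho):
    return 10.0 ** (1.38 + 1.91 * np.log10(np.asarray(rho, dtype=float)))


YIELD_CORTICAL = 141.6


def modulus_crossover() -> float:
    """Density where the cortical and trabecular modulus laws intersect."""
    return float(optimize.brentq(
        lambda r: young_modulus_cortical(r) - young_modulus_trabecular(r),
        0.5, 5.0, xtol=1e-12))


@dataclass
class MaterialField:
    """Per-element material data aligned with a LabeledMesh's elements."""

    density: np.ndarray        # g/cm3
    young_modulus: np.ndarray  # MPa
    poisson: np.ndarray
    yield_strength: np.ndarray  # MPa
    material_class: np.ndarray  # unicode array of class names

    def __post_init__(self) -> None:
        n = len(self.density)
        for arr in (self.young_modulus, self.poisson, self.yield_strength,
                    self.material_class):
            if len(arr) != n:
                raise ValueError("material arrays must have equal length")

    @property
    def n_elements(self) -> int:
        return len(self.density)

    def is_bone(self) -> np.ndarray:
        return np.isin(self.material_class, (CLASS_CORTICAL, CLASS_TRABECULAR))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "element_id": np.arange(self.n_elements),
            "density": self.density,
            "young_modulus": self.young_modulus,
            "poisson": self.poisson,
            "yield_strength": self.yield_strength,
            "material_class": self.material_class,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Element density sampling
# ---------------------------------------------------------------------------

def sample_element_density(mesh, image: VoxelImage,
                           label_image: VoxelImage | None = None) -> np.ndarray:
    """Mean calibrated density over the voxels whose centers lie in each element.

    When a label image is supplied, only bone-labeled voxels contribute
    (hardware sentinels and air would otherwise bleed partial-volume values
    into boundary elements).  Elements containing no voxel center fall back
    to trilinear interpolation at the element centroid.  Densities are
    floored at ``DENSITY_FLOOR``.
    """
    if image.units != "g/cm3":
        raise ValueError("density image must be calibrated (units g/cm3)")
    sp = np.asarray(image.spacing)
    origin = np.asarray(image.origin)
    shape = np.asarray(image.shape)
    extent = origin + shape * sp

    corners = mesh.nodes[mesh.elements[:, :4]]       # (n_el, 4, 3)
    lo = corners.min(axis=1)
    hi = corners.max(axis=1)
    if np.any(lo < origin - 1e-9) or np.any(hi > extent + 1e-9):
        bad = int(np.argmax(np.any(lo < origin - 1e-9, axis=1)
                            | np.any(hi > extent + 1e-9, axis=1)))
        raise ValueError(f"element {bad} lies outside the image bounds")

    values = np.asarray(image.values, dtype=float)
    if label_image is not None:
        bone = np.isin(label_image.values, ph.BONE_LABELS)
    else:
        bone = None

    centers = [image.voxel_centers(a) for a in range(3)]
    rho = np.empty(len(corners))
    need_interp = []
    for e in range(len(corners)):
        i0 = np.maximum(((lo[e] - origin) / sp - 0.5).astype(int), 0)
        i1 = np.minimum(((hi[e] - origin) / sp + 0.5).astype(int) + 1, shape)
        sl = tuple(slice(i0[a], i1[a]) for a in range(3))
        gx, gy, gz = np.meshgrid(centers[0][sl[0]], centers[1][sl[1]],
                                 centers[2][sl[2]], indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        x0 = corners[e, 0]
        A = (corners[e, 1:] - x0).T
        try:
            lam = np.linalg.solve(A, (pts - x0).T)
        except np.linalg.LinAlgError:
            need_interp.append(e)
            continue
        inside = np.all(lam >= -1e-9, axis=0) & (lam.sum(axis=0) <= 1 + 1e-9)
        if bone is not None:
            inside &= bone[sl].reshape(-1)
        if inside.any():
            rho[e] = values[sl].reshape(-1)[inside].mean()
        else:
            need_interp.append(e)

    if need_interp:
        cent = corners[np.array(need_interp)].mean(axis=1)
        idx = ((cent - origin) / sp - 0.5).T
        rho[np.array(need_interp)] = ndimage.map_coordinates(
            values, idx, order=1, mode="nearest")
    return np.maximum(rho, DENSITY_FLOOR)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_and_assign(rho: np.ndarray, region_labels: np.ndarray) -> MaterialField:
    """Assign per-element material from density and region label."""
    rho = np.asarray(rho, dtype=float)
    labels = np.asarray(region_labels)
    if np.any(rho <= 0):
        raise ValueError("densities must be positive (floored upstream)")
    n = len(rho)
    E = np.empty(n)
    nu = np.full(n, 0.3)
    ys = np.empty(n)
    cls = np.empty(n, dtype="U10")

    known = np.isin(labels, ph.BONE_LABELS + (ph.SCREW, ph.CEMENT))
    if not known.all():
        bad = np.unique(labels[~known])
        raise ValueError(f"unknown region labels {bad.tolist()}")

    bone = np.isin(labels, ph.BONE_LABELS)
    cort = bone & (rho >= CORTICAL_TRABECULAR_THRESHOLD)
    trab = bone & ~cort
    E[cort] = young_modulus_cortical(rho[cort])
    ys[cort] = YIELD_CORTICAL
    cls[cort] = CLASS_CORTICAL
    E[trab] = young_modulus_trabecular(rho[trab])
    ys[trab] = yield_strength_trabecular(rho[trab])
    cls[trab] = CLASS_TRABECULAR

    ti = labels == ph.SCREW
    E[ti], nu[ti], ys[ti], cls[ti] = (TITANIUM["E"], TITANIUM["nu"],
                                      TITANIUM["yield"], CLASS_TITANIUM)
    pm = labels == ph.CEMENT
    E[pm], nu[pm], ys[pm], cls[pm] = (PMMA["E"], PMMA["nu"],
                                      PMMA["yield"], CLASS_PMMA)
    return MaterialField(rho.copy(), E, nu, ys, cls)


def fill_screw_void(field: MaterialField, void_elements: np.ndarray,
                    screw_variant: str) -> MaterialField:
    """Assign the screw-void track trabecular bone at exactly 0.94 g/cm3.

    Only meaningful for the uni-cortical scenario, where the distal-lateral
    part of the 70 mm track is bone instead of screw.
    """
    if screw_variant != "unicortical_50":
        raise ValueError("fill_screw_void applies only to the uni-cortical "
                         f"scenario, not {screw_variant!r}")
    void_elements = np.asarray(void_elements)
    if void_elements.dtype == bool:
        void_elements = np.flatnonzero(void_elements)
    field.density[void_elements] = SCREW_VOID_DENSITY
    field.young_modulus[void_elements] = young_modulus_trabecular(SCREW_VOID_DENSITY)
    field.poisson[void_elements] = 0.3
    field.yield_strength[void_elements] = yield_strength_trabecular(SCREW_VOID_DENSITY)
    field.material_class[void_elements] = CLASS_TRABECULAR
    return field
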