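"""Synthetic voxel phantom of a stabilized split-depression tibial plateau fracture.

The phantom stands in for a postoperative CT of a Schatzker-II fracture that
has been reduced and stabilized with a medio-lateral cancellous screw and,
optionally, PMMA cement.  It produces a labeled voxel image (bone regions,
fracture fragments, hardware), a co-registered "raw-unit" density image whose
relation to g/cm3 is a hidden affine map (so that the calibration stage is
genuinely exercised), and a set of calibration inserts of known density.

Geometry is deliberately idealized: the proximal tibia is a capped, tapered
elliptical cylinder; the depressed fragment is a block under the articular
surface separated from the parent bone by a uniform residual gap; the
separated fragment is a lateral wedge offset by the split-gap width.  The
fibula is omitted: the mechanics exercised by the study run through the
fracture/hardware region.

Coordinates: image axes are (medial->lateral, posterior->anterior,
distal->proximal); world coordinates are mm from the image origin; the center
of voxel ``i`` is at ``(i + 0.5) * spacing``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

# ---------------------------------------------------------------------------
# Region labels
# ---------------------------------------------------------------------------

BACKGROUND = 0
SHAFT = 1
PLATEAU = 2
FRAG_DEPRESSED = 3
FRAG_SEPARATED = 4
SCREW = 5
CEMENT = 6
SCREW_VOID = 7  # bone occupying the unused distal-lateral part of the screw track

LABEL_NAMES = {
    BACKGROUND: "background",
    SHAFT: "shaft",
    PLATEAU: "plateau",
    FRAG_DEPRESSED: "depressed_fragment",
    FRAG_SEPARATED: "separated_fragment",
    SCREW: "screw",
    CEMENT: "cement",
    SCREW_VOID: "screw_void",
}

BONE_LABELS = (SHAFT, PLATEAU, FRAG_DEPRESSED, FRAG_SEPARATED, SCREW_VOID)

# Raw-image sentinels expressed as equivalent densities (g/cm3) pushed through
# the hidden map: metal saturates bright, cement is distinctly bright but
# below metal.
SCREW_SENTINEL_DENSITY = 4.0
CEMENT_SENTINEL_DENSITY = 2.6

_SCREW_RADIUS = 3.25           # mm, 6.5 mm diameter
_SCREW_LENGTH = {"bicortical_70": 70.0, "unicortical_50": 50.0}
_THREAD_LENGTH = {"bicortical_70": 40.0, "unicortical_50": 20.0}
_CEMENT_OUTER_RADIUS = 10.5    # mm, sleeve radius of the cement around the screw


# ---------------------------------------------------------------------------
# Image container
# ---------------------------------------------------------------------------

@dataclass
class VoxelImage:
    """A voxel grid with spacing/origin metadata.

    ``units`` is one of ``"raw"`` (uncalibrated scanner units), ``"g/cm3"``
    (calibrated bone mineral density) or ``"label"`` (integer region ids).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "raw"

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.spacing)
        return aff

    def copy(self) -> "VoxelImage":
        return VoxelImage(self.values.copy(), tuple(self.spacing),
                          tuple(self.origin), self.units)

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asanyarray(self.values), self.affine())
        img.header["descrip"] = f"units={self.units}".encode()
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelImage":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(aff[i, i]) for i in range(3))
        origin = tuple(float(aff[i, 3] - 0.5 * aff[i, i]) for i in range(3))
        descrip = img.header["descrip"].tobytes().decode(errors="ignore")
        units = "raw"
        if "units=" in descrip:
            units = descrip.split("units=")[1].split("\x00")[0].strip()
        return cls(np.asanyarray(img.dataobj), spacing, origin, units)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class PhantomParams:
    """Geometric and imaging parameters of the synthetic phantom.

    Defaults reproduce the study conditions where stated (gap sizes, screw
    dimensions, patient mass) and otherwise desk-scale anatomic values.
    """

    body_mass: float = 80.0                 # kg (patient of record)
    body_height: float = 1.82               # m, metadata only
    shaft_length: float = 12.0              # mm of distal diaphysis below the flare
    shaft_outer_radius: float = 11.0        # mm
    cortical_thickness: float = 3.0         # mm
    plateau_width: float = 70.0             # mm medio-lateral (hosts the 70 mm screw)
    depressed_gap: float = 1.78             # mm residual gap around the depressed fragment
    separated_gap: float = 3.5              # mm split gap of the lateral wedge
    screw_variant: str = "bicortical_70"    # or "unicortical_50"
    cement: bool = True
    healing_state: str = "mobile"           # mobile | bonded | fused
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    trabecular_density_mean: float = 0.40   # g/cm3, plateau interior
    shaft_density_max: float = 0.90         # g/cm3, interior at the distal end
    cortical_density_mean: float = 1.85     # g/cm3
    noise_sd: float = 0.02                  # g/cm3
    seed: int = 0

    # hidden ground-truth affine map density = slope * raw + intercept
    truth_slope: float = 0.001
    truth_intercept: float = -0.1

    def __post_init__(self) -> None:
        for name in ("shaft_length", "shaft_outer_radius", "cortical_thickness",
                     "plateau_width", "body_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.depressed_gap < 0 or self.separated_gap < 0:
            raise ValueError("gap sizes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.screw_variant not in _SCREW_LENGTH:
            raise ValueError(f"unknown screw_variant {self.screw_variant!r}")
        if self.healing_state not in ("mobile", "bonded", "fused"):
            raise ValueError(f"unknown healing_state {self.healing_state!r}")
        self.voxel_spacing = tuple(float(v) for v in self.voxel_spacing)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be > 0")
        if not (np.isfinite(self.trabecular_density_mean)
                and np.isfinite(self.cortical_density_mean)):
            raise ValueError("density parameters must be finite")
        if self.truth_slope <= 0:
            raise ValueError("truth_slope must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PhantomBundle:
    """Everything the downstream pipeline needs about one phantom."""

    density_image: VoxelImage
    label_image: VoxelImage
    insert_spec: list[dict]
    geometry_meta: dict
    params: PhantomParams = field(repr=False, default=None)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.density_image.save(out / "density.nii.gz")
        self.label_image.save(out / "labels.nii.gz")
        meta = {
            "geometry_meta": self.geometry_meta,
            "insert_spec": self.insert_spec,
            "params": self.params.to_dict() if self.params else None,
        }
        (out / "phantom.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _layout(params: PhantomParams) -> dict:
    """Derived world-coordinate layout of the phantom."""
    rx = params.plateau_width / 2.0
    ry = rx * (15.0 / 35.0)                  # anteroposterior half-depth
    flare_height = 28.0
    plateau_height = 21.0
    z_shaft0 = 2.0
    z_flare0 = z_shaft0 + params.shaft_length
    z_plateau0 = z_flare0 + flare_height
    z_top = z_plateau0 + plateau_height

    cx = 7.0 + rx
    cy = 3.0 + ry
    nx = int(np.ceil((2 * rx + 14.0) / params.voxel_spacing[0]))
    insert_y = cy + ry + 4.5
    insert_r = 3.5
    ny = int(np.ceil((insert_y + insert_r + 3.0) / params.voxel_spacing[1]))
    nz = int(np.ceil((z_top + 4.0) / params.voxel_spacing[2]))

    # depressed fragment: block under the articular surface, medial of the split
    frag_x = (-9.0, 8.5)        # local x' extents
    frag_y = (-12.0, 12.0)
    frag_z = (z_top - 12.0, z_top)
    split_x0 = frag_x[1]        # split fracture plane (parent lateral boundary)
    wedge_x0 = split_x0 + params.separated_gap
    wedge_z0 = z_top - 21.0
    wedge_clearance = params.separated_gap + 0.5   # basal void under the wedge
    side_clearance = 5.0                            # impaction defect around the fragment
    z_screw = frag_z[0] - _SCREW_RADIUS + 0.25     # top of screw just touches fragment

    screw_x0 = -rx
    screw_x1 = screw_x0 + _SCREW_LENGTH[params.screw_variant]
    track_x1 = screw_x0 + _SCREW_LENGTH["bicortical_70"]

    return {
        "rx": rx, "ry": ry, "cx": cx, "cy": cy,
        "shape": (nx, ny, nz),
        "z_shaft0": z_shaft0, "z_flare0": z_flare0,
        "z_plateau0": z_plateau0, "z_top": z_top,
        "frag_x": frag_x, "frag_y": frag_y, "frag_z": frag_z,
        "split_x0": split_x0, "wedge_x0": wedge_x0, "wedge_z0": wedge_z0,
        "wedge_clearance": wedge_clearance,
        "side_clearance": side_clearance,
        "screw_axis_y": 0.0, "screw_axis_z": z_screw,
        "screw_x0": screw_x0, "screw_x1": screw_x1, "track_x1": track_x1,
        "screw_radius": _SCREW_RADIUS,
        "thread_length": _THREAD_LENGTH[params.screw_variant],
        "cement_outer_radius": _CEMENT_OUTER_RADIUS,
        "insert_y": insert_y, "insert_r": insert_r,
    }


def default_insert_spec(params: PhantomParams) -> list[dict]:
    """Five rod-like (spherical) inserts of known density, CIRS-style."""
    lay = _layout(params)
    nx = lay["shape"][0] * params.voxel_spacing[0]
    xs = np.linspace(12.0, nx - 12.0, 5)
    densities = [0.0, 0.4, 0.8, 1.2, 1.6]
    return [
        {"center": (float(x), float(lay["insert_y"]), 14.0),
         "radius": float(lay["insert_r"]),
         "density": float(d)}
        for x, d in zip(xs, densities)
    ]


def build_geometry(params: PhantomParams) -> tuple[VoxelImage, dict]:
    """Rasterize the labeled phantom geometry.

    Returns the label image and the geometry metadata (fragment frames, screw
    axis, condylar patch definitions, hidden density map, ...).
    """
    lay = _layout(params)
    sp = params.voxel_spacing
    nx, ny, nz = lay["shape"]
    x = (np.arange(nx) + 0.5) * sp[0]
    y = (np.arange(ny) + 0.5) * sp[1]
    z = (np.arange(nz) + 0.5) * sp[2]
    X = x[:, None, None] - lay["cx"]         # local medio-lateral
    Y = y[None, :, None] - lay["cy"]         # local antero-posterior
    Z = z[None, None, :]                     # distal->proximal, world

    rx, ry = lay["rx"], lay["ry"]
    r_sh = params.shaft_outer_radius

    # bone hull: shaft cylinder -> flare -> plateau elliptical cylinder
    t = np.clip((Z - lay["z_flare0"]) / (lay["z_plateau0"] - lay["z_flare0"]), 0.0, 1.0)
    rx_z = r_sh + (rx - r_sh) * t
    ry_z = r_sh + (ry - r_sh) * t
    hull = (((X / rx_z) ** 2 + (Y / ry_z) ** 2) <= 1.0) \
        & (Z >= lay["z_shaft0"]) & (Z <= lay["z_top"])
    hull = np.broadcast_to(hull, (nx, ny, nz)).copy()

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    labels[hull & np.broadcast_to(Z < lay["z_plateau0"], hull.shape)] = SHAFT
    labels[hull & np.broadcast_to(Z >= lay["z_plateau0"], hull.shape)] = PLATEAU

    fused = params.healing_state == "fused"
    fx, fy, fz = lay["frag_x"], lay["frag_y"], lay["frag_z"]
    g = params.depressed_gap

    frag_box = (X >= fx[0]) & (X <= fx[1]) & (Y >= fy[0]) & (Y <= fy[1]) \
        & (Z >= fz[0]) & (Z <= fz[1])
    wedge = (X >= lay["wedge_x0"]) & (Z >= lay["wedge_z0"])

    if not fused:
        # carve the residual gaps (voxels whose centers lie strictly inside).
        # The basal gap is the nominal residual gap; the impaction defect
        # around the fragment's medial and AP faces is wider, so the only
        # apposition surface (and the minimum fragment-parent distance) is
        # the basal one.
        side = max(lay["side_clearance"], g)
        carve_d = (X > fx[0] - side) & (X <= fx[1]) \
            & (Y > fy[0] - side) & (Y < fy[1] + side) \
            & (Z > fz[0] - g) & (Z <= fz[1]) & ~frag_box
        z_void0 = lay["wedge_z0"] - lay["wedge_clearance"]
        carve_s = (X > lay["split_x0"]) & (Z > z_void0) & ~wedge
        labels[(carve_d | carve_s) & hull] = BACKGROUND
        labels[frag_box & hull] = FRAG_DEPRESSED
        labels[wedge & hull & (labels == PLATEAU)] = FRAG_SEPARATED

    # screw and (for the uni-cortical variant) the void part of the track
    ax_d2 = (Y - lay["screw_axis_y"]) ** 2 + (Z - lay["screw_axis_z"]) ** 2
    in_track = np.broadcast_to(ax_d2 <= lay["screw_radius"] ** 2, (nx, ny, nz))
    void = in_track & (X > lay["screw_x1"]) & (X <= lay["track_x1"]) \
        & np.isin(labels, (SHAFT, PLATEAU, FRAG_SEPARATED))
    labels[np.broadcast_to(void, labels.shape)] = SCREW_VOID
    screw = in_track & (X >= lay["screw_x0"]) & (X <= lay["screw_x1"]) & hull
    labels[np.broadcast_to(screw, labels.shape)] = SCREW

    if params.cement:
        sleeve = (ax_d2 > lay["screw_radius"] ** 2) \
            & (ax_d2 <= lay["cement_outer_radius"] ** 2) \
            & (X >= fx[0]) & (X <= fx[1]) & hull \
            & ((labels == PLATEAU) | (labels == BACKGROUND))
        labels[np.broadcast_to(sleeve, labels.shape)] = CEMENT

    expected = [SHAFT, PLATEAU, SCREW]
    if not fused:
        expected += [FRAG_DEPRESSED, FRAG_SEPARATED]
    if params.cement:
        expected += [CEMENT]
    if params.screw_variant == "unicortical_50":
        expected += [SCREW_VOID]
    for lab in expected:
        if not np.any(labels == lab):
            raise ValueError(
                f"geometry collision: label {LABEL_NAMES[lab]!r} is empty")

    label_image = VoxelImage(labels, tuple(sp), (0.0, 0.0, 0.0), units="label")

    geometry_meta = {
        "layout": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in lay.items()},
        "screw_axis": {
            "point": [lay["cx"] + lay["screw_x0"], lay["cy"], lay["screw_axis_z"]],
            "direction": [1.0, 0.0, 0.0],
            "radius": lay["screw_radius"],
            "length": _SCREW_LENGTH[params.screw_variant],
            "thread_length": lay["thread_length"],
        },
        "fragment_frames": {
            "depressed": {"x": [lay["cx"] + fx[0], lay["cx"] + fx[1]],
                          "y": [lay["cy"] + fy[0], lay["cy"] + fy[1]],
                          "z": [fz[0], fz[1]]},
            "separated": {"x_min": lay["cx"] + lay["wedge_x0"],
                          "z_min": lay["wedge_z0"]},
        },
        "condylar_patches": {
            # the lateral compartment of the phantom is the fracture complex
            "lateral": {"center": [lay["cx"] - 0.25, lay["cy"], lay["z_top"]],
                        "area_mm2": 403.0},
            "medial": {"center": [lay["cx"] - 21.0, lay["cy"], lay["z_top"]],
                       "area_mm2": 374.0},
        },
        "truth_map": {"slope": params.truth_slope,
                      "intercept": params.truth_intercept},
        "distal_z": lay["z_shaft0"],
        "articular_z": lay["z_top"],
    }
    return label_image, geometry_meta


# ---------------------------------------------------------------------------
# Density rasterization
# ---------------------------------------------------------------------------

def _density_to_raw(density: np.ndarray | float, params: PhantomParams):
    return (np.asarray(density, dtype=np.float64) - params.truth_intercept) \
        / params.truth_slope


def rasterize_density(label_image: VoxelImage, params: PhantomParams,
                      geometry_meta: dict) -> VoxelImage:
    """Draw the raw-unit density image matching the label image.

    Cortical-shell voxels (within ``cortical_thickness`` of the exterior of
    the *filled* bone hull, so fracture surfaces stay trabecular) are drawn
    around the cortical mean, interior bone around the trabecular mean, with
    Gaussian noise of ``noise_sd`` (in g/cm3), then pushed through the hidden
    affine map to raw units.  Screw and cement voxels get distinct bright
    sentinels.
    """
    if not (np.isfinite(params.trabecular_density_mean)
            and np.isfinite(params.cortical_density_mean)
            and np.isfinite(params.noise_sd)):
        raise ValueError("non-finite density parameters")
    labels = label_image.values
    sp = label_image.spacing

    # filled hull = every labeled voxel plus the carved gaps; reconstruct the
    # gaps by closing the label mask so fracture surfaces are not "exterior"
    filled = labels > 0
    filled = ndimage.binary_closing(filled, structure=np.ones((3, 3, 3)),
                                    iterations=3)
    dist = ndimage.distance_transform_edt(filled, sampling=sp)
    cortical = dist <= params.cortical_thickness

    # interior (trabecular) density: uniform in the plateau, ramping up
    # toward the distal shaft -- deep metaphyseal bone is denser, and the
    # solid distal section stands in for the cortical tube of the diaphysis
    lay = geometry_meta["layout"]
    z = np.broadcast_to(
        (np.arange(labels.shape[2]) + 0.5) * sp[2], labels.shape)
    ramp = np.clip((lay["z_plateau0"] - z)
                   / max(lay["z_plateau0"] - lay["z_shaft0"], 1e-9), 0.0, 1.0)
    trab = params.trabecular_density_mean + ramp * (
        params.shaft_density_max - params.trabecular_density_mean)

    density = np.zeros(labels.shape, dtype=np.float64)
    bone = np.isin(labels, BONE_LABELS)
    density[bone] = np.where(cortical[bone], params.cortical_density_mean,
                             trab[bone])
    density[labels == SCREW_VOID] = 0.94   # bone where the longer screw would end

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        density += rng.normal(0.0, params.noise_sd, size=labels.shape)

    raw = _density_to_raw(density, params)
    raw[labels == SCREW] = _density_to_raw(SCREW_SENTINEL_DENSITY, params)
    raw[labels == CEMENT] = _density_to_raw(CEMENT_SENTINEL_DENSITY, params)
    return VoxelImage(raw, tuple(sp), tuple(label_image.origin), units="raw")


def place_calibration_inserts(image: VoxelImage, insert_spec: list[dict],
                              params: PhantomParams) -> VoxelImage:
    """Overwrite spherical insert regions with raw values of known density."""
    densities = {round(s["density"], 9) for s in insert_spec}
    if len(insert_spec) < 2 or len(densities) < 2:
        raise ValueError("calibration underdetermined: need >= 2 inserts "
                         "with distinct known densities")
    out = image.copy()
    sp = image.spacing
    shape = np.asarray(image.shape)
    extent = shape * np.asarray(sp)

    centers = np.array([s["center"] for s in insert_spec], dtype=float)
    radii = np.array([s["radius"] for s in insert_spec], dtype=float)
    for i, s in enumerate(insert_spec):
        c, r = centers[i], radii[i]
        if np.any(c - r < 0) or np.any(c + r > extent):
            raise ValueError(f"insert {i} partially outside the image")
        for j in range(i + 1, len(insert_spec)):
            if np.linalg.norm(c - centers[j]) < r + radii[j]:
                raise ValueError(f"inserts {i} and {j} overlap")

    rng = np.random.default_rng(params.seed + 1)
    xs = [image.voxel_centers(a) for a in range(3)]
    for s in insert_spec:
        c, r = np.asarray(s["center"]), s["radius"]
        lo = np.maximum(((c - r) / sp).astype(int), 0)
        hi = np.minimum(((c + r) / sp).astype(int) + 2, shape)
        sub = tuple(slice(lo[a], hi[a]) for a in range(3))
        gx, gy, gz = np.meshgrid(xs[0][sub[0]], xs[1][sub[1]], xs[2][sub[2]],
                                 indexing="ij")
        inside = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= r ** 2
        rho = np.full(inside.sum(), float(s["density"]))
        if params.noise_sd > 0:
            rho = rho + rng.normal(0.0, params.noise_sd, size=rho.size)
        out.values[sub][inside] = _density_to_raw(rho, params)
    return out


def build_phantom(params: PhantomParams,
                  insert_spec: list[dict] | None = None) -> PhantomBundle:
    """Full phantom: geometry + density raster + calibration inserts."""
    label_image, geometry_meta = build_geometry(params)
    density = rasterize_density(label_image, params, geometry_meta)
    if insert_spec is None:
        insert_spec = default_insert_spec(params)
    density = place_calibration_inserts(density, insert_spec, params)
    geometry_meta["insert_spec"] = insert_spec
    return PhantomBundle(density, label_image, insert_spec, geometry_meta, params)


# ---------------------------------------------------------------------------
# Measurement helpers (used by tests and reporting)
# ---------------------------------------------------------------------------

def min_label_distance(label_image: VoxelImage, label_a: int, label_b: int) -> float:
    """Minimum center-to-center distance (mm) between voxels of two labels."""
    labels = label_image.values
    a = labels == label_a
    b = labels == label_b
    if not a.any() or not b.any():
        raise ValueError("one of the labels is empty")
    dist = ndimage.distance_transform_edt(~a, sampling=label_image.spacing)
    return float(dist[b].min())
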