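"""Region-tagged quadratic tetrahedral meshes from labeled voxel images.

The mesher fills the image bounding box with a uniform cube lattice of edge
``target_size``, splits every cube into six Kuhn tetrahedra (a conforming
subdivision), keeps tetrahedra whose centroid samples a nonzero label, and
promotes them to straight-sided 10-node (TET10) elements by inserting edge
midpoints.

Fracture interfaces are handled by node splitting: wherever elements of a
fragment and of the parent bone would share lattice nodes, the fragment gets
its own copies, so the two surfaces are geometrically coincident-or-offset
but topologically disconnected.  Hardware (screw, cement) and the screw-void
bone bond to everything they touch, which is exactly the "contacts that
include cement or screw are bonded" modeling rule; the mobile and the bonded
healing states therefore share one mesh and differ only in the interface
constraints applied by the solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import phantom as ph
from .phantom import VoxelImage

# VTK TET10 local edge ordering: node 4 + k is the midpoint of _EDGES[k]
_EDGES = np.array([(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)])
_EDGE_OF = {frozenset(e): 4 + k for k, e in enumerate(map(tuple, _EDGES))}
# face k is opposite local corner k
_FACES = np.array([(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)])

# bonding groups: parent bone, depressed fragment, separated fragment, glue
_GLUE = 3
_GROUP = {ph.SHAFT: 0, ph.PLATEAU: 0, ph.FRAG_DEPRESSED: 1,
          ph.FRAG_SEPARATED: 2, ph.SCREW: _GLUE, ph.CEMENT: _GLUE,
          ph.SCREW_VOID: _GLUE}

PARENT_LABELS = (ph.SHAFT, ph.PLATEAU, ph.SCREW_VOID)
FRAGMENT_LABEL = {"depressed": ph.FRAG_DEPRESSED, "separated": ph.FRAG_SEPARATED}


@dataclass
class LabeledMesh:
    """Straight-sided TET10 mesh with per-element region labels."""

    nodes: np.ndarray          # (n_nodes, 3) mm
    elements: np.ndarray       # (n_el, 10) node ids, VTK ordering
    labels: np.ndarray         # (n_el,) region label per element
    boundary_facets: dict = field(default_factory=dict)  # tag -> (n_f, 6) node ids
    facet_elements: dict = field(default_factory=dict)   # tag -> (n_f,) element id

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_coords(self) -> np.ndarray:
        return self.nodes[self.elements[:, :4]]

    def element_volumes(self) -> np.ndarray:
        c = self.corner_coords()
        return np.abs(np.linalg.det(c[:, 1:] - c[:, :1])) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)


@dataclass
class InterfacePairs:
    """Node-to-surface pairing across one fracture interface."""

    fragment: str                     # "depressed" | "separated"
    node_ids: np.ndarray              # (n_p,) fragment-side node ids
    opposing_nodes: np.ndarray        # (n_p, 6) TRI6 node ids of target facet
    opposing_weights: np.ndarray      # (n_p, 6) shape-function weights
    gaps: np.ndarray                  # (n_p,) initial gap, mm
    normals: np.ndarray               # (n_p, 3) unit, from parent toward fragment
    areas: np.ndarray = None          # (n_p,) tributary surface area, mm2

    def __len__(self) -> int:
        return len(self.node_ids)


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------

def mesh_domains(label_image: VoxelImage, target_size: float = 3.0) -> LabeledMesh:
    """Mesh every labeled region of a voxel image with TET10 elements."""
    if target_size <= 0:
        raise ValueError("target_size must be > 0")
    sp = np.asarray(label_image.spacing)
    if target_size < 2 * sp.max():
        warnings.warn("target_size below 2x voxel spacing; centroid sampling "
                      "may alias thin features", stacklevel=2)
    labels_img = label_image.values
    origin = np.asarray(label_image.origin, dtype=float)
    extent = np.asarray(labels_img.shape) * sp
    ncell = np.maximum(np.ceil(extent / target_size).astype(int), 1)

    # lattice vertices and the 6-tet Kuhn subdivision of each cube
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    corners_local = []
    for p in perms:
        steps = np.zeros((4, 3), dtype=int)
        for k, axis in enumerate(p):
            steps[k + 1] = steps[k]
            steps[k + 1, axis] += 1
        corners_local.append(steps)
    corners_local = np.array(corners_local)            # (6, 4, 3) in {0,1}

    ii, jj, kk = np.meshgrid(np.arange(ncell[0]), np.arange(ncell[1]),
                             np.arange(ncell[2]), indexing="ij")
    base = np.stack([ii, jj, kk], axis=-1).reshape(-1, 1, 1, 3)
    vert_idx = base + corners_local[None]              # (ncubes, 6, 4, 3)
    vert_idx = vert_idx.reshape(-1, 4, 3)              # (ncubes*6, 4, 3)

    h = target_size
    coords = origin + vert_idx * h
    centroids = coords.mean(axis=1)
    vox = np.floor((centroids - origin) / sp).astype(int)
    ok = np.all((vox >= 0) & (vox < labels_img.shape), axis=1)
    lab = np.zeros(len(vox), dtype=np.int16)
    lab[ok] = labels_img[vox[ok, 0], vox[ok, 1], vox[ok, 2]]
    keep = lab > 0

    # Fracture-gap fidelity: a bone tetrahedron whose corners reach into an
    # interfragmentary gap (interior background) would protrude across the
    # gap and spuriously graze the opposing surface.  Such tets are dropped,
    # so fracture surfaces retreat to lattice planes.  Hardware (screw,
    # cement) legitimately spans gaps and is exempt.
    interior_bg = ndimage.binary_closing(
        labels_img > 0, structure=np.ones((3, 3, 3)), iterations=3) \
        & (labels_img == 0)
    # where a gap meets the hull surface, the first exterior voxels belong
    # to the fracture too -- without this, slender bone slivers survive at
    # the rim and wobble freely
    interior_bg |= ndimage.binary_dilation(
        interior_bg, np.ones((3, 3, 3)), iterations=2) & (labels_img == 0)
    if interior_bg.any():
        bone_tet = np.isin(lab, (ph.SHAFT, ph.PLATEAU, ph.FRAG_DEPRESSED,
                                 ph.FRAG_SEPARATED, ph.SCREW_VOID))
        probe = coords + 0.02 * (centroids[:, None, :] - coords)
        pv = np.floor((probe - origin) / sp).astype(int)
        pv_ok = np.all((pv >= 0) & (pv < labels_img.shape), axis=2)
        in_gap = np.zeros(pv.shape[:2], dtype=bool)
        flat_ok = pv_ok.reshape(-1)
        pvf = pv.reshape(-1, 3)[flat_ok]
        in_gap.reshape(-1)[flat_ok] = interior_bg[pvf[:, 0], pvf[:, 1], pvf[:, 2]]
        keep &= ~(bone_tet & in_gap.any(axis=1))

    vert_idx, lab = vert_idx[keep], lab[keep]

    if len(vert_idx) == 0:
        raise ValueError("meshing failure: no labeled material in image")

    nvy, nvz = ncell[1] + 1, ncell[2] + 1
    conn4 = (vert_idx[..., 0] * nvy + vert_idx[..., 1]) * nvz + vert_idx[..., 2]

    # positive orientation
    vcoords = origin + np.stack(
        np.unravel_index(conn4.reshape(-1), ((ncell[0] + 1), nvy, nvz)),
        axis=-1).reshape(-1, 4, 3) * h
    det = np.linalg.det(vcoords[:, 1:] - vcoords[:, :1])
    flip = det < 0
    conn4[flip, 1], conn4[flip, 2] = conn4[flip, 2].copy(), conn4[flip, 1].copy()

    conn4, src = _split_fracture_nodes(conn4, lab)
    nodes, conn10 = _promote_tet10(conn4, src, origin, h, ncell)
    mesh = LabeledMesh(nodes, conn10, lab)
    _check_jacobians(mesh)
    return mesh


def _split_fracture_nodes(conn4: np.ndarray,
                          lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate lattice vertices shared across non-bonded regions.

    Returns the remapped connectivity and ``src``, mapping every vertex id
    (including split copies) back to its lattice vertex.
    """
    group = np.zeros(len(lab), dtype=np.int8)
    for label, g in _GROUP.items():
        group[lab == label] = g

    nv = int(conn4.max()) + 1
    touched = np.zeros((4, nv), dtype=bool)
    for g in range(4):
        touched[g, conn4[group == g].reshape(-1)] = True
    plain = touched[:3]
    cand = ~touched[_GLUE] & (plain.sum(axis=0) >= 2)
    src = np.arange(nv, dtype=np.int64)
    if not cand.any():
        return conn4, src

    min_group = np.full(nv, 3, dtype=np.int8)
    for g in (2, 1, 0):
        min_group[plain[g]] = g

    next_id = nv
    conn4 = conn4.copy()
    src_extra = []
    for g in (1, 2):
        verts = np.flatnonzero(cand & plain[g] & (min_group < g))
        if len(verts) == 0:
            continue
        lut = np.arange(next_id + len(verts), dtype=conn4.dtype)
        lut[verts] = next_id + np.arange(len(verts))
        rows = group == g
        conn4[rows] = lut[conn4[rows]]
        src_extra.append(verts)
        next_id += len(verts)
    if src_extra:
        src = np.concatenate([src] + src_extra)
    return conn4, src


def _promote_tet10(conn4: np.ndarray, src: np.ndarray, origin: np.ndarray,
                   h: float, ncell: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compact vertex ids, add edge midpoints, return (nodes, conn10)."""
    nvy, nvz = ncell[1] + 1, ncell[2] + 1

    used, inv = np.unique(conn4, return_inverse=True)
    conn4c = inv.reshape(conn4.shape).astype(np.int64)

    coords = origin + np.stack(
        np.unravel_index(src[used], ((ncell[0] + 1), nvy, nvz)),
        axis=-1) * h

    edges = conn4c[:, _EDGES]                          # (n_el, 6, 2)
    ekey = np.sort(edges, axis=-1)
    flat = ekey.reshape(-1, 2)
    enc = flat[:, 0] * (conn4c.max() + 1) + flat[:, 1]
    uniq, einv = np.unique(enc, return_inverse=True)
    mid_ids = len(used) + einv.reshape(len(conn4c), 6)
    mid_pairs = np.stack([uniq // (conn4c.max() + 1),
                          uniq % (conn4c.max() + 1)], axis=-1)
    mid_coords = 0.5 * (coords[mid_pairs[:, 0]] + coords[mid_pairs[:, 1]])

    nodes = np.vstack([coords, mid_coords])
    conn10 = np.hstack([conn4c, mid_ids]).astype(np.int64)
    return nodes, conn10


def _check_jacobians(mesh: LabeledMesh) -> None:
    vols = np.linalg.det(mesh.corner_coords()[:, 1:]
                         - mesh.corner_coords()[:, :1]) / 6.0
    if np.any(vols <= 0):
        bad = np.flatnonzero(vols <= 0)[:5].tolist()
        raise ValueError(f"inverted elements produced by meshing: {bad}")


# ---------------------------------------------------------------------------
# Boundary facets and tagging
# ---------------------------------------------------------------------------

def boundary_faces(mesh: LabeledMesh) -> tuple[np.ndarray, np.ndarray]:
    """(element id, local face id) of every boundary face."""
    conn = mesh.elements
    tris = conn[:, _FACES.reshape(-1)].reshape(-1, 3)
    key = np.sort(tris, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                  return_counts=True)
    on_boundary = counts[inv] == 1
    face_el = np.repeat(np.arange(mesh.n_elements), 4)
    face_local = np.tile(np.arange(4), mesh.n_elements)
    return face_el[on_boundary], face_local[on_boundary]


def facet_nodes(mesh: LabeledMesh, face_el: np.ndarray,
                face_local: np.ndarray) -> np.ndarray:
    """TRI6 node ids (3 corners outward-oriented + 3 midsides) per face."""
    out = np.empty((len(face_el), 6), dtype=np.int64)
    conn = mesh.elements
    for i, (e, f) in enumerate(zip(face_el, face_local)):
        lc = _FACES[f]
        corners = conn[e, lc]
        # orient outward: normal away from opposite corner
        opp = conn[e, f]
        a, b, c = mesh.nodes[corners]
        n = np.cross(b - a, c - a)
        if np.dot(n, (a + b + c) / 3.0 - mesh.nodes[opp]) < 0:
            lc = lc[[0, 2, 1]]
            corners = conn[e, lc]
        mids = [conn[e, _EDGE_OF[frozenset((lc[j], lc[(j + 1) % 3]))]]
                for j in range(3)]
        out[i, :3] = corners
        out[i, 3:] = mids
    return out


def facet_areas(mesh: LabeledMesh, facets: np.ndarray) -> np.ndarray:
    a, b, c = (mesh.nodes[facets[:, k]] for k in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def facet_normals(mesh: LabeledMesh, facets: np.ndarray) -> np.ndarray:
    a, b, c = (mesh.nodes[facets[:, k]] for k in range(3))
    n = np.cross(b - a, c - a)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def tag_boundary(mesh: LabeledMesh, geometry_meta: dict) -> None:
    """Tag distal support and condylar patch facets in place.

    Patch facets are accumulated on the articular surface in order of
    distance from the patch center until the nominal patch area is reached,
    so the loaded area tracks the prescribed 403 / 374 mm2.
    """
    face_el, face_local = boundary_faces(mesh)
    facets = facet_nodes(mesh, face_el, face_local)
    areas = facet_areas(mesh, facets)
    normals = facet_normals(mesh, facets)
    centroids = mesh.nodes[facets[:, :3]].mean(axis=1)

    # distal support: every boundary face within one element of the bottom
    # (the voxel mesher can leave a jagged fringe below the lowest full layer)
    h_est = float(np.cbrt(mesh.element_volumes().mean() * 6.0))
    zmin = mesh.nodes[:, 2].min()
    corner_z = mesh.nodes[facets[:, :3], 2]
    distal = np.all(corner_z <= zmin + h_est + 1e-9, axis=1) \
        & (normals[:, 2] < -0.3)
    mesh.boundary_facets["distal_fixed"] = facets[distal]
    mesh.facet_elements["distal_fixed"] = face_el[distal]

    z_top = geometry_meta["articular_z"]
    ztop_mesh = mesh.nodes[:, 2].max()
    top = (np.abs(centroids[:, 2] - ztop_mesh) < 1e-9) & (normals[:, 2] > 0.9) \
        & (np.abs(ztop_mesh - z_top) < 1.0 + 1e-9)
    taken = np.zeros(len(facets), dtype=bool)
    for name in ("lateral", "medial"):
        spec = geometry_meta["condylar_patches"][name]
        center = np.asarray(spec["center"][:2])
        target = float(spec["area_mm2"])
        avail = np.flatnonzero(top & ~taken)
        order = avail[np.argsort(
            np.linalg.norm(centroids[avail, :2] - center, axis=1))]
        cum = np.cumsum(areas[order])
        n_take = int(np.searchsorted(cum, target)) + 1
        n_take = min(n_take, len(order))
        chosen = order[:n_take]
        taken[chosen] = True
        mesh.boundary_facets[f"{name}_patch"] = facets[chosen]
        mesh.facet_elements[f"{name}_patch"] = face_el[chosen]


# ---------------------------------------------------------------------------
# Quality
# ---------------------------------------------------------------------------

@dataclass
class QualityReport:
    aspect_ratio: np.ndarray
    min_dihedral_deg: np.ndarray
    scaled_jacobian: np.ndarray
    quantiles: dict
    failing: dict

    def summary(self) -> dict:
        return {"quantiles": self.quantiles,
                "n_failing": {k: len(v) for k, v in self.failing.items()}}

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "element_id": np.arange(len(self.aspect_ratio)),
            "aspect_ratio": self.aspect_ratio,
            "min_dihedral_deg": self.min_dihedral_deg,
            "scaled_jacobian": self.scaled_jacobian,
        }).to_csv(path, index=False)

    def summary_json(self, path) -> None:
        import json
        from pathlib import Path
        Path(path).write_text(json.dumps(self.summary(), indent=2,
                                         sort_keys=True))


def check_quality(mesh: LabeledMesh, aspect_max: float = 3.0,
                  dihedral_min_deg: float = 10.0,
                  scaled_jacobian_min: float = 0.2) -> QualityReport:
    """Per-element quality metrics; warns (never fails) on threshold trips.

    Aspect ratio is longest edge / (2*sqrt(6) * inradius), which equals 1 for
    the regular tetrahedron; scaled Jacobian is the corner-normalized volume
    determinant, also 1 for the regular tetrahedron.
    """
    c = mesh.corner_coords()
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edge_vec = np.stack([c[:, j] - c[:, i] for i, j in pairs], axis=1)
    edge_len = np.linalg.norm(edge_vec, axis=2)
    lmax = edge_len.max(axis=1)

    vol = np.abs(np.linalg.det(c[:, 1:] - c[:, :1])) / 6.0
    face_area = np.zeros(len(c))
    for f in _FACES:
        a, b, d = c[:, f[0]], c[:, f[1]], c[:, f[2]]
        face_area += 0.5 * np.linalg.norm(np.cross(b - a, d - a), axis=1)
    r_in = 3.0 * vol / face_area
    aspect = lmax / (2.0 * np.sqrt(6.0) * r_in)

    # dihedral angles from face normals (6 edges, each between two faces)
    normals = np.empty((len(c), 4, 3))
    for k, f in enumerate(_FACES):
        a, b, d = c[:, f[0]], c[:, f[1]], c[:, f[2]]
        n = np.cross(b - a, d - a)
        normals[:, k] = n / np.linalg.norm(n, axis=1, keepdims=True)
    min_dih = np.full(len(c), np.inf)
    face_pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    for i, j in face_pairs:
        cosang = np.clip(np.sum(normals[:, i] * normals[:, j], axis=1), -1, 1)
        dih = np.degrees(np.pi - np.arccos(cosang))
        min_dih = np.minimum(min_dih, dih)

    # scaled Jacobian: min over corners of sqrt(2)*det/(product of edge norms)
    sj = np.full(len(c), np.inf)
    for corner in range(4):
        others = [k for k in range(4) if k != corner]
        e = c[:, others] - c[:, corner:corner + 1]
        det = np.linalg.det(e)
        prod = np.prod(np.linalg.norm(e, axis=2), axis=1)
        sj = np.minimum(sj, np.sqrt(2.0) * np.abs(det) / prod)

    failing = {
        "aspect_ratio": np.flatnonzero(aspect > aspect_max),
        "min_dihedral_deg": np.flatnonzero(min_dih < dihedral_min_deg),
        "scaled_jacobian": np.flatnonzero(sj < scaled_jacobian_min),
    }
    if any(len(v) for v in failing.values()):
        warnings.warn("mesh quality thresholds violated: "
                      + ", ".join(f"{k}: {len(v)}" for k, v in failing.items()
                                  if len(v)), stacklevel=2)
    qs = {}
    for name, arr in (("aspect_ratio", aspect), ("min_dihedral_deg", min_dih),
                      ("scaled_jacobian", sj)):
        qs[name] = {f"q{q}": float(np.percentile(arr, q)) for q in (25, 50, 75)}
    return QualityReport(aspect, min_dih, sj, qs, failing)


# ---------------------------------------------------------------------------
# Interface pairing
# ---------------------------------------------------------------------------

def _tri6_weights(bary: np.ndarray) -> np.ndarray:
    """TRI6 shape functions at barycentric (L1, L2, L3)."""
    l1, l2, l3 = bary
    return np.array([l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
                     4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1])


def _closest_point_triangle(p, a, b, c):
    """Closest point on triangle abc to p; returns (point, barycentric)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a, np.array([1.0, 0.0, 0.0])
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b, np.array([0.0, 1.0, 0.0])
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return a + v * ab, np.array([1 - v, v, 0.0])
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c, np.array([0.0, 0.0, 1.0])
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return a + w * ac, np.array([1 - w, 0.0, w])
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b), np.array([0.0, 1 - w, w])
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return a + ab * v + ac * w, np.array([1 - v - w, v, w])


def find_interface_pairs(mesh: LabeledMesh, fragment: str,
                         cutoff: float, min_gap: float = 0.0) -> InterfacePairs:
    """Closest-point pairing of fragment surface nodes onto the parent surface.

    Pairs whose initial gap exceeds ``cutoff`` (conventionally twice the
    nominal fracture gap) are discarded, as are pairs below ``min_gap``
    (coincident duplicated lattice corners are aliasing artifacts when the
    true surfaces are separated by a fracture gap).
    """
    if fragment not in FRAGMENT_LABEL:
        raise ValueError(f"unknown fragment {fragment!r}")
    flabel = FRAGMENT_LABEL[fragment]
    if not np.any(mesh.labels == flabel):
        raise ValueError(f"no {fragment} fragment in mesh (fused state?)")

    face_el, face_local = boundary_faces(mesh)
    el_labels = mesh.labels[face_el]
    frag_faces = facet_nodes(mesh, face_el[el_labels == flabel],
                             face_local[el_labels == flabel])
    parent_sel = np.isin(el_labels, PARENT_LABELS)
    parent_faces = facet_nodes(mesh, face_el[parent_sel],
                               face_local[parent_sel])
    if len(frag_faces) == 0 or len(parent_faces) == 0:
        raise ValueError("interface mis-specified: missing surfaces")

    frag_nodes = np.unique(frag_faces)
    # outward surface normal per fragment node (area-weighted average of its
    # adjacent boundary faces): only parent facets facing *against* it are
    # admissible targets, so coplanar side walls never capture a pairing
    fnorm = facet_normals(mesh, frag_faces)
    farea = facet_areas(mesh, frag_faces)
    node_normal = np.zeros((mesh.n_nodes, 3))
    for j in range(6):
        np.add.at(node_normal, frag_faces[:, j], farea[:, None] * fnorm)
    # tributary areas, consistent-load style: facet area split over midsides
    node_area = np.zeros(mesh.n_nodes)
    for j in range(3, 6):
        np.add.at(node_area, frag_faces[:, j], farea / 3.0)
    lens = np.linalg.norm(node_normal, axis=1, keepdims=True)
    node_normal = np.divide(node_normal, lens, out=np.zeros_like(node_normal),
                            where=lens > 0)

    pcent = mesh.nodes[parent_faces[:, :3]].mean(axis=1)
    pnorm = facet_normals(mesh, parent_faces)
    tree = cKDTree(pcent)
    pts = mesh.nodes[frag_nodes]
    k = min(16, len(parent_faces))
    _, cand = tree.query(pts, k=k, distance_upper_bound=cutoff + 3.0)
    if k == 1:
        cand = cand[:, None]

    keep_nodes, opp_nodes, opp_w, gaps, normals = [], [], [], [], []
    for i, node in enumerate(frag_nodes):
        p = pts[i]
        nn = node_normal[node]
        best = (np.inf, None, None)
        for fidx in cand[i]:
            if fidx >= len(parent_faces):
                continue
            if pnorm[fidx] @ nn > -0.1:
                continue
            tri = parent_faces[fidx]
            a, b, c = mesh.nodes[tri[0]], mesh.nodes[tri[1]], mesh.nodes[tri[2]]
            q, bary = _closest_point_triangle(p, a, b, c)
            d = np.linalg.norm(p - q)
            if d < best[0]:
                best = (d, fidx, bary)
        d, fidx, bary = best
        if fidx is None or d > cutoff or d < min_gap:
            continue
        tri = parent_faces[fidx]
        a, b, c = mesh.nodes[tri[0]], mesh.nodes[tri[1]], mesh.nodes[tri[2]]
        n = np.cross(b - a, c - a)
        n = n / np.linalg.norm(n)
        q = a + (b - a) * bary[1] + (c - a) * bary[2]
        if d > 1e-9:
            direction = (p - q) / d
            if direction @ n < 0:
                n = -n
            n = direction          # pair direction is the contact normal
        keep_nodes.append(node)
        opp_nodes.append(tri)
        opp_w.append(_tri6_weights(bary))
        gaps.append(d)
        normals.append(n)

    if not keep_nodes:
        raise ValueError(f"interface mis-specified: zero pairs for {fragment}")
    keep = np.array(keep_nodes)
    return InterfacePairs(fragment, keep,
                          np.array(opp_nodes), np.array(opp_w),
                          np.array(gaps), np.array(normals),
                          node_area[keep])
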