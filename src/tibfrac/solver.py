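"""Static small-strain linear elasticity on labeled TET10 meshes.

Quadratic tetrahedra with 4-point Gauss quadrature (exact for the
straight-sided elements produced by the mesher), heterogeneous isotropic
materials, fixed distal supports, and two fracture-interface conditions:

* ``bonded`` -- every interface pair is tied in all directions with stiff
  penalty springs (callus stage);
* ``frictionless`` -- normal-only, compression-only contact resolved by an
  active-set penalty iteration (early, mobile stage).  Pairs start inactive;
  pairs penetrating beyond tolerance are activated, tensile pairs released,
  until the active set is a fixed point.

The small-displacement regime of the application (total displacements well
below a tenth of a millimetre, fracture gaps of millimetres) justifies
fixed, small-sliding pairings established once from the reference geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.linalg as spla

from .materials import MaterialField
from .mesh import InterfacePairs, LabeledMesh, facet_areas

GRAVITY = 9.81  # m/s2

# 4-point Gauss rule on the tetrahedron (degree 2), barycentric coordinates
_GA = 0.5854101966249685
_GB = 0.1381966011250105
_GAUSS = np.array([
    [_GA, _GB, _GB, _GB],
    [_GB, _GA, _GB, _GB],
    [_GB, _GB, _GA, _GB],
    [_GB, _GB, _GB, _GA],
])
_GW = np.full(4, 0.25)

_CENTROID = np.full((1, 4), 0.25)


@dataclass
class LoadCase:
    """Peak gait loading split between the two condylar patches."""

    body_mass: float                    # kg
    load_factor: float = 2.59           # x body weight at peak gait
    lateral_fraction: float = 0.37
    lateral_patch_area: float = 403.0   # mm2
    medial_patch_area: float = 374.0    # mm2
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if not 0 < self.lateral_fraction < 1:
            raise ValueError("lateral_fraction must lie in (0, 1)")
        if self.lateral_patch_area <= 0 or self.medial_patch_area <= 0:
            raise ValueError("patch areas must be > 0")

    @property
    def medial_fraction(self) -> float:
        return 1.0 - self.lateral_fraction

    def total_force(self) -> float:
        """Total axial force, N."""
        return self.load_factor * self.body_mass * self.gravity


@dataclass
class ContactSpec:
    """Interface treatment for the fracture surfaces."""

    pairs: list[InterfacePairs]
    mode: str = "frictionless"          # frictionless | bonded
    penalty: float | None = None        # N/mm per pair; default from materials
    penetration_tol: float = 1e-3       # mm
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("frictionless", "bonded"):
            raise ValueError(f"unknown contact mode {self.mode!r}")


@dataclass
class SolutionField:
    """Displacements, element stresses, reactions, and contact state."""

    displacements: np.ndarray          # (n_nodes, 3) mm
    stress: np.ndarray                 # (n_el, 6) Voigt [xx,yy,zz,xy,yz,zx] MPa
    reactions: np.ndarray              # (n_nodes, 3) N, nonzero at supports
    contact_active: dict               # fragment -> bool array per pair
    contact_gaps: dict                 # fragment -> final gap per pair, mm
    residual: float
    iterations: int

    def stress_tensors(self) -> np.ndarray:
        s = self.stress
        t = np.zeros((len(s), 3, 3))
        t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
        t[:, 0, 1] = t[:, 1, 0] = s[:, 3]
        t[:, 1, 2] = t[:, 2, 1] = s[:, 4]
        t[:, 0, 2] = t[:, 2, 0] = s[:, 5]
        return t


# ---------------------------------------------------------------------------
# Element kinematics
# ---------------------------------------------------------------------------

def _barycentric_gradients(corners: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the 4 barycentric coordinates and element volumes."""
    n = len(corners)
    M = np.empty((n, 4, 4))
    M[:, :, 0] = 1.0
    M[:, :, 1:] = corners
    Minv = np.linalg.inv(M)
    grads = Minv[:, 1:, :].transpose(0, 2, 1)       # (n_el, 4, 3)
    vol = np.abs(np.linalg.det(corners[:, 1:] - corners[:, :1])) / 6.0
    return grads, vol


def _shape_gradients(grads: np.ndarray, bary: np.ndarray) -> np.ndarray:
    """TET10 shape-function gradients at one barycentric point: (n_el, 10, 3)."""
    n = len(grads)
    dN = np.empty((n, 10, 3))
    for k in range(4):
        dN[:, k] = (4.0 * bary[k] - 1.0) * grads[:, k]
    edges = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    for m, (a, b) in enumerate(edges):
        dN[:, 4 + m] = 4.0 * (bary[a] * grads[:, b] + bary[b] * grads[:, a])
    return dN


def _b_matrix(dN: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix, engineering shear: (n_el, 6, 30)."""
    n = len(dN)
    B = np.zeros((n, 6, 30))
    dx, dy, dz = dN[:, :, 0], dN[:, :, 1], dN[:, :, 2]
    B[:, 0, 0::3] = dx
    B[:, 1, 1::3] = dy
    B[:, 2, 2::3] = dz
    B[:, 3, 0::3] = dy
    B[:, 3, 1::3] = dx
    B[:, 4, 1::3] = dz
    B[:, 4, 2::3] = dy
    B[:, 5, 0::3] = dz
    B[:, 5, 2::3] = dx
    return B


def _elasticity_tensors(materials: MaterialField) -> np.ndarray:
    E, nu = materials.young_modulus, materials.poisson
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    n = len(E)
    D = np.zeros((n, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

@dataclass
class FESystem:
    mesh: LabeledMesh
    materials: MaterialField
    K: sparse.csr_matrix
    f: np.ndarray
    fixed_mask: np.ndarray            # (ndof,) bool
    fixed_values: np.ndarray          # (ndof,)
    B_centroid: np.ndarray            # (n_el, 6, 30)
    D: np.ndarray                     # (n_el, 6, 6)
    edof: np.ndarray                  # (n_el, 30)
    notes: dict = field(default_factory=dict)

    @property
    def ndof(self) -> int:
        return len(self.f)

    def fresh(self) -> "FESystem":
        """A copy sharing the assembled operator but with clean loads/BCs."""
        return FESystem(self.mesh, self.materials, self.K,
                        np.zeros(self.ndof), np.zeros(self.ndof, dtype=bool),
                        np.zeros(self.ndof), self.B_centroid, self.D,
                        self.edof)

    def fix_nodes(self, node_ids: np.ndarray,
                  values: np.ndarray | float = 0.0) -> None:
        node_ids = np.asarray(node_ids)
        dofs = (3 * node_ids[:, None] + np.arange(3)).reshape(-1)
        self.fixed_mask[dofs] = True
        vals = np.broadcast_to(np.asarray(values, dtype=float),
                               (len(node_ids), 3)).reshape(-1)
        self.fixed_values[dofs] = vals

    def fix_component(self, node_ids: np.ndarray, component: int,
                      value: float | np.ndarray = 0.0) -> None:
        """Constrain a single displacement component (roller supports)."""
        node_ids = np.asarray(node_ids)
        dofs = 3 * node_ids + component
        self.fixed_mask[dofs] = True
        self.fixed_values[dofs] = value

    def add_nodal_forces(self, node_ids: np.ndarray, forces: np.ndarray) -> None:
        node_ids = np.asarray(node_ids)
        forces = np.broadcast_to(np.asarray(forces, dtype=float),
                                 (len(node_ids), 3))
        np.add.at(self.f, 3 * node_ids[:, None] + np.arange(3), forces)

    def apply_pressure(self, tag: str, pressure: float,
                       direction=(0.0, 0.0, -1.0)) -> float:
        """Uniform pressure on a tagged facet set via consistent TRI6 loads.

        For a straight TRI6 facet under constant traction the consistent
        nodal forces are zero at the corners and one third of the facet force
        at each midside.  Returns the total applied force magnitude.
        """
        facets = self.mesh.boundary_facets.get(tag)
        if facets is None or len(facets) == 0:
            raise ValueError(f"no facets tagged {tag!r}")
        areas = facet_areas(self.mesh, facets)
        if areas.sum() <= 0:
            raise ValueError(f"zero patch area for {tag!r}")
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        per_mid = pressure * areas / 3.0
        for k in range(3, 6):
            np.add.at(self.f, 3 * facets[:, k, None] + np.arange(3),
                      per_mid[:, None] * d)
        return pressure * areas.sum()


def assemble_system(mesh: LabeledMesh, materials: MaterialField) -> FESystem:
    """Assemble the global stiffness operator and stress-recovery data."""
    if materials.n_elements != mesh.n_elements:
        raise ValueError("materials and mesh element counts differ")
    if np.any(materials.young_modulus <= 0) or \
            np.any((materials.poisson < 0) | (materials.poisson >= 0.5)):
        raise ValueError("materials must be positive definite (E > 0, 0 <= nu < 0.5)")

    corners = mesh.corner_coords()
    grads, vol = _barycentric_gradients(corners)
    D = _elasticity_tensors(materials)

    n_el = mesh.n_elements
    Ke = np.zeros((n_el, 30, 30))
    for gp in range(4):
        B = _b_matrix(_shape_gradients(grads, _GAUSS[gp]))
        DB = np.einsum("eij,ejk->eik", D, B)
        Ke += _GW[gp] * vol[:, None, None] * np.einsum("eji,ejk->eik", B, DB)

    if not np.all(np.isfinite(Ke)):
        bad = int(np.flatnonzero(~np.isfinite(Ke).all(axis=(1, 2)))[0])
        raise ValueError(f"non-finite stiffness entries in element {bad}")

    edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(n_el, 30)
    rows = np.repeat(edof, 30, axis=1).reshape(-1)
    cols = np.tile(edof, (1, 30)).reshape(-1)
    ndof = 3 * mesh.n_nodes
    K = sparse.coo_matrix((Ke.reshape(-1), (rows, cols)),
                          shape=(ndof, ndof)).tocsr()

    B_cent = _b_matrix(_shape_gradients(grads, _CENTROID[0]))
    return FESystem(mesh, materials, K, np.zeros(ndof),
                    np.zeros(ndof, dtype=bool), np.zeros(ndof),
                    B_cent, D, edof)


def apply_supports_and_ties(system: FESystem) -> FESystem:
    """Fix all DOFs of the distal support nodes.

    Bonded hardware interfaces (screw-bone, cement-bone, fused plateau) share
    nodes by mesh construction and need no extra constraints; fragment
    interface ties belong to the bonded ContactSpec.
    """
    facets = system.mesh.boundary_facets.get("distal_fixed")
    if facets is None or len(facets) == 0:
        raise ValueError("no distal_fixed facets tagged; system would be singular")
    system.fix_nodes(np.unique(facets))
    return system


def apply_loads(system: FESystem, load_case: LoadCase) -> FESystem:
    """Distribute the peak gait force over the condylar patches as pressure.

    The pressure on each patch is its force share divided by the *achieved*
    facet area, so the integral of the applied tractions equals the
    prescribed force exactly; a mismatch between achieved and nominal patch
    area beyond 15% raises a warning.
    """
    total = load_case.total_force()
    shares = {"lateral_patch": (load_case.lateral_fraction,
                                load_case.lateral_patch_area),
              "medial_patch": (load_case.medial_fraction,
                               load_case.medial_patch_area)}
    for tag, (frac, nominal) in shares.items():
        facets = system.mesh.boundary_facets.get(tag)
        if facets is None or len(facets) == 0:
            raise ValueError(f"no facets tagged {tag!r}")
        achieved = float(facet_areas(system.mesh, facets).sum())
        if achieved <= 0:
            raise ValueError(f"zero area for {tag!r}")
        if abs(achieved - nominal) / nominal > 0.15:
            warnings.warn(f"{tag} area {achieved:.1f} mm2 deviates >15% from "
                          f"nominal {nominal:.1f} mm2", stacklevel=2)
        system.apply_pressure(tag, frac * total / achieved)
        system.notes[f"{tag}_area_mm2"] = achieved
        system.notes[f"{tag}_force_N"] = frac * total
    return system


# ---------------------------------------------------------------------------
# Contact machinery
# ---------------------------------------------------------------------------

def default_penalty(mesh: LabeledMesh, materials: MaterialField,
                    pairs: list[InterfacePairs]) -> float:
    """Stiff-but-conditioned penalty: 100 x (interface E x tributary area / size)."""
    labels = {p.fragment for p in pairs}
    from .mesh import FRAGMENT_LABEL
    sel = np.isin(mesh.labels, [FRAGMENT_LABEL[f] for f in labels])
    E_mean = float(materials.young_modulus[sel].mean()) if sel.any() \
        else float(materials.young_modulus.mean())
    h = float(np.cbrt(mesh.element_volumes().mean() * 6.0))
    return 100.0 * E_mean * (h * h / 2.0) / h


def _tie_rows(system: FESystem, pairs: InterfacePairs) -> sparse.csr_matrix:
    """Node-to-nearest-node tie rows, one per pair and direction.

    Bonded ties use a 1-to-1 coupling with the geometrically closest node of
    the opposing facet: with the mesher's matched lattice surfaces this is an
    accurate tie, and it keeps the factorization fill close to the untied
    operator (facet-interpolated ties couple each pair to seven nodes and
    roughly double the fill).
    """
    coords = system.mesh.nodes
    d2 = np.linalg.norm(coords[pairs.opposing_nodes]
                        - coords[pairs.node_ids][:, None, :], axis=2)
    nearest = pairs.opposing_nodes[np.arange(len(pairs)), d2.argmin(axis=1)]
    n_p = len(pairs)
    rows = np.repeat(np.arange(3 * n_p), 2)
    cols = np.empty(6 * n_p, dtype=np.int64)
    vals = np.tile([1.0, -1.0], 3 * n_p)
    for c in range(3):
        cols[2 * c * n_p:2 * (c + 1) * n_p:2] = 3 * pairs.node_ids + c
        cols[2 * c * n_p + 1:2 * (c + 1) * n_p:2] = 3 * nearest + c
    return sparse.csr_matrix((vals, (rows, cols)),
                             shape=(3 * n_p, system.ndof))


def _pair_rows(system: FESystem, pairs: InterfacePairs,
               directions: np.ndarray) -> sparse.csr_matrix:
    """Sparse rows a such that a @ u = d . (u_node - u_opposing) per pair."""
    n_p = len(pairs)
    rows, cols, vals = [], [], []
    for i in range(n_p):
        d = directions[i]
        for c in range(3):
            rows.append(i)
            cols.append(3 * pairs.node_ids[i] + c)
            vals.append(d[c])
        for j in range(6):
            w = pairs.opposing_weights[i, j]
            if abs(w) < 1e-14:
                continue
            for c in range(3):
                rows.append(i)
                cols.append(3 * pairs.opposing_nodes[i, j] + c)
                vals.append(-w * d[c])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n_p, system.ndof))


def solve_static(system: FESystem,
                 contact: ContactSpec | None = None) -> SolutionField:
    """Solve the constrained system, iterating the contact active set."""
    free = ~system.fixed_mask
    if free.all():
        raise ValueError("no supports applied; system is singular")
    K = system.K
    uc = system.fixed_values
    f_eff = system.f - K @ (np.where(system.fixed_mask, uc, 0.0))
    Kff = K[free][:, free].tocsc()
    rhs = f_eff[free]

    pair_data = []
    kp = None
    if contact is not None and contact.pairs:
        kp = contact.penalty
        if kp is None:
            kp = default_penalty(system.mesh, system.materials, contact.pairs)
        for pr in contact.pairs:
            if contact.mode == "bonded":
                A = _tie_rows(system, pr)
            else:
                A = _pair_rows(system, pr, pr.normals)
            pair_data.append((pr, A[:, free].tocsr()))

    def factor(extra):
        M = Kff if extra is None else (Kff + extra).tocsc()
        try:
            return spla.splu(M, permc_spec="COLAMD")
        except RuntimeError as exc:
            raise ValueError(f"singular system (insufficient constraints?): "
                             f"{exc}") from exc

    contact_active: dict[str, np.ndarray] = {}
    contact_gaps: dict[str, np.ndarray] = {}
    iterations = 1
    contact_force = np.zeros(system.ndof)   # internal force from penalty springs

    if contact is None or not pair_data:
        u_f = factor(None).solve(rhs)
    elif contact.mode == "bonded":
        # Ties resist any relative displacement jump across the interface.
        # Tie stiffness is bone-scale (the callus bridges at tissue-level
        # stiffness, the 100x contact penalty would inject point loads into
        # the trabecular surface) and is distributed over the pairs by
        # tributary surface area, which keeps the transferred traction
        # smooth instead of spiking at interface corners.
        kp_tie = kp if contact.penalty is not None else kp / 1000.0
        extra = None
        weights = []
        for pr, A in pair_data:
            if pr.areas is not None and np.any(pr.areas > 0):
                w = pr.areas / pr.areas.mean()
                w = np.maximum(w, 0.05)
            else:
                w = np.ones(len(pr))
            W = sparse.diags(np.tile(w, 3))
            term = kp_tie * (A.T @ (W @ A))
            extra = term if extra is None else extra + term
            weights.append(w)
        u_f = factor(extra).solve(rhs)
        for (pr, A), w in zip(pair_data, weights):
            jump = (A @ u_f).reshape(3, len(pr))
            contact_active[pr.fragment] = np.ones(len(pr), dtype=bool)
            contact_gaps[pr.fragment] = pr.gaps + np.einsum(
                "pc,cp->p", pr.normals, jump)
            W = sparse.diags(np.tile(w, 3))
            contact_force += _scatter(A, free, kp_tie * (W @ (A @ u_f)),
                                      system.ndof)
    else:
        # active-set penalty: gap g = g0 + a.u, spring pushes when g < 0.
        # Initially touching pairs start active (and release if tensile), so
        # a body supported only through contact is never left floating.
        # Small active sets are solved by a Woodbury low-rank update of the
        # base factorization, so the active-set loop refactorizes only when
        # many pairs engage.
        base_lu = factor(None)
        active = [pr.gaps <= 0 for pr, _ in pair_data]
        history: list[tuple] = []
        u_f = None
        for it in range(contact.max_iterations):
            iterations = it + 1
            rows = []
            rhs_it = rhs.copy()
            for (pr, A), act in zip(pair_data, active):
                if act.any():
                    Aa = A[np.flatnonzero(act)]
                    rows.append(Aa)
                    rhs_it -= kp * (Aa.T @ pr.gaps[act])
            if not rows:
                u_f = base_lu.solve(rhs_it)
            else:
                Aall = sparse.vstack(rows).tocsr()
                r = Aall.shape[0]
                u_f = None
                if r <= 200:
                    X = base_lu.solve(Aall.T.toarray())
                    y0 = base_lu.solve(rhs_it)
                    C = np.eye(r) / kp + Aall @ X
                    u_f = y0 - X @ np.linalg.solve(C, Aall @ y0)
                    # the update is only valid when the base operator was
                    # nonsingular (a body held by contact alone is not)
                    res = Kff @ u_f + kp * (Aall.T @ (Aall @ u_f)) - rhs_it
                    if not np.all(np.isfinite(u_f)) or np.linalg.norm(res) \
                            > 1e-8 * max(np.linalg.norm(rhs_it), 1e-30):
                        u_f = None
                if u_f is None:
                    u_f = factor(kp * (Aall.T @ Aall)).solve(rhs_it)
            new_active = []
            for (pr, A), act in zip(pair_data, active):
                g = pr.gaps + A @ u_f
                # activate pairs penetrating beyond tolerance, keep active
                # pairs still in compression, release tensile pairs
                new_active.append((g < -contact.penetration_tol)
                                  | (act & (g < 0)))
            if all((na == a).all() for na, a in zip(new_active, active)):
                break
            sig = tuple(arr.tobytes() for arr in new_active)
            if sig in history:
                osc = [int(np.flatnonzero(na != a)[0])
                       for na, a in zip(new_active, active) if (na != a).any()]
                raise ValueError("contact active set oscillates; first "
                                 f"oscillating pairs {osc}")
            history.append(sig)
            active = new_active
        else:
            raise ValueError("contact active set failed to converge in "
                             f"{contact.max_iterations} iterations")
        for (pr, A), act in zip(pair_data, active):
            g = pr.gaps + A @ u_f
            contact_active[pr.fragment] = act
            contact_gaps[pr.fragment] = g
            if act.any():
                Aa = A[np.flatnonzero(act)]
                contact_force += _scatter(Aa, free, kp * g[act], system.ndof)

    u = np.where(system.fixed_mask, uc, 0.0)
    u[np.flatnonzero(free)] = u_f

    # equilibrium residual on free DOFs (internal minus external forces)
    internal = K @ u + contact_force
    res_num = np.linalg.norm((internal - system.f)[free])
    res_den = max(np.linalg.norm(system.f), 1e-30)
    residual = float(res_num / res_den)

    reactions = np.zeros(system.ndof)
    reactions[system.fixed_mask] = (internal - system.f)[system.fixed_mask]

    ue = u[system.edof]
    strain = np.einsum("eik,ek->ei", system.B_centroid, ue)
    stress = np.einsum("eij,ej->ei", system.D, strain)

    return SolutionField(u.reshape(-1, 3), stress, reactions.reshape(-1, 3),
                         contact_active, contact_gaps, residual, iterations)


def _scatter(A: sparse.csr_matrix, free: np.ndarray, lam: np.ndarray,
             ndof: int) -> np.ndarray:
    out = np.zeros(ndof)
    out[np.flatnonzero(free)] = A.T @ lam
    return out


def strain_energy(system: FESystem, solution: SolutionField) -> float:
    u = solution.displacements.reshape(-1)
    return float(0.5 * u @ (system.K @ u))


def external_work(system: FESystem, solution: SolutionField) -> float:
    u = solution.displacements.reshape(-1)
    return float(0.5 * system.f @ u)
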