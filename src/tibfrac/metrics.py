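"""Fracture-stability outcome metrics.

From a solved scenario we extract the quantities used to judge fixation:
von Mises stress extrema per material, the volume of bone loaded beyond its
local (density-dependent) yield strength, reduction-loss displacements of
the fragments, and interfragmentary strains (relative interface movement
over initial gap).  A scenario counts as stable when no bone volume exceeds
yield and every interfragmentary strain stays below 10%, the strain limit
cited for secondary bone healing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import phantom as ph
from .materials import MaterialField
from .mesh import InterfacePairs, LabeledMesh
from .solver import SolutionField

STRAIN_LIMIT_PCT = 10.0
HARDWARE_STRESS_LIMIT_FRACTION = 0.20


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress.

    Accepts Voigt rows ``[xx, yy, zz, xy, yz, zx]`` of shape (n, 6) or full
    tensors of shape (n, 3, 3); tensors asymmetric beyond 1e-8 (relative)
    are rejected.
    """
    s = np.asarray(stress, dtype=float)
    single = False
    if s.ndim == 2 and s.shape == (3, 3):
        s = s[None]
        single = True
    if s.ndim == 3:
        scale = max(np.abs(s).max(), 1.0)
        if np.abs(s - s.transpose(0, 2, 1)).max() > 1e-8 * scale:
            raise ValueError("stress tensor not symmetric (beyond 1e-8)")
        v = np.stack([s[:, 0, 0], s[:, 1, 1], s[:, 2, 2],
                      s[:, 0, 1], s[:, 1, 2], s[:, 0, 2]], axis=1)
    elif s.ndim == 2 and s.shape[1] == 6:
        v = s
    elif s.ndim == 1 and s.shape[0] == 6:
        v = s[None]
        single = True
    else:
        raise ValueError("expected (n,6) Voigt or (n,3,3) tensors")
    sxx, syy, szz, sxy, syz, szx = v.T
    vm = np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                 + 3.0 * (sxy**2 + syz**2 + szx**2))
    return float(vm[0]) if single else vm


def yield_volume(vm: np.ndarray, materials: MaterialField,
                 mesh: LabeledMesh) -> float:
    """Total volume (mm3) of bone elements with von Mises above local yield."""
    if materials.yield_strength is None or len(materials.yield_strength) != len(vm):
        raise ValueError("yield strengths missing or misaligned")
    bone = materials.is_bone()
    over = bone & (vm > materials.yield_strength)
    return float(mesh.element_volumes()[over].sum())


def interfragmentary_strain(solution: SolutionField,
                            pairs: InterfacePairs) -> float:
    """Maximum interfragmentary strain (%) over the interface pairs.

    Per pair the interfragmentary movement is the magnitude of the 3-D
    relative displacement between the fragment node and its projection on
    the parent surface; the strain is that movement over the pair's initial
    gap.  Zero-gap pairs are excluded (division guard).
    """
    u = solution.displacements
    du = u[pairs.node_ids] - np.einsum(
        "pj,pjc->pc", pairs.opposing_weights, u[pairs.opposing_nodes])
    movement = np.linalg.norm(du, axis=1)
    ok = pairs.gaps > 1e-9
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} zero-gap pairs excluded from "
                      "interfragmentary strain", stacklevel=2)
    if not ok.any():
        raise ValueError("no pairs with positive initial gap")
    return float((movement[ok] / pairs.gaps[ok]).max() * 100.0)


def reduction_loss_depressed(solution: SolutionField,
                             mesh: LabeledMesh) -> float:
    """Max distal-proximal (|z|) displacement of the depressed fragment, mm."""
    nodes = np.unique(mesh.elements[mesh.labels == ph.FRAG_DEPRESSED])
    if len(nodes) == 0:
        raise ValueError("no depressed-fragment nodes")
    return float(np.abs(solution.displacements[nodes, 2]).max())


def separation_opening(solution: SolutionField,
                       pairs: InterfacePairs) -> float:
    """Max medial-lateral opening of the separated fragment, mm (lateral +)."""
    if pairs.fragment != "separated":
        raise ValueError("separation opening needs the separated-fragment pairs")
    u = solution.displacements
    du = u[pairs.node_ids] - np.einsum(
        "pj,pjc->pc", pairs.opposing_weights, u[pairs.opposing_nodes])
    return float(du[:, 0].max())


@dataclass
class StabilityReport:
    """Per-scenario outcome metrics mirroring the study's comparison table."""

    scenario_id: int
    screw_variant: str
    cement: bool
    interface: str
    max_von_mises: dict                       # material class -> MPa
    yield_volume_mm3: float
    reduction_loss_depressed_mm: float | None
    separation_opening_mm: float | None
    max_strain_depressed_pct: float | None    # None for fused ("--")
    max_strain_separated_pct: float | None
    max_total_displacement_mm: float
    screw_stress_fraction: float | None       # of titanium yield
    cement_stress_fraction: float | None      # of PMMA yield
    stable: bool

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize(scenario_id: int, screw_variant: str, cement: bool,
              interface: str, solution: SolutionField,
              materials: MaterialField, mesh: LabeledMesh,
              strains: dict | None,
              reduction_depressed: float | None,
              opening: float | None) -> StabilityReport:
    """Assemble the stability report for one scenario."""
    from .materials import CLASS_PMMA, CLASS_TITANIUM, PMMA, TITANIUM

    vm = von_mises(solution.stress)
    max_vm = {}
    for cls in np.unique(materials.material_class):
        max_vm[str(cls)] = float(vm[materials.material_class == cls].max())
    yv = yield_volume(vm, materials, mesh)

    strains = strains or {}
    strain_values = [s for s in strains.values() if s is not None]
    stable = (yv == 0.0) and all(s < STRAIN_LIMIT_PCT for s in strain_values)

    screw_frac = (max_vm[CLASS_TITANIUM] / TITANIUM["yield"]
                  if CLASS_TITANIUM in max_vm else None)
    cement_frac = (max_vm[CLASS_PMMA] / PMMA["yield"]
                   if CLASS_PMMA in max_vm else None)

    return StabilityReport(
        scenario_id=scenario_id,
        screw_variant=screw_variant,
        cement=cement,
        interface=interface,
        max_von_mises=max_vm,
        yield_volume_mm3=yv,
        reduction_loss_depressed_mm=reduction_depressed,
        separation_opening_mm=opening,
        max_strain_depressed_pct=strains.get("depressed"),
        max_strain_separated_pct=strains.get("separated"),
        max_total_displacement_mm=float(
            np.linalg.norm(solution.displacements, axis=1).max()),
        screw_stress_fraction=screw_frac,
        cement_stress_fraction=cement_frac,
        stable=bool(stable),
    )
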