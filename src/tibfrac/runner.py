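"""End-to-end orchestration of the 12-scenario stabilization matrix.

Two screw variants x cement yes/no x three healing states (mobile, bonded,
fused) make twelve scenarios.  Each runs the full pipeline: phantom ->
density calibration -> mesh -> material mapping -> FE solve -> stability
metrics.  Mobile and bonded scenarios share the same phantom and mesh (only
the interface condition differs); fused scenarios merge the fragments and
fill the gaps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import phantom as ph
from .calibration import calibrate_phantom
from .materials import (classify_and_assign, fill_screw_void,
                        sample_element_density)
from .mesh import (check_quality, find_interface_pairs, mesh_domains,
                   tag_boundary)
from .metrics import (StabilityReport, interfragmentary_strain,
                      reduction_loss_depressed, separation_opening, summarize)
from .phantom import PhantomParams, build_phantom
from .solver import (ContactSpec, LoadCase, apply_loads,
                     apply_supports_and_ties, assemble_system, solve_static)
from .vtu import write_vtu

log = logging.getLogger("tibfrac")

HEALING_LABEL = {"mobile": "before 3 weeks",
                 "bonded": "6-12 weeks",
                 "fused": "1 year"}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the stabilization matrix."""

    id: int
    screw_variant: str      # bicortical_70 | unicortical_50
    cement: bool
    interface: str          # mobile | bonded | fused

    @property
    def healing_label(self) -> str:
        return HEALING_LABEL[self.interface]


def build_scenario_matrix(config: "RunConfig | None" = None) -> list[ScenarioSpec]:
    """The twelve scenarios in canonical order (screw, cement, interface)."""
    specs = []
    i = 1
    for screw in ("bicortical_70", "unicortical_50"):
        for cement in (True, False):
            for interface in ("mobile", "bonded", "fused"):
                specs.append(ScenarioSpec(i, screw, cement, interface))
                i += 1
    return specs


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    mesh_size: float = 3.0          # mm target element size
    penalty: float | None = None    # contact/tie penalty, N/mm per pair
    penetration_tol: float = 1e-3   # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.phantom, dict):
            self.phantom = PhantomParams(**self.phantom)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


class PipelineCache:
    """Shares phantom/mesh/material stages across scenarios.

    Mobile and bonded scenarios of one stabilization variant use identical
    geometry, so they share one entry; fused scenarios get their own.
    """

    def __init__(self) -> None:
        self._store: dict = {}

    def prepare(self, screw_variant: str, cement: bool, fused: bool,
                config: RunConfig) -> dict:
        key = (screw_variant, cement, fused)
        if key in self._store:
            return self._store[key]
        params = dataclasses.replace(
            config.phantom, screw_variant=screw_variant, cement=cement,
            healing_state="fused" if fused else "mobile", seed=config.seed)
        bundle = build_phantom(params)
        density, cal = calibrate_phantom(bundle.density_image, bundle.insert_spec)
        mesh = mesh_domains(bundle.label_image, config.mesh_size)
        tag_boundary(mesh, bundle.geometry_meta)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            quality = check_quality(mesh)
        for w in caught:
            log.warning("%s", w.message)
        rho = sample_element_density(mesh, density, bundle.label_image)
        materials = classify_and_assign(rho, mesh.labels)
        if screw_variant == "unicortical_50":
            materials = fill_screw_void(
                materials, mesh.labels == ph.SCREW_VOID, screw_variant)
        pairs = None
        if not fused:
            # depressed: cutoff twice the nominal gap captures the basal
            # apposition surface; separated: 1.3x captures the split face
            # while excluding the evacuation void under the wedge, which is
            # not an apposition surface
            min_gap = 0.5 * max(params.voxel_spacing)
            reach = 1.3 * config.mesh_size   # quantized surfaces sit on lattice planes
            pairs = [
                find_interface_pairs(mesh, "depressed",
                                     cutoff=max(2.0 * params.depressed_gap,
                                                reach),
                                     min_gap=min_gap),
                find_interface_pairs(mesh, "separated",
                                     cutoff=max(1.3 * params.separated_gap,
                                                reach),
                                     min_gap=min_gap),
            ]
        entry = {"params": params, "bundle": bundle, "calibration": cal,
                 "mesh": mesh, "materials": materials, "pairs": pairs,
                 "quality": quality,
                 "assembly": assemble_system(mesh, materials)}
        self._store[key] = entry
        return entry


def run_scenario(spec: ScenarioSpec, config: RunConfig,
                 cache: PipelineCache | None = None,
                 out_dir: str | Path | None = None) -> StabilityReport:
    """Run one scenario end to end; writes artifacts when out_dir is given."""
    t0 = time.time()
    cache = cache or PipelineCache()
    fused = spec.interface == "fused"
    entry = cache.prepare(spec.screw_variant, spec.cement, fused, config)
    mesh, materials, pairs = entry["mesh"], entry["materials"], entry["pairs"]

    system = entry["assembly"].fresh()
    apply_supports_and_ties(system)
    load_case = LoadCase(body_mass=entry["params"].body_mass)
    apply_loads(system, load_case)

    contact = None
    if not fused:
        mode = "frictionless" if spec.interface == "mobile" else "bonded"
        contact = ContactSpec(pairs=pairs, mode=mode, penalty=config.penalty,
                              penetration_tol=config.penetration_tol)
    solution = solve_static(system, contact)

    strains = None
    red_depr = None
    opening = None
    if not fused:
        strains = {p.fragment: interfragmentary_strain(solution, p)
                   for p in pairs}
        red_depr = reduction_loss_depressed(solution, mesh)
        opening = separation_opening(
            solution, next(p for p in pairs if p.fragment == "separated"))

    report = summarize(spec.id, spec.screw_variant, spec.cement,
                       spec.interface, solution, materials, mesh,
                       strains, red_depr, opening)
    log.info("scenario %d (%s, cement=%s, %s): yield %.2f mm3, stable=%s "
             "(%.1f s)", spec.id, spec.screw_variant, spec.cement,
             spec.interface, report.yield_volume_mm3, report.stable,
             time.time() - t0)

    if out_dir is not None:
        _write_artifacts(Path(out_dir), spec, config, entry, solution, report,
                         time.time() - t0)
    return report


def _write_artifacts(out: Path, spec: ScenarioSpec, config: RunConfig,
                     entry: dict, solution, report: StabilityReport,
                     wall_s: float) -> None:
    sdir = out / f"scenario_{spec.id:02d}"
    sdir.mkdir(parents=True, exist_ok=True)
    entry["bundle"].save(sdir / "phantom")
    entry["calibration"].save(sdir / "calibration.json")
    entry["materials"].to_csv(sdir / "materials.csv")
    entry["quality"].summary_json(sdir / "mesh_quality.json")
    from .metrics import von_mises
    write_vtu(sdir / "solution.vtu", entry["mesh"],
              point_data={"displacement": solution.displacements},
              cell_data={"region": entry["mesh"].labels,
                         "young_modulus": entry["materials"].young_modulus,
                         "von_mises": von_mises(solution.stress)})
    report.to_json(sdir / "report.json")
    prov = {"config_hash": config.config_hash(),
            "config": config.to_dict(),
            "scenario": dataclasses.asdict(spec),
            "version": __version__,
            "wall_time_s": wall_s,
            "solver": {"residual": solution.residual,
                       "iterations": solution.iterations,
                       "reaction_sum_N": solution.reactions.sum(axis=0).tolist()}}
    (sdir / "provenance.json").write_text(json.dumps(prov, indent=2,
                                                     sort_keys=True))


def run_matrix(config: RunConfig,
               scenario_ids: list[int] | None = None,
               out_dir: str | Path | None = None) -> list[StabilityReport]:
    """Run all (or selected) scenarios with shared pipeline stages."""
    cache = PipelineCache()
    reports = []
    for spec in build_scenario_matrix(config):
        if scenario_ids is not None and spec.id not in scenario_ids:
            continue
        reports.append(run_scenario(spec, config, cache, out_dir))
    return reports


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def reports_to_frame(reports: list[StabilityReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "scenario": r.scenario_id,
            "screw": r.screw_variant,
            "cement": r.cement,
            "interface": r.interface,
            "max_strain_depressed_pct": r.max_strain_depressed_pct,
            "max_strain_separated_pct": r.max_strain_separated_pct,
            "yield_volume_mm3": r.yield_volume_mm3,
            "max_bone_stress_MPa": max(
                r.max_von_mises.get("cortical", 0.0),
                r.max_von_mises.get("trabecular", 0.0)),
            "reduction_loss_depressed_mm": r.reduction_loss_depressed_mm,
            "separation_opening_mm": r.separation_opening_mm,
            "max_total_displacement_mm": r.max_total_displacement_mm,
            "stable": r.stable,
        })
    return pd.DataFrame(rows).set_index("scenario")


def directional_findings(reports: list[StabilityReport]) -> dict:
    """Evaluate the transferable orderings on the phantom.

    (a) cemented-mobile yield volume is zero while uncemented-mobile is not;
    (b) uncemented-mobile strains exceed cemented-mobile strains;
    (c) bonded strains are below mobile strains;
    (d) uni- vs bi-cortical difference in separated-fragment opening is small.
    """
    by = {(r.screw_variant, r.cement, r.interface): r for r in reports}
    findings: dict[str, bool | None] = {}

    def _max_strain(r):
        vals = [v for v in (r.max_strain_depressed_pct,
                            r.max_strain_separated_pct) if v is not None]
        return max(vals) if vals else None

    try:
        cem_mobile = [by[(s, True, "mobile")] for s in
                      ("bicortical_70", "unicortical_50")]
        unc_mobile = [by[(s, False, "mobile")] for s in
                      ("bicortical_70", "unicortical_50")]
        findings["a_cement_prevents_yield"] = (
            all(r.yield_volume_mm3 == 0.0 for r in cem_mobile)
            and all(r.yield_volume_mm3 > 0.0 for r in unc_mobile))
        findings["b_cement_lowers_strain"] = all(
            _max_strain(by[(s, False, "mobile")])
            > _max_strain(by[(s, True, "mobile")])
            for s in ("bicortical_70", "unicortical_50"))
        findings["c_bonded_below_mobile"] = all(
            _max_strain(by[(s, c, "bonded")]) < _max_strain(by[(s, c, "mobile")])
            for s in ("bicortical_70", "unicortical_50")
            for c in (True, False))
        openings = {}
        for c in (True, False):
            bi = by[("bicortical_70", c, "mobile")].separation_opening_mm
            uni = by[("unicortical_50", c, "mobile")].separation_opening_mm
            openings[c] = abs(uni - bi)
        findings["d_screw_length_opening_negligible"] = all(
            d < 0.02 for d in openings.values())
        findings["d_opening_difference_mm"] = max(openings.values())
    except KeyError:
        # partial matrices cannot be checked
        return {}
    return findings


def write_report(reports: list[StabilityReport],
                 out_dir: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Comparison table plus directional-findings check."""
    if not reports:
        raise ValueError("need at least one report")
    frame = reports_to_frame(reports)
    findings = directional_findings(reports) if len(reports) == 12 else {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "comparison.csv")
        payload = {"table": json.loads(frame.to_json(orient="index")),
                   "directional_findings": findings}
        (out / "comparison.json").write_text(json.dumps(payload, indent=2,
                                                        sort_keys=True))
    for key, val in findings.items():
        if isinstance(val, bool):
            log.info("directional finding %s: %s", key,
                     "OK" if val else "FAILED")
    return frame, findings
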