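"""Shared fixtures: session-scoped phantom/mesh stages and small FE helpers."""

from __future__ import annotations

import numpy as np
import pytest

import tibfrac as tf
from tibfrac.materials import MaterialField
from tibfrac.mesh import boundary_faces, facet_nodes, mesh_domains
from tibfrac.phantom import VoxelImage


@pytest.fixture(scope="session")
def default_params() -> tf.PhantomParams:
    return tf.PhantomParams()


@pytest.fixture(scope="session")
def phantom_bundle(default_params) -> tf.PhantomBundle:
    return tf.build_phantom(default_params)


@pytest.fixture(scope="session")
def phantom_mesh(phantom_bundle) -> tf.LabeledMesh:
    mesh = tf.mesh_domains(phantom_bundle.label_image, 3.0)
    tf.tag_boundary(mesh, phantom_bundle.geometry_meta)
    return mesh


@pytest.fixture(scope="session")
def matrix_results():
    """Full 12-scenario run on the default phantom, with wall times."""
    import time

    cfg = tf.RunConfig()
    cache = tf.PipelineCache()
    reports, times = [], []
    for spec in tf.build_scenario_matrix(cfg):
        t0 = time.time()
        reports.append(tf.run_scenario(spec, cfg, cache))
        times.append(time.time() - t0)
    return {"reports": reports, "times": times, "config": cfg}


# ---------------------------------------------------------------------------
# Small-problem helpers
# ---------------------------------------------------------------------------

def box_mesh(nx: int, ny: int, nz: int, h: float = 2.0,
             label: int = 2, spacing: float = 1.0) -> tf.LabeledMesh:
    """Uniform box of one region meshed at element size h (mm)."""
    img = VoxelImage(np.full((nx, ny, nz), label, dtype=np.int16),
                     (spacing,) * 3, units="label")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mesh_domains(img, h)


def uniform_materials(mesh, E: float = 1000.0, nu: float = 0.3,
                      ys: float = 100.0) -> MaterialField:
    n = mesh.n_elements
    return MaterialField(np.full(n, 1.0), np.full(n, E), np.full(n, nu),
                         np.full(n, ys), np.full(n, "trabecular", dtype="U10"))


def tag_plane(mesh, tag: str, axis: int, value: float, normal_sign: float):
    """Tag the boundary facets lying in a coordinate plane."""
    from tibfrac.mesh import facet_normals

    bf_el, bf_loc = boundary_faces(mesh)
    fns = facet_nodes(mesh, bf_el, bf_loc)
    cents = mesh.nodes[fns[:, :3]].mean(axis=1)
    nrm = facet_normals(mesh, fns)
    sel = (np.abs(cents[:, axis] - value) < 1e-9) \
        & (nrm[:, axis] * normal_sign > 0.9)
    mesh.boundary_facets[tag] = fns[sel]
    mesh.facet_elements[tag] = bf_el[sel]
    return fns[sel]
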