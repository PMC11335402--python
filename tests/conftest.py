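from __future__ import annotations

import numpy as np
import pytest

import jawscape as jw


def circle_loop(r: float = 1.0, n: int = 360, center=(0.0, 0.0)) -> jw.OutlineLoop:
    t = np.linspace(0.0, 2 * np.pi, n + 1)[:-1]
    return jw.OutlineLoop(
        np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)]),
        source_id="circle",
    )


def ellipse_loop(a: float, b: float, n: int = 720) -> jw.OutlineLoop:
    t = np.linspace(0.0, 2 * np.pi, n + 1)[:-1]
    return jw.OutlineLoop(
        np.column_stack([a * np.cos(t), b * np.sin(t)]), source_id="ellipse"
    )


def rect_loop(L: float, d: float) -> jw.OutlineLoop:
    return jw.OutlineLoop(
        np.array([[0.0, 0.0], [L, 0.0], [L, d], [0.0, d]]), source_id="rect"
    )


def uniform_tension_load(mesh: jw.TriMesh, sigma0: float) -> jw.LoadCase:
    """Left edge fixed in x (bottom-left corner also in y); consistent
    nodal loads applying sigma0 on the right edge."""
    xmin, xmax = mesh.nodes[:, 0].min(), mesh.nodes[:, 0].max()
    left = np.flatnonzero(np.isclose(mesh.nodes[:, 0], xmin))
    right = set(int(n) for n in np.flatnonzero(np.isclose(mesh.nodes[:, 0], xmax)))
    con = {int(n): (True, False) for n in left}
    corner = int(left[np.argmin(mesh.nodes[left, 1])])
    con[corner] = (True, True)
    ring = mesh.boundary_nodes
    forces: dict[int, tuple[float, float]] = {}
    for i in range(len(ring)):
        a, b = int(ring[i]), int(ring[(i + 1) % len(ring)])
        if a in right and b in right:
            half = sigma0 * mesh.thickness * float(np.linalg.norm(mesh.nodes[a] - mesh.nodes[b])) / 2
            for n in (a, b):
                fx, fy = forces.get(n, (0.0, 0.0))
                forces[n] = (fx + half, fy)
    return jw.LoadCase(constrained=con, nodal_forces=forces)


@pytest.fixture(scope="session")
def jaw_loop() -> jw.OutlineLoop:
    return jw.generate_jaw(jw.JawParams(), K=600)


@pytest.fixture(scope="session")
def jaw_mesh(jaw_loop) -> jw.TriMesh:
    return jw.triangulate(jaw_loop, n_target=2500)


@pytest.fixture(scope="session")
def small_pipeline_cfg(tmp_path_factory) -> jw.PipelineConfig:
    """Scaled-down end-to-end configuration: 30 synthetic shapes, 10 x 8
    grid, ~1200-element meshes, 50 bootstrap iterations."""
    out = tmp_path_factory.mktemp("pipeline") / "run_a"
    return jw.PipelineConfig(
        synth_n=30,
        landmarks=400,
        harmonics=30,
        grid_nx=10,
        grid_ny=8,
        mesh_target=1200,
        n_iter=50,
        seed=11,
        output_dir=str(out),
    )


@pytest.fixture(scope="session")
def small_pipeline_run(small_pipeline_cfg):
    return jw.run_pipeline(small_pipeline_cfg)
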