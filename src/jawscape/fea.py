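"""Plane-stress linear elasticity with constant-strain triangles (CST).

Each theoretical jaw is a thin uniformly thick plate.  The standard 3-node
triangle stiffness (strain-displacement B matrix per element, plane-stress
constitutive matrix from Young's modulus E and Poisson's ratio nu) is
assembled into a sparse symmetric system K u = f, solved with constraint
elimination so the patch test is exact.  Von Mises stress per element,

    vms = sqrt(sxx^2 - sxx*syy + syy^2 + 3*txy^2),

is the strength proxy; the per-shape statistic is the MEDIAN element value,
which is robust to the stress singularities at constrained nodes.

The muscle-loading bootstrap re-draws the force node position (uniform
within a fraction of the outline perimeter on either side of the insertion)
and the force direction (uniform within an angular band about the inward
surface normal), re-solving for each draw.  The stiffness factorization
depends only on the constraints, so it is computed once per shape and
reused across iterations.  Iteration i's random draws are a pure function
of (seed, i), making surfaces reproducible under any evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .meshing import FunctionalNodes, TriMesh


@dataclass
class Material:
    """Isotropic linear-elastic plate material (defaults follow standard
    2D bone-proxy values: E = 2 GPa, nu = 0.3)."""

    young_modulus: float = 2.0e9
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("E must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("nu must be in [0, 0.5)")

    @property
    def D(self) -> np.ndarray:
        E, nu = self.young_modulus, self.poisson_ratio
        return (E / (1 - nu**2)) * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1 - nu) / 2]]
        )


@dataclass
class LoadCase:
    """Constraints and a point force.

    constrained maps node index -> (fix_x, fix_y).  nodal_forces, if given,
    maps node index -> (fx, fy) and is added on top of the point force
    (used e.g. for distributed edge tractions in verification problems).
    """

    constrained: dict[int, tuple[bool, bool]]
    force_node: int | None = None
    force_vector: tuple[float, float] = (0.0, 0.0)
    nodal_forces: dict[int, tuple[float, float]] = field(default_factory=dict)


@dataclass
class StressField:
    stress: np.ndarray        # (n_elements, 3): sxx, syy, txy
    von_mises: np.ndarray     # (n_elements,)
    displacements: np.ndarray  # (n_nodes, 2)


@dataclass
class BootstrapConfig:
    """Pseudo-randomization settings for loading-uncertainty bootstraps."""

    n_iter: int = 1000
    node_jitter_frac: float = 0.05
    angle_jitter_deg: float = 45.0
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.node_jitter_frac < 0 or self.angle_jitter_deg < 0:
            raise ValueError("jitters must be non-negative")


@dataclass
class BootstrapResult:
    mean: float
    ci_low: float
    ci_high: float
    values: np.ndarray
    n_failed: int = 0


def von_mises(stress: np.ndarray) -> np.ndarray:
    sxx, syy, txy = stress[..., 0], stress[..., 1], stress[..., 2]
    return np.sqrt(np.maximum(sxx**2 - sxx * syy + syy**2 + 3 * txy**2, 0.0))


class CSTSystem:
    """Assembled CST plane-stress system with a reusable factorization.

    Constraints are eliminated (rows/columns removed), so for a fixed
    constraint set many load vectors can be solved by back-substitution.
    """

    def __init__(self, mesh: TriMesh, material: Material, constrained: dict[int, tuple[bool, bool]]):
        n_con = sum(fx + fy for fx, fy in constrained.values())
        if n_con < 3:
            raise ValueError("need at least 3 constrained DOFs to remove rigid-body motion")
        self.mesh = mesh
        self.material = material
        self.constrained = dict(constrained)
        nodes, elems = mesh.nodes, mesh.elements
        p = nodes[elems]  # (E, 3, 2)
        x, y = p[..., 0], p[..., 1]
        b = np.stack(
            [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
        )
        c = np.stack(
            [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
        )
        area = mesh.element_area
        B = np.zeros((len(elems), 3, 6))
        B[:, 0, 0::2] = b
        B[:, 1, 1::2] = c
        B[:, 2, 0::2] = c
        B[:, 2, 1::2] = b
        B /= (2 * area)[:, None, None]
        self.B = B
        D = material.D
        ke = mesh.thickness * area[:, None, None] * np.einsum(
            "eji,jk,ekl->eil", B, D, B
        )
        dof = np.empty((len(elems), 6), dtype=int)
        dof[:, 0::2] = 2 * elems
        dof[:, 1::2] = 2 * elems + 1
        rows = np.repeat(dof, 6, axis=1).ravel()
        cols = np.tile(dof, (1, 6)).ravel()
        ndof = 2 * mesh.n_nodes
        K = coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsc()
        fixed = np.zeros(ndof, dtype=bool)
        for node, (fx, fy) in constrained.items():
            if fx:
                fixed[2 * node] = True
            if fy:
                fixed[2 * node + 1] = True
        self.free = np.flatnonzero(~fixed)
        Kff = csc_matrix(K[np.ix_(self.free, self.free)])
        self.lu = splu(Kff)
        self._ndof = ndof
        self._edof = dof

    def solve(self, load: LoadCase) -> StressField:
        f = np.zeros(self._ndof)
        if load.force_node is not None:
            f[2 * load.force_node : 2 * load.force_node + 2] += load.force_vector
        for node, (fx, fy) in load.nodal_forces.items():
            f[2 * node] += fx
            f[2 * node + 1] += fy
        u = np.zeros(self._ndof)
        u[self.free] = self.lu.solve(f[self.free])
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("singular or ill-conditioned system")
        ue = u[self._edof]  # (E, 6)
        strain = np.einsum("eij,ej->ei", self.B, ue)
        stress = strain @ self.material.D.T
        return StressField(
            stress=stress,
            von_mises=von_mises(stress),
            displacements=u.reshape(-1, 2),
        )


def default_jaw_constraints(nodes: FunctionalNodes) -> dict[int, tuple[bool, bool]]:
    """Standard 2D lever boundary conditions: joint pinned (x and y), bite
    point supported vertically (y only)."""
    return {nodes.joint: (True, True), nodes.bite: (False, True)}


def solve_cst(mesh: TriMesh, material: Material, load: LoadCase) -> StressField:
    """Single plane-stress CST solve (assembles and factorizes once)."""
    return CSTSystem(mesh, material, load.constrained).solve(load)


def vms_statistic(field: StressField) -> float:
    """Median per-element Von Mises stress (robust to constraint
    singularities)."""
    return float(np.median(field.von_mises))


def _boundary_arcs(mesh: TriMesh) -> tuple[np.ndarray, float]:
    ring = mesh.nodes[mesh.boundary_nodes]
    seg = np.roll(ring, -1, axis=0) - ring
    lens = np.hypot(seg[:, 0], seg[:, 1])
    arcs = np.concatenate([[0.0], np.cumsum(lens)])[:-1]
    return arcs, float(lens.sum())


def jitter_boundary_index(
    mesh: TriMesh, base_boundary_idx: int, offset_frac: float
) -> int:
    """Boundary-chain index at arc position offset_frac*perimeter away
    from the base node (nearest node wins)."""
    arcs, perim = _boundary_arcs(mesh)
    target = (arcs[base_boundary_idx] + offset_frac * perim) % perim
    dist = np.abs(arcs - target)
    dist = np.minimum(dist, perim - dist)
    return int(np.argmin(dist))


def bootstrap_vms(
    mesh: TriMesh,
    material: Material,
    nodes: FunctionalNodes,
    cfg: BootstrapConfig,
) -> BootstrapResult:
    """Bootstrap the median-VMS statistic over muscle load uncertainty.

    Per iteration the muscle node slides uniformly within
    +/- node_jitter_frac of the perimeter and the (unit) force direction
    rotates uniformly within +/- angle_jitter_deg about the inward normal
    at the drawn node.  Returns the mean and the central percentile
    interval across iterations.
    """
    system = CSTSystem(mesh, material, default_jaw_constraints(nodes))
    b_idx = {int(n): i for i, n in enumerate(mesh.boundary_nodes)}
    muscle_b = b_idx[nodes.muscle]
    normals = nodes.normals
    values = []
    n_failed = 0
    for i in range(cfg.n_iter):
        rng = np.random.default_rng([cfg.seed, i])
        off = rng.uniform(-cfg.node_jitter_frac, cfg.node_jitter_frac)
        ang = np.deg2rad(rng.uniform(-cfg.angle_jitter_deg, cfg.angle_jitter_deg))
        bi = jitter_boundary_index(mesh, muscle_b, off)
        inward = -normals[bi]
        ca, sa = np.cos(ang), np.sin(ang)
        fvec = (ca * inward[0] - sa * inward[1], sa * inward[0] + ca * inward[1])
        load = LoadCase(
            constrained=system.constrained,
            force_node=int(mesh.boundary_nodes[bi]),
            force_vector=fvec,
        )
        try:
            values.append(vms_statistic(system.solve(load)))
        except (FloatingPointError, RuntimeError):
            n_failed += 1
    if n_failed > 0.05 * cfg.n_iter:
        raise RuntimeError(f"{n_failed}/{cfg.n_iter} bootstrap solves failed")
    values = np.asarray(values)
    alpha = (1.0 - cfg.ci_level) / 2
    return BootstrapResult(
        mean=float(values.mean()),
        ci_low=float(np.quantile(values, alpha)),
        ci_high=float(np.quantile(values, 1 - alpha)),
        values=values,
        n_failed=n_failed,
    )
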