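"""Non-FEA performance metrics: rotational efficiency and relative area.

Rotational efficiency is a jaw-closure-speed proxy: the linear speed v of
the bite point when the jaw carries E_rot = 1 J of rotational kinetic
energy about the joint.  With I = sum_i m_i r_i^2 (element mass times
squared centroid distance from the joint) and L the joint-to-bite distance,

    omega = sqrt(2 E_rot / I),   v = L * omega = L * sqrt(2 / I).

Relative lateral area is a form-drag proxy for lateral head sweeps: the
outline's polygon area once scaled so the first-harmonic semi-major axis
(the jaw-length proxy) equals 1.  Both metrics are unitless model values
meaningful only in relative comparisons across equally scaled shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .efa import HarmonicSet
from .fea import BootstrapConfig, BootstrapResult, jitter_boundary_index
from .meshing import FunctionalNodes, TriMesh
from .outline import OutlineLoop


@dataclass
class RotationalResult:
    I: float       # moment of inertia about the joint
    L: float       # joint-to-bite distance
    v: float       # bite-point speed at E_rot = 1
    E_rot: float = 1.0


@dataclass
class AreaResult:
    rel_area: float


def moment_of_inertia(mesh: TriMesh, axis_point) -> float:
    """Centroid-lumped moment of inertia: sum over elements of mass times
    squared distance from axis_point to the element centroid."""
    if mesh.n_elements == 0:
        raise ValueError("empty mesh")
    r2 = np.sum((mesh.element_centroid - np.asarray(axis_point)) ** 2, axis=1)
    return float(np.sum(mesh.element_mass * r2))


def rotational_efficiency(
    mesh: TriMesh, nodes: FunctionalNodes, e_rot: float = 1.0
) -> RotationalResult:
    """Bite-point speed at e_rot rotational energy about the joint node."""
    joint = mesh.nodes[nodes.joint]
    bite = mesh.nodes[nodes.bite]
    I = moment_of_inertia(mesh, joint)
    if I <= 0:
        raise ValueError("zero moment of inertia")
    L = float(np.linalg.norm(bite - joint))
    v = L * np.sqrt(2.0 * e_rot / I)
    return RotationalResult(I=I, L=L, v=float(v), E_rot=e_rot)


def bootstrap_re(
    mesh: TriMesh, nodes: FunctionalNodes, cfg: BootstrapConfig
) -> BootstrapResult:
    """Bootstrap v over independent arc-position jitters of the joint and
    bite nodes (each uniform within +/- node_jitter_frac of the perimeter).
    Iteration i's draws are a pure function of (cfg.seed, i)."""
    b_idx = {int(n): i for i, n in enumerate(mesh.boundary_nodes)}
    joint_b, bite_b = b_idx[nodes.joint], b_idx[nodes.bite]
    values = np.empty(cfg.n_iter)
    for i in range(cfg.n_iter):
        # offset by 1 in the spawn key so draws differ from the VMS bootstrap
        rng = np.random.default_rng([cfg.seed, i, 1])
        dj = rng.uniform(-cfg.node_jitter_frac, cfg.node_jitter_frac)
        db = rng.uniform(-cfg.node_jitter_frac, cfg.node_jitter_frac)
        ji = jitter_boundary_index(mesh, joint_b, dj)
        bi = jitter_boundary_index(mesh, bite_b, db)
        joint = mesh.nodes[mesh.boundary_nodes[ji]]
        bite = mesh.nodes[mesh.boundary_nodes[bi]]
        I = moment_of_inertia(mesh, joint)
        L = float(np.linalg.norm(bite - joint))
        values[i] = L * np.sqrt(2.0 / I)
    alpha = (1.0 - cfg.ci_level) / 2
    return BootstrapResult(
        mean=float(values.mean()),
        ci_low=float(np.quantile(values, alpha)),
        ci_high=float(np.quantile(values, 1 - alpha)),
        values=values,
    )


def relative_area(loop: OutlineLoop, h: HarmonicSet | None = None) -> AreaResult:
    """Shoelace polygon area at unit first-harmonic length.

    The loop is expected to be a reconstruction from NORMALIZED harmonics
    (first-harmonic semi-major axis already 1); if an unnormalized harmonic
    set is supplied the loop is rescaled by its recorded scale factor.
    Higher values mean more lateral area exposed during head sweeps, hence
    higher form drag.
    """
    from .morphospace import is_self_intersecting

    if is_self_intersecting(loop):
        raise ValueError("relative area undefined for self-intersecting outline")
    area = loop.area
    if h is not None and not h.normalized:
        raise ValueError("harmonic set must be normalized")
    return AreaResult(rel_area=float(area))
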