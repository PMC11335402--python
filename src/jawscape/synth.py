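"""Parametric generator of jaw-like closed outlines.

This module emulates the dominant shape factors of archosaur lower jaws in
lateral view — relative robustness (depth) of the anterior tooth-bearing
region versus the posterior region, dorsoventral bowing of the jaw, and the
vertical position of the jaw joint relative to the tooth row — so that the
whole pipeline (outline tracing, EFA, PCA, grid, functional surfaces) can
run and be validated without any empirical specimens.  It is an emulator of
those axes of variation, not of any real taxon's anatomy.

Construction: the jaw occupies x in [0, 1] with the joint (posterior) end
at x = 0 and the anterior tip at x = 1.  A half-depth profile blends the
posterior and anterior depth parameters with a smoothstep and pinches to
zero at both ends (a fast superellipse roll-off posteriorly, a tunable one
anteriorly for tip rounding).  A midline adds dorsoventral curvature (a
single sine bow; positive = ventrally convex) and a joint drop that decays
anteriorly.  Dorsal and ventral margins are midline +/- half-depth; the
loop is closed, oriented counterclockwise and resampled to K landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .outline import OutlineLoop, resample_loop


@dataclass
class JawParams:
    """Generator parameters (lengths relative to jaw length = 1)."""

    length: float = 1.0
    depth_anterior: float = 0.15
    depth_posterior: float = 0.25
    curvature: float = 0.0   # positive = ventrally convex bowing
    joint_drop: float = 0.0  # positive = joint below the tooth row
    tip_round: float = 3.0   # superellipse exponent of the anterior tip
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_anterior <= 0 or self.depth_posterior <= 0:
            raise ValueError("depths must be positive")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.tip_round <= 0:
            raise ValueError("tip_round must be positive")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return x * x * (3.0 - 2.0 * x)


def generate_jaw(params: JawParams, K: int = 600) -> OutlineLoop:
    """Deterministic smooth closed jaw outline at K landmarks.

    Raises ValueError if the parameter combination produces a
    self-intersecting outline.
    """
    from .morphospace import is_self_intersecting

    n = max(4 * K, 800)
    # cosine spacing concentrates samples at the pinched ends
    x = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))
    s = _smoothstep(x)
    half_depth = 0.5 * (params.depth_posterior + (params.depth_anterior - params.depth_posterior) * s)
    # pinch to zero at both ends: blunt posteriorly (q=6), tunable tip
    q_post = 6.0
    roll_post = (1.0 - (1.0 - x) ** q_post) ** (1.0 / q_post)
    m = params.tip_round
    roll_ant = (1.0 - x**m) ** (1.0 / m)
    h = half_depth * roll_post * roll_ant
    mid = -params.curvature * np.sin(np.pi * x) + params.joint_drop * (s - 1.0)
    dorsal = np.column_stack([x, mid + h])
    ventral = np.column_stack([x, mid - h])
    # margins pinch together at both ends (h = 0), so the shared end points
    # appear once: ventral left-to-right then dorsal right-to-left is CCW
    pts = np.vstack([ventral[:-1], dorsal[::-1][:-1]])
    pts *= params.length
    loop = OutlineLoop(pts, source_id=f"jaw(da={params.depth_anterior:.3f},dp={params.depth_posterior:.3f},c={params.curvature:+.3f},j={params.joint_drop:+.3f})")
    loop = resample_loop(loop.ensure_ccw().roll_to_max_x(), K)
    if is_self_intersecting(loop):
        raise ValueError(f"self-intersecting outline for parameters {params}")
    return loop


@dataclass
class PopulationParams:
    """Independent sampling distributions for generate_population.

    Depths are log-uniform over [0.05, 0.45] of jaw length; curvature and
    joint drop are uniform over bands narrow enough that in-range
    combinations stay simple (non-self-intersecting).
    """

    depth_log_range: tuple[float, float] = (0.05, 0.45)
    curvature_range: tuple[float, float] = (-0.10, 0.10)
    joint_drop_range: tuple[float, float] = (-0.08, 0.08)
    tip_round_range: tuple[float, float] = (2.0, 4.0)


def generate_population(
    n: int,
    param_distributions: PopulationParams | None = None,
    seed: int = 0,
    K: int = 600,
) -> list[tuple[OutlineLoop, JawParams]]:
    """Draw n jaws from independent parameter distributions.

    Reproducible from the seed; every emitted outline is checked simple.
    Draws that would self-intersect are redrawn (deterministically, from
    the same stream).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    dist = param_distributions or PopulationParams()
    rng = np.random.default_rng(seed)
    out: list[tuple[OutlineLoop, JawParams]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise RuntimeError("rejection sampling failed to produce enough simple outlines")
        lo, hi = dist.depth_log_range
        da = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        dp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        params = JawParams(
            depth_anterior=da,
            depth_posterior=dp,
            curvature=float(rng.uniform(*dist.curvature_range)),
            joint_drop=float(rng.uniform(*dist.joint_drop_range)),
            tip_round=float(rng.uniform(*dist.tip_round_range)),
            seed=seed,
        )
        try:
            loop = generate_jaw(params, K=K)
        except ValueError:
            continue
        loop = replace(loop, source_id=f"synth_{len(out):04d}")
        out.append((loop, params))
    return out


def population_table(pop: list[tuple[OutlineLoop, JawParams]]):
    """Ground-truth parameter table for a generated population."""
    import pandas as pd

    rows = []
    for loop, p in pop:
        rows.append(
            {
                "shape_id": loop.source_id,
                "depth_anterior": p.depth_anterior,
                "depth_posterior": p.depth_posterior,
                "curvature": p.curvature,
                "joint_drop": p.joint_drop,
                "tip_round": p.tip_round,
            }
        )
    return pd.DataFrame(rows)


def rasterize(loop: OutlineLoop, long_axis_px: int = 1000, pad: int = 8) -> np.ndarray:
    """Binary mask of a loop's interior at a given long-axis resolution,
    with the y axis in image convention (row 0 at top).  Used to exercise
    mask tracing end-to-end against known generator polygons."""
    from skimage.draw import polygon as sk_polygon

    pts = loop.points
    span = pts.max(axis=0) - pts.min(axis=0)
    scale = (long_axis_px - 1) / span.max()
    xy = (pts - pts.min(axis=0)) * scale + pad
    w = int(np.ceil(span[0] * scale)) + 2 * pad + 1
    h = int(np.ceil(span[1] * scale)) + 2 * pad + 1
    mask = np.zeros((h, w), dtype=bool)
    rows = (h - 1) - xy[:, 1]
    rr, cc = sk_polygon(rows, xy[:, 0], shape=mask.shape)
    mask[rr, cc] = True
    return mask
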