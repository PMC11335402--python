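"""Morphospace construction: PCA over normalized harmonic vectors,
reconstruction of theoretical shapes on a regular PC1-PC2 grid, and
detection of impossible (self-intersecting) reconstructions.

The theoretical grid spans the empirical score range on the first two
principal axes, padded on both ends of both axes by a fraction of the PC1
range, and reconstructs one outline per cell by adding scaled PC loadings
to the mean coefficient vector.  Cells whose reconstructed outline
self-intersects are flagged invalid: they belong to "impossible
morphospace" and carry no functional values downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString
from sklearn.decomposition import PCA

from .efa import HarmonicSet, efa_inverse
from .outline import OutlineLoop


@dataclass
class Morphospace:
    """PCA basis over normalized EFA coefficient vectors."""

    mean_vector: np.ndarray
    axes: np.ndarray          # (n_axes, n_features), rows orthonormal
    variances: np.ndarray     # eigenvalues, decreasing
    var_explained: np.ndarray  # percentages, sum to 100
    scores: np.ndarray        # (n_shapes, n_axes)
    shape_ids: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]

    def project(self, vec: np.ndarray) -> np.ndarray:
        return (np.asarray(vec) - self.mean_vector) @ self.axes.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        return self.mean_vector + scores @ self.axes[: scores.shape[-1]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean_vector": self.mean_vector.tolist(),
            "axes": self.axes.tolist(),
            "variances": self.variances.tolist(),
            "var_explained": self.var_explained.tolist(),
            "scores": self.scores.tolist(),
            "shape_ids": list(self.shape_ids),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Morphospace":
        d = json.loads(Path(path).read_text())
        return cls(
            mean_vector=np.array(d["mean_vector"]),
            axes=np.array(d["axes"]),
            variances=np.array(d["variances"]),
            var_explained=np.array(d["var_explained"]),
            scores=np.array(d["scores"]),
            shape_ids=d["shape_ids"],
        )


def fit_pca(vectors: np.ndarray, shape_ids: list[str] | None = None) -> Morphospace:
    """Covariance-based PCA of normalized coefficient vectors.

    Axes carry a deterministic sign convention: each axis's
    largest-magnitude loading is positive.  All ``min(n-1, p)`` components
    are retained so that full-score reconstruction is exact.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 vectors of equal length")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    axes = pca.components_
    # deterministic sign: largest-|loading| entry of each axis positive
    flip = np.sign(axes[np.arange(len(axes)), np.argmax(np.abs(axes), axis=1)])
    flip[flip == 0] = 1.0
    axes = axes * flip[:, None]
    scores = scores * flip[None, :]
    variances = pca.explained_variance_
    total = variances.sum()
    var_explained = 100.0 * variances / total if total > 0 else np.zeros_like(variances)
    return Morphospace(
        mean_vector=pca.mean_,
        axes=axes,
        variances=variances,
        var_explained=var_explained,
        scores=scores,
        shape_ids=list(shape_ids) if shape_ids is not None else [],
    )


def scores_to_harmonics(ms: Morphospace, coords) -> HarmonicSet:
    """Coefficient vector at (pc1, pc2) with all other PCs at zero."""
    pc1, pc2 = coords
    vec = ms.mean_vector + pc1 * ms.axes[0] + pc2 * ms.axes[1]
    return HarmonicSet.from_vector(vec, normalized=True, source_id=f"pc({pc1:g},{pc2:g})")


def is_self_intersecting(loop: OutlineLoop) -> bool:
    """True iff two non-adjacent edges of the closed polygon properly
    intersect or overlap (shared endpoints of adjacent edges do not count)."""
    return not LineString(loop.closed_points).is_simple


@dataclass
class TheoreticalGrid:
    """Regular grid of theoretical shapes in the PC1-PC2 plane."""

    pc1_values: np.ndarray
    pc2_values: np.ndarray
    shapes: list[OutlineLoop]   # row-major: index = iy * nx + ix
    valid: np.ndarray           # bool per cell
    coords: np.ndarray          # (n_cells, 2) pc1, pc2 per cell

    @property
    def nx(self) -> int:
        return len(self.pc1_values)

    @property
    def ny(self) -> int:
        return len(self.pc2_values)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def manifest(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell": np.arange(self.n_cells),
                "pc1": self.coords[:, 0],
                "pc2": self.coords[:, 1],
                "valid": self.valid,
            }
        )


def sample_grid(
    ms: Morphospace,
    nx: int = 25,
    ny: int = 20,
    extension_frac: float = 0.20,
    K: int = 600,
) -> TheoreticalGrid:
    """Reconstruct a theoretical grid spanning the empirical scores.

    Grid bounds are the empirical min/max on PC1 and PC2, each axis padded
    on both ends by ``extension_frac`` times the PC1 range (the PC1 range
    sets the pad length on both axes).  Each cell is reconstructed at K
    landmarks and validity-flagged by the self-intersection test.
    """
    if ms.scores.size == 0:
        raise ValueError("empty morphospace: no scores to span")
    s1, s2 = ms.scores[:, 0], ms.scores[:, 1]
    pad = extension_frac * (s1.max() - s1.min())
    pc1_values = np.linspace(s1.min() - pad, s1.max() + pad, nx)
    pc2_values = np.linspace(s2.min() - pad, s2.max() + pad, ny)
    shapes, valid, coords = [], [], []
    for iy, p2 in enumerate(pc2_values):
        for ix, p1 in enumerate(pc1_values):
            h = scores_to_harmonics(ms, (p1, p2))
            loop = efa_inverse(h, K)
            loop.source_id = f"cell_{iy * nx + ix}"
            shapes.append(loop)
            valid.append(not is_self_intersecting(loop))
            coords.append((p1, p2))
    return TheoreticalGrid(
        pc1_values=pc1_values,
        pc2_values=pc2_values,
        shapes=shapes,
        valid=np.array(valid),
        coords=np.array(coords),
    )
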