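"""Elliptical Fourier analysis (EFA) of closed outlines.

A closed planar curve sampled at landmarks is decomposed into harmonic
quadruples (a_n, b_n, c_n, d_n) — the cosine/sine coefficients of x(t) and
y(t) over the arc-length parameter — using the classic piecewise-linear
(chain-code generalised) formulation of Kuhl & Giardina.  The first harmonic
is the best-fit ellipse; normalization removes position, size and
orientation by rotating the first-harmonic major axis onto the x-axis,
shifting the parameter origin to the canonical phase, and dividing by the
semi-major axis length.  Normalized coefficient vectors are the coordinates
on which the morphospace PCA operates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .outline import OutlineLoop


@dataclass
class HarmonicSet:
    """EFA coefficients for one shape.

    Attributes
    ----------
    coeffs : (H, 4) array
        Rows are harmonics 1..H; columns are (a_n, b_n, c_n, d_n).
    dc : (2,) array
        Centroid offsets (A0, C0) of the arc-length parameterisation.
    normalized : bool
        Whether size/orientation/phase normalization has been applied.
    scale_factor : float
        The size divisor applied during normalization (1.0 if raw).
    """

    coeffs: np.ndarray
    dc: np.ndarray
    normalized: bool = False
    scale_factor: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        self.dc = np.asarray(self.dc, dtype=float)
        if self.coeffs.shape[1] != 4 or self.coeffs.shape[0] < 1:
            raise ValueError("coeffs must be (H, 4) with H >= 1")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite EFA coefficients")

    @property
    def H(self) -> int:
        return self.coeffs.shape[0]

    def to_vector(self) -> np.ndarray:
        """Flatten to the PCA layout (a_1..a_H, b_1..b_H, c_1..c_H, d_1..d_H)."""
        return self.coeffs.T.ravel().copy()

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, normalized: bool = True, source_id: str = ""
    ) -> "HarmonicSet":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 4:
            raise ValueError("coefficient vector length must be a multiple of 4")
        H = vec.size // 4
        return cls(
            coeffs=vec.reshape(4, H).T,
            dc=np.zeros(2),
            normalized=normalized,
            scale_factor=1.0,
            source_id=source_id,
        )


def efa_forward(loop: OutlineLoop, H: int) -> HarmonicSet:
    """Compute the raw (unnormalized) EFA coefficients of a closed loop.

    Uses the exact Fourier integrals of the piecewise-linear closed curve
    parameterised by cumulative arc length.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    pts = loop.closed_points
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    T = dt.sum()
    if T <= 0:
        raise ValueError("zero-perimeter loop")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    n = np.arange(1, H + 1)[:, None]  # (H, 1)
    phi1 = 2 * np.pi * n * t[:-1] / T  # (H, K)
    phi2 = 2 * np.pi * n * t[1:] / T
    const = T / (2 * np.pi**2 * n.astype(float) ** 2)  # (H, 1)
    dcos = np.cos(phi2) - np.cos(phi1)
    dsin = np.sin(phi2) - np.sin(phi1)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = (const * (dxdt * dcos)).sum(axis=1)
    b = (const * (dxdt * dsin)).sum(axis=1)
    c = (const * (dydt * dcos)).sum(axis=1)
    dd = (const * (dydt * dsin)).sum(axis=1)
    # dc terms: arc-length average of the piecewise-linear curve
    mid = 0.5 * (pts[:-1] + pts[1:])
    dc = (mid * dt[:, None]).sum(axis=0) / T
    return HarmonicSet(
        coeffs=np.column_stack([a, b, c, dd]),
        dc=dc,
        normalized=False,
        scale_factor=1.0,
        source_id=loop.source_id,
    )


def _apply_phase_rotation(coeffs: np.ndarray, theta: float, psi: float) -> np.ndarray:
    """Rotate parameter start by theta and spatial frame by psi."""
    H = coeffs.shape[0]
    out = np.empty_like(coeffs)
    cpsi, spsi = np.cos(psi), np.sin(psi)
    R_psi = np.array([[cpsi, spsi], [-spsi, cpsi]])
    for i in range(H):
        nth = (i + 1) * theta
        R_th = np.array([[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]])
        M = np.array([[coeffs[i, 0], coeffs[i, 1]], [coeffs[i, 2], coeffs[i, 3]]])
        M2 = R_psi @ M @ R_th
        out[i] = [M2[0, 0], M2[0, 1], M2[1, 0], M2[1, 1]]
    return out


def efa_normalize(h: HarmonicSet) -> HarmonicSet:
    """Standard size/orientation/phase normalization.

    After normalization the first-harmonic ellipse has semi-major axis 1
    lying along the x-axis, dc = (0, 0), and d_1 > 0 (reflection resolved by
    flipping y if needed).  Idempotent on already-normalized sets.
    """
    if h.normalized:
        return replace(h, coeffs=h.coeffs.copy(), dc=h.dc.copy())
    a1, b1, c1, d1 = h.coeffs[0]
    denom = a1**2 + c1**2 - b1**2 - d1**2
    if a1**2 + b1**2 + c1**2 + d1**2 < 1e-300:
        raise ValueError("degenerate first harmonic")
    theta = 0.5 * np.arctan2(2 * (a1 * b1 + c1 * d1), denom)
    # pick the phase putting the MAJOR axis first
    ct, st = np.cos(theta), np.sin(theta)
    major = np.hypot(a1 * ct + b1 * st, c1 * ct + d1 * st)
    minor = np.hypot(-a1 * st + b1 * ct, -c1 * st + d1 * ct)
    if major < minor:
        theta += np.pi / 2
        ct, st = np.cos(theta), np.sin(theta)
        major, minor = minor, major
    a1s = a1 * ct + b1 * st
    c1s = c1 * ct + d1 * st
    psi = np.arctan2(c1s, a1s)
    scale = np.hypot(a1s, c1s)
    if scale <= 0:
        raise ValueError("degenerate first harmonic")
    # psi rotates (a1, c1) onto the +x axis, so a1 = +1 after scaling
    coeffs = _apply_phase_rotation(h.coeffs, theta, psi) / scale
    if coeffs[0, 3] < 0:  # reflection: flip y
        coeffs[:, 2] *= -1
        coeffs[:, 3] *= -1
    return HarmonicSet(
        coeffs=coeffs,
        dc=np.zeros(2),
        normalized=True,
        scale_factor=float(scale),
        source_id=h.source_id,
    )


def efa_inverse(h: HarmonicSet, K: int) -> OutlineLoop:
    """Evaluate the truncated Fourier series at K equally spaced parameter
    values, returning a closed loop."""
    if K < 8:
        raise ValueError("K must be >= 8")
    s = np.arange(K) / K  # parameter in [0, 1)
    n = np.arange(1, h.H + 1)[:, None]
    ang = 2 * np.pi * n * s[None, :]  # (H, K)
    cos, sin = np.cos(ang), np.sin(ang)
    a, b, c, d = h.coeffs.T
    x = h.dc[0] + a @ cos + b @ sin
    y = h.dc[1] + c @ cos + d @ sin
    return OutlineLoop(np.column_stack([x, y]), source_id=h.source_id)


def harmonics_to_frame(sets: list[HarmonicSet]):
    """Tabulate a list of harmonic sets as a pandas DataFrame (one row per
    shape: id, H, then the flattened coefficient vector)."""
    import pandas as pd

    H = sets[0].H
    cols = [f"{letter}{i}" for letter in "abcd" for i in range(1, H + 1)]
    data = [hs.to_vector() for hs in sets]
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "H", H)
    df.insert(0, "shape_id", [hs.source_id for hs in sets])
    return df
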