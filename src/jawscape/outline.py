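"""Closed-outline ingestion: boundary tracing from binary masks and
arc-length resampling to equally spaced landmarks.

The atomic shape representation throughout the package is the
:class:`OutlineLoop` — an ordered, closed, counterclockwise polygon of 2D
landmarks.  Masks are traced at single-pixel (marching-squares) resolution;
no sub-pixel smoothing is applied, because harmonic truncation in the
elliptical Fourier step performs the smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage import measure


class OutlineError(ValueError):
    """Raised for invalid or ambiguous outline inputs."""


@dataclass
class OutlineLoop:
    """Ordered closed polygon of 2D landmarks.

    Parameters
    ----------
    points : (n, 2) float array
        Vertex coordinates in mathematical convention (y up).  The closing
        edge from the last point back to the first is implicit.
    source_id : str
        Free-text label for provenance.
    """

    points: np.ndarray
    source_id: str = ""
    closed: bool = field(default=True)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise OutlineError("points must be an (n, 2) array")
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise OutlineError("an outline needs at least 3 distinct points")
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise OutlineError("consecutive duplicate points in outline")
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def closed_points(self) -> np.ndarray:
        """Vertices with the first point repeated at the end."""
        return np.vstack([self.points, self.points[:1]])

    def edge_lengths(self) -> np.ndarray:
        seg = np.diff(self.closed_points, axis=0)
        return np.hypot(seg[:, 0], seg[:, 1])

    @property
    def perimeter(self) -> float:
        return float(self.edge_lengths().sum())

    def signed_area(self) -> float:
        """Shoelace signed area; positive for counterclockwise loops."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area())

    def is_ccw(self) -> bool:
        return self.signed_area() > 0

    def reversed(self) -> "OutlineLoop":
        # keep the same start vertex, reverse traversal direction
        return replace(self, points=np.vstack([self.points[:1], self.points[:0:-1]]))

    def ensure_ccw(self) -> "OutlineLoop":
        return self if self.is_ccw() else self.reversed()

    def roll_to_max_x(self) -> "OutlineLoop":
        """Rotate the vertex ordering so landmark 0 is the point of maximum x
        (the anterior tip under the anterior-right convention).  Ties broken
        by smallest y."""
        pts = self.points
        candidates = np.flatnonzero(pts[:, 0] == pts[:, 0].max())
        i0 = candidates[np.argmin(pts[candidates, 1])]
        return replace(self, points=np.roll(pts, -i0, axis=0))


def trace_outline(mask: np.ndarray, source_id: str = "") -> OutlineLoop:
    """Trace the outer boundary of a single-component binary mask.

    The mask must contain exactly one 4-connected foreground component not
    touching the image border.  The returned loop is in image coordinates
    with the y axis flipped to mathematical convention (y up), oriented
    counterclockwise, with landmark 0 at maximum x.

    Raises
    ------
    OutlineError
        ``"ambiguous outline"`` for zero or multiple components,
        ``"clipped outline"`` if the foreground touches the border.
    """
    mask = np.asarray(mask)
    binary = mask > 0 if mask.dtype != bool else mask
    labels, n_comp = measure.label(binary, connectivity=1, return_num=True)
    if n_comp != 1:
        raise OutlineError(f"ambiguous outline: {n_comp} foreground components")
    if binary[0, :].any() or binary[-1, :].any() or binary[:, 0].any() or binary[:, -1].any():
        raise OutlineError("clipped outline: foreground touches the image border")

    contours = measure.find_contours(binary.astype(float), 0.5)
    # outer boundary = longest contour (holes produce shorter inner contours)
    contour = max(contours, key=len)
    rows, cols = contour[:, 0], contour[:, 1]
    h = binary.shape[0]
    pts = np.column_stack([cols, (h - 1) - rows])
    # find_contours closes the loop by repeating the first point
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # drop any residual consecutive duplicates from the marching squares walk
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
    pts = pts[keep]
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    loop = OutlineLoop(pts, source_id=source_id)
    return loop.ensure_ccw().roll_to_max_x()


def resample_loop(loop: OutlineLoop, K: int) -> OutlineLoop:
    """Resample a closed loop to ``K`` points equally spaced by arc length,
    starting from the loop's first point."""
    if K < 3:
        raise OutlineError("K must be at least 3")
    perim = loop.perimeter
    if perim <= 0:
        raise OutlineError("degenerate zero-perimeter loop")
    pts = loop.closed_points
    seg = loop.edge_lengths()
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(K) * (perim / K)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / seg[idx]
    new_pts = pts[idx] + frac[:, None] * (pts[idx + 1] - pts[idx])
    return replace(loop, points=new_pts)


def read_landmarks_csv(path: str | Path, source_id: str | None = None) -> OutlineLoop:
    """Read an x,y landmark loop from CSV (two columns, header optional)."""
    path = Path(path)
    raw = path.read_text().strip().splitlines()
    start = 0
    first = raw[0].replace(",", " ").split()
    try:
        [float(v) for v in first[:2]]
    except ValueError:
        start = 1
    rows = []
    for line in raw[start:]:
        parts = line.replace(",", " ").split()
        if parts:
            rows.append((float(parts[0]), float(parts[1])))
    return OutlineLoop(np.array(rows), source_id=source_id or path.stem)


def write_landmarks_csv(loop: OutlineLoop, path: str | Path) -> None:
    """Write a loop as a two-column x,y CSV at 6 decimal places."""
    with open(path, "w") as fh:
        fh.write("x,y\n")
        for x, y in loop.points:
            fh.write(f"{x:.6f},{y:.6f}\n")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask image (TIFF or PNG) as a boolean array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (arr.max() / 2 if arr.dtype != bool else 0)
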