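"""Multi-objective Pareto optimality surfaces over the theoretical grid.

Each grid cell carries k performance values (k = 2 or 3 here: median Von
Mises stress to minimize, rotational efficiency to maximize, relative area
to minimize).  A cell is Pareto optimal when no other cell weakly dominates
it — performs at least as well in every objective and strictly better in at
least one.  Iterative front peeling (Goldberg ranking) removes the current
Pareto set and recomputes, assigning front 1, 2, ... until all cells are
ranked; ranks are rescaled linearly to [0, 1] with 1 = first front.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


@dataclass
class ObjectiveSet:
    """Per-cell objective values with optimization senses.

    values : (n, k) array; senses : length-k sequence of "max"/"min";
    valid_mask : bool per cell (invalid cells are excluded from ranking).
    """

    values: np.ndarray
    senses: tuple[str, ...]
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.senses) != self.values.shape[1]:
            raise ValueError("senses length must equal number of objectives")
        if any(s not in ("max", "min") for s in self.senses):
            raise ValueError("senses must be 'max' or 'min'")
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.values), dtype=bool)

    def oriented(self) -> np.ndarray:
        """Values with every objective oriented to maximize."""
        sign = np.array([1.0 if s == "max" else -1.0 for s in self.senses])
        return self.values * sign


@dataclass
class ParetoSurface:
    """Front indices and [0, 1] optimality ranks per cell (NaN for cells
    excluded as invalid)."""

    rank: np.ndarray
    front_index: np.ndarray
    k: int
    metric_names: tuple[str, ...] = field(default_factory=tuple)


def _front_mask(oriented: np.ndarray) -> np.ndarray:
    """Weak-dominance Pareto front of oriented (all-maximize) points.

    Point j dominates i if j >= i in all objectives and j > i in at least
    one; exact duplicates do not dominate each other and co-rank.
    """
    n = len(oriented)
    on_front = np.ones(n, dtype=bool)
    for i in range(n):
        ge = np.all(oriented >= oriented[i], axis=1)
        gt = np.any(oriented > oriented[i], axis=1)
        if np.any(ge & gt):
            on_front[i] = False
    return on_front


def pareto_front(points: ObjectiveSet) -> np.ndarray:
    """Boolean mask (full length) of Pareto-optimal cells among the valid."""
    mask = np.zeros(len(points.values), dtype=bool)
    vi = np.flatnonzero(points.valid_mask)
    if len(vi) == 0:
        return mask
    if not np.all(np.isfinite(points.values[vi])):
        raise ValueError("non-finite objective values among valid cells")
    mask[vi[_front_mask(points.oriented()[vi])]] = True
    return mask


def goldberg_rank(points: ObjectiveSet) -> ParetoSurface:
    """Iterative front peeling with linear [0, 1] rescale.

    Front 1 is the Pareto set of all valid cells; it is removed and the
    front of the remainder becomes front 2, and so on.  With K fronts,
    rank(front j) = (K - j) / (K - 1); a single front ranks 1 everywhere.
    Invalid cells get NaN rank and front_index 0.
    """
    n = len(points.values)
    front_index = np.zeros(n, dtype=int)
    remaining = points.valid_mask.copy()
    if remaining.any() and not np.all(np.isfinite(points.values[remaining])):
        raise ValueError("non-finite objective values among valid cells")
    oriented = points.oriented()
    j = 0
    while remaining.any():
        j += 1
        idx = np.flatnonzero(remaining)
        on_front = _front_mask(oriented[idx])
        front_index[idx[on_front]] = j
        remaining[idx[on_front]] = False
    K = j
    rank = np.full(n, np.nan)
    ranked = front_index > 0
    if K == 1:
        rank[ranked] = 1.0
    elif K > 1:
        rank[ranked] = (K - front_index[ranked]) / (K - 1)
    return ParetoSurface(rank=rank, front_index=front_index, k=points.values.shape[1])


def optimality_surface(
    surfaces: dict[str, np.ndarray],
    senses: dict[str, str],
    valid_mask: np.ndarray | None = None,
) -> dict[tuple[str, ...], ParetoSurface]:
    """Goldberg-rank every objective pair and (for k = 3) the combined set.

    surfaces maps metric name -> per-cell mean value arrays sharing the
    same grid; senses maps metric name -> "max"/"min".  Returns a dict
    keyed by metric-name tuples.
    """
    names = list(surfaces)
    if not 2 <= len(names) <= 3:
        raise ValueError("need 2 or 3 performance surfaces")
    lengths = {len(np.asarray(surfaces[n])) for n in names}
    if len(lengths) != 1:
        raise ValueError("mismatched grids: surfaces differ in length")
    combos = list(combinations(names, 2))
    if len(names) == 3:
        combos.append(tuple(names))
    out = {}
    for combo in combos:
        obj = ObjectiveSet(
            values=np.column_stack([np.asarray(surfaces[n], dtype=float) for n in combo]),
            senses=tuple(senses[n] for n in combo),
            valid_mask=None if valid_mask is None else np.asarray(valid_mask, dtype=bool),
        )
        surf = goldberg_rank(obj)
        surf.metric_names = tuple(combo)
        out[tuple(combo)] = surf
    return out
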