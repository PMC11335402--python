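"""End-to-end orchestration: outlines -> EFA -> PCA -> theoretical grid ->
performance surfaces (with bootstraps) -> Pareto optimality surfaces.

Artifacts are plain CSV/JSON files written per stage so a run can be
inspected or resumed; the full configuration is serialized into the run
log for provenance.  All randomness is keyed from the single config seed:
cell c's bootstrap stream is a pure function of (seed, c, iteration), so
results do not depend on evaluation order.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import efa as efa_mod
from . import fea as fea_mod
from . import meshing as mesh_mod
from . import morphospace as ms_mod
from . import performance as perf_mod
from . import pareto as pareto_mod
from . import synth as synth_mod
from .outline import OutlineLoop, read_landmarks_csv, read_mask, resample_loop, trace_outline

METRIC_SENSES = {"vms": "min", "rot_eff": "max", "rel_area": "min"}


@dataclass
class PipelineConfig:
    """Full parameter set of one analysis run.

    Defaults follow the reference workflow: 600 landmarks, 40 harmonics,
    25 x 20 = 500 grid cells padded by 20% of the PC1 range, ~2500-element
    meshes at unit area, E = 2 GPa, nu = 0.3, 1000 bootstrap iterations
    with 5%-perimeter node jitter and 45-degree direction jitter.
    """

    input_dir: str | None = None
    synth_n: int | None = None
    landmarks: int = 600
    harmonics: int = 40
    grid_nx: int = 25
    grid_ny: int = 20
    extension: float = 0.20
    mesh_target: int = 2500
    young_modulus: float = 2.0e9
    poisson_ratio: float = 0.3
    n_iter: int = 1000
    node_jitter: float = 0.05
    angle_jitter: float = 45.0
    seed: int = 0
    metrics: tuple[str, ...] = ("vms", "rot_eff", "rel_area")
    output_dir: str = "jawscape_run"
    write_grid_shapes: bool = False

    def __post_init__(self) -> None:
        for name in ("landmarks", "harmonics", "grid_nx", "grid_ny", "mesh_target", "n_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.metrics) - set(METRIC_SENSES)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "metrics" in data:
            data["metrics"] = tuple(data["metrics"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        d["metrics"] = list(d["metrics"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _cell_seed(seed: int, cell: int) -> int:
    # stable per-cell stream key, kept below 2**31
    return int((seed * 1_000_003 + cell) % 2_147_483_647)


def load_outlines(cfg: PipelineConfig) -> list[OutlineLoop]:
    """Collect input outlines: synthetic population or a directory of
    binary mask images (.tif/.png) and/or landmark CSV loops."""
    loops: list[OutlineLoop] = []
    if cfg.synth_n is not None:
        pop = synth_mod.generate_population(cfg.synth_n, seed=cfg.seed, K=cfg.landmarks)
        loops = [loop for loop, _ in pop]
    elif cfg.input_dir is not None:
        paths = sorted(Path(cfg.input_dir).iterdir())
        for p in paths:
            if p.suffix.lower() in (".tif", ".tiff", ".png"):
                loops.append(trace_outline(read_mask(p), source_id=p.stem))
            elif p.suffix.lower() == ".csv":
                loops.append(read_landmarks_csv(p).ensure_ccw().roll_to_max_x())
        if not loops:
            raise FileNotFoundError(f"no outline inputs found in {cfg.input_dir}")
    else:
        raise ValueError("config must set input_dir or synth_n")
    return [resample_loop(lp, cfg.landmarks) for lp in loops]


def evaluate_cell(
    loop: OutlineLoop,
    cfg: PipelineConfig,
    cell_seed: int,
) -> dict[str, tuple[float, float, float]]:
    """All requested metrics for one valid grid cell.

    Returns metric -> (mean, ci_low, ci_high); relative area is a point
    value (its interval collapses to the value).
    """
    mesh = mesh_mod.triangulate(loop, n_target=cfg.mesh_target)
    mesh = mesh_mod.scale_to_area(mesh, 1.0)
    nodes = mesh_mod.identify_functional_nodes(loop, mesh)
    bcfg = fea_mod.BootstrapConfig(
        n_iter=cfg.n_iter,
        node_jitter_frac=cfg.node_jitter,
        angle_jitter_deg=cfg.angle_jitter,
        seed=cell_seed,
    )
    out: dict[str, tuple[float, float, float]] = {}
    if "vms" in cfg.metrics:
        material = fea_mod.Material(cfg.young_modulus, cfg.poisson_ratio)
        r = fea_mod.bootstrap_vms(mesh, material, nodes, bcfg)
        out["vms"] = (r.mean, r.ci_low, r.ci_high)
    if "rot_eff" in cfg.metrics:
        r = perf_mod.bootstrap_re(mesh, nodes, bcfg)
        out["rot_eff"] = (r.mean, r.ci_low, r.ci_high)
    if "rel_area" in cfg.metrics:
        a = perf_mod.relative_area(loop).rel_area
        out["rel_area"] = (a, a, a)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of artifact paths and
    in-memory results (morphospace, grid, surfaces, pareto)."""
    t0 = time.time()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(cfg), "stages": {}, "skipped_cells": []}
    log["config"]["metrics"] = list(cfg.metrics)

    # --- outlines -> normalized harmonics ---
    t = time.time()
    loops = load_outlines(cfg)
    hsets = [
        efa_mod.efa_normalize(efa_mod.efa_forward(lp, cfg.harmonics)) for lp in loops
    ]
    hdf = efa_mod.harmonics_to_frame(hsets)
    hdf.to_csv(outdir / "harmonics.csv", index=False, float_format="%.12g")
    log["stages"]["efa"] = {"n_shapes": len(loops), "seconds": time.time() - t}

    # --- PCA morphospace ---
    t = time.time()
    vectors = np.array([h.to_vector() for h in hsets])
    ms = ms_mod.fit_pca(vectors, shape_ids=[h.source_id for h in hsets])
    ms.to_json(outdir / "morphospace.json")
    scores = pd.DataFrame(ms.scores, columns=[f"PC{i+1}" for i in range(ms.n_axes)])
    scores.insert(0, "shape_id", ms.shape_ids)
    scores.to_csv(outdir / "scores.csv", index=False, float_format="%.12g")
    log["stages"]["pca"] = {
        "var_explained_pc1_pc2_pc3": [float(v) for v in ms.var_explained[:3]],
        "seconds": time.time() - t,
    }

    # --- theoretical grid ---
    t = time.time()
    grid = ms_mod.sample_grid(
        ms, nx=cfg.grid_nx, ny=cfg.grid_ny, extension_frac=cfg.extension, K=cfg.landmarks
    )
    grid.manifest().to_csv(outdir / "grid_manifest.csv", index=False, float_format="%.12g")
    if cfg.write_grid_shapes:
        shape_dir = outdir / "grid_shapes"
        shape_dir.mkdir(exist_ok=True)
        from .outline import write_landmarks_csv

        for i, shp in enumerate(grid.shapes):
            write_landmarks_csv(shp, shape_dir / f"cell_{i:04d}.csv")
    log["stages"]["grid"] = {
        "n_cells": grid.n_cells,
        "n_valid": int(grid.valid.sum()),
        "seconds": time.time() - t,
    }

    # --- per-cell performance surfaces ---
    t = time.time()
    n_cells = grid.n_cells
    surf = {
        m: {"value": np.full(n_cells, np.nan), "ci_low": np.full(n_cells, np.nan), "ci_high": np.full(n_cells, np.nan)}
        for m in cfg.metrics
    }
    for c in range(n_cells):
        if not grid.valid[c]:
            continue
        try:
            res = evaluate_cell(grid.shapes[c], cfg, _cell_seed(cfg.seed, c))
        except (mesh_mod.MeshingError, RuntimeError, ValueError) as exc:
            log["skipped_cells"].append({"cell": c, "reason": str(exc)})
            continue
        for m, (mean, lo, hi) in res.items():
            surf[m]["value"][c] = mean
            surf[m]["ci_low"][c] = lo
            surf[m]["ci_high"][c] = hi
    surfaces = {}
    for m in cfg.metrics:
        df = grid.manifest()
        df["metric"] = m
        df["value"] = surf[m]["value"]
        df["ci_low"] = surf[m]["ci_low"]
        df["ci_high"] = surf[m]["ci_high"]
        df.to_csv(outdir / f"surface_{m}.csv", index=False, float_format="%.12g")
        surfaces[m] = surf[m]["value"]
    log["stages"]["surfaces"] = {"seconds": time.time() - t}

    # --- Pareto optimality ---
    pareto = {}
    if len(cfg.metrics) >= 2:
        t = time.time()
        evaluated = grid.valid & np.all(
            [np.isfinite(surfaces[m]) for m in cfg.metrics], axis=0
        )
        pareto = pareto_mod.optimality_surface(
            surfaces, {m: METRIC_SENSES[m] for m in cfg.metrics}, valid_mask=evaluated
        )
        for combo, ps in pareto.items():
            df = grid.manifest()
            df["front_index"] = ps.front_index
            df["rank"] = ps.rank
            df["metric_pair"] = "+".join(combo)
            df.to_csv(outdir / f"pareto_{'_'.join(combo)}.csv", index=False, float_format="%.12g")
        (outdir / "pareto_manifest.json").write_text(
            json.dumps({"+".join(k): [METRIC_SENSES[m] for m in k] for k in pareto})
        )
        log["stages"]["pareto"] = {"seconds": time.time() - t}

    log["total_seconds"] = time.time() - t0
    log["seed"] = cfg.seed
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return {
        "morphospace": ms,
        "grid": grid,
        "surfaces": surfaces,
        "pareto": pareto,
        "log": log,
        "output_dir": str(outdir),
    }
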