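"""Run configuration, output writers and the run manifest.

Configurations are YAML or JSON mappings validated against a strict
schema (unknown keys are rejected).  Every run directory receives a JSON
manifest recording the fully-resolved configuration, its content hash,
the seed and the package version, which is sufficient to re-execute the
run exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class LatticeConfig(_Strict):
    h: float = Field(1.0, gt=0)
    dt: float = Field(1.0, gt=0)
    tau: float = Field(1.0, gt=0.5)
    resolution_scale: float = Field(1.0, ge=0.5)


class PortsConfig(_Strict):
    alpha: float = Field(6.0, gt=0)
    beta: float = Field(0.25, gt=0, lt=1)
    mode: str = "pressure"
    u_sum: float = Field(0.01, gt=0)

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("pressure", "flux"):
            raise ValueError("ports.mode must be 'pressure' or 'flux'")
        return v


class CellsConfig(_Strict):
    diameters: list[float] = [8.0, 16.0, 20.0, 24.0]
    Kl: float = Field(5.0, ge=0)
    Kb: float = Field(0.1, ge=0)
    Ks: float = Field(2.0, ge=0)
    Ke: float = Field(0.003, ge=0)
    rc_um: float = Field(2.0, gt=0)


class RunSection(_Strict):
    steps: int = Field(100_000, gt=0)
    ramp_steps: int = Field(2000, ge=0)
    snapshot_every: int = Field(0, ge=0)
    seed: int = 0


class RunConfig(_Strict):
    """Complete run description; defaults marked 'paper' come from the
    published device/benchmark, the rest are artifact defaults."""

    experiment: str = "sort"
    lattice: LatticeConfig = LatticeConfig()
    ports: PortsConfig = PortsConfig()
    cells: CellsConfig = CellsConfig()
    run: RunSection = RunSection()
    outdir: str = "runs/out"

    @field_validator("experiment")
    @classmethod
    def _exp(cls, v):
        allowed = {"sort", "sweep-alpha", "benchmark-cylinder",
                   "map-branches"}
        if v not in allowed:
            raise ValueError(f"experiment must be one of {sorted(allowed)}")
        return v

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)


# ---------------------------------------------------------------------
# writers

def write_vtk_image(path, arrays: dict, spacing: float = 1.0):
    """Legacy-VTK ASCII STRUCTURED_POINTS snapshot of 2D scalar fields."""
    first = next(iter(arrays.values()))
    ny, nx = first.shape[:2]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\npinchflow snapshot\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} 1\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {spacing} {spacing} 1\n")
        f.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in arrays.items():
            if arr.ndim == 2:
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr.reshape(-1, 1), fmt="%.9g")
            else:
                f.write(f"VECTORS {name} double\n")
                v = np.zeros((ny * nx, 3))
                v[:, :2] = arr.reshape(-1, 2)
                np.savetxt(f, v, fmt="%.9g")


def write_snapshot_h5(path, field, membranes=()):
    """HDF5 snapshot: macroscopic fields, mask and membrane chains."""
    with h5py.File(path, "w") as f:
        f.create_dataset("rho", data=field.rho, compression="gzip")
        f.create_dataset("ux", data=field.ux, compression="gzip")
        f.create_dataset("uy", data=field.uy, compression="gzip")
        f.create_dataset("mask", data=field.mask, compression="gzip")
        f.attrs["time_step"] = field.time_step
        for i, m in enumerate(membranes):
            grp = f.create_group(f"membrane_{i}")
            grp.create_dataset("X", data=m.X)
            grp.attrs["cell_id"] = m.cell_id
            grp.attrs["diameter"] = m.diameter
            grp.attrs["S0"] = m.S0


def read_snapshot_h5(path):
    out = {}
    with h5py.File(path, "r") as f:
        for k in ("rho", "ux", "uy", "mask"):
            out[k] = f[k][()]
        out["time_step"] = int(f.attrs["time_step"])
    return out


def write_membranes_csv(path, membranes):
    """Lagrangian chains as CSV rows (cell id, point index, x, y)."""
    with open(path, "w") as f:
        f.write("cell_id,point,x,y\n")
        for m in membranes:
            for j, (x, y) in enumerate(m.X):
                f.write(f"{m.cell_id},{j},{x:.10g},{y:.10g}\n")


def write_series_csv(path, header: list, rows):
    with open(path, "w") as f:
        f.write(",".join(header) + "\n")
        for row in rows:
            f.write(",".join(f"{v:.10g}" if isinstance(v, float)
                             else str(v) for v in row) + "\n")


def write_outputs(outdir, config: RunConfig, series: dict | None = None,
                  field=None, membranes=(), extra: dict | None = None
                  ) -> dict:
    """Write snapshots, CSV series and the JSON manifest; returns the
    manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    if field is not None:
        vtk = out / "snapshot.vtk"
        write_vtk_image(vtk, {"rho": field.rho,
                              "velocity": field.velocity()})
        files.append(vtk.name)
        h5 = out / "snapshot.h5"
        write_snapshot_h5(h5, field, membranes)
        files.append(h5.name)
    if membranes:
        mp = out / "membranes.csv"
        write_membranes_csv(mp, membranes)
        files.append(mp.name)
    for name, (header, rows) in (series or {}).items():
        p = out / f"{name}.csv"
        write_series_csv(p, header, rows)
        files.append(p.name)
    from . import __version__

    manifest = {
        "config": config.model_dump(),
        "config_hash": config.content_hash(),
        "seed": config.run.seed,
        "version": __version__,
        "files": sorted(files),
    }
    if extra:
        manifest["results"] = extra
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest
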