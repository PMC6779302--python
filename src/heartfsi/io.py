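"""Plain-text output: legacy-ASCII VTK snapshots, time-series CSV, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from heartfsi.ibfe import LagrangianMesh
from heartfsi.params import SimulationConfig


def write_mesh_vtk(path: str | Path, mesh: LagrangianMesh,
                   cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the triangulated structure (current configuration) as legacy VTK.

    Chord segments are included as VTK_LINE cells; per-element fields (region
    code, fibre vectors, any extra ``cell_data``) are attached as cell data.
    """
    path = Path(path)
    pts = mesh.chi
    n_tri, n_ch = len(mesh.tris), len(mesh.chords)
    lines = [
        "# vtk DataFile Version 3.0",
        "heartfsi structure snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} float",
    ]
    lines += [f"{x:.7g} {y:.7g} 0" for x, y in pts]
    lines.append(f"CELLS {n_tri + n_ch} {4 * n_tri + 3 * n_ch}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.tris]
    lines += [f"2 {a} {b}" for a, b in mesh.chords]
    lines.append(f"CELL_TYPES {n_tri + n_ch}")
    lines += ["5"] * n_tri + ["3"] * n_ch

    regions = sorted({str(r) for r in mesh.tri_region} | {str(r) for r in mesh.chord_region})
    code = {r: i for i, r in enumerate(regions)}
    reg = [code[str(r)] for r in mesh.tri_region] + [code[str(r)] for r in mesh.chord_region]
    lines.append(f"CELL_DATA {n_tri + n_ch}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(v) for v in reg]
    lines.append("VECTORS fibre float")
    lines += [f"{f[0]:.5g} {f[1]:.5g} 0" for f in mesh.frame_f]
    lines += ["0 0 0"] * n_ch
    for name, vals in (cell_data or {}).items():
        vals = np.asarray(vals, dtype=float)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in vals]
        if len(vals) < n_tri + n_ch:
            lines += ["0"] * (n_tri + n_ch - len(vals))
    path.write_text("\n".join(lines) + "\n")
    # region code legend alongside the snapshot
    path.with_suffix(".regions.json").write_text(json.dumps(code, indent=1))


def write_field_vtk(path: str | Path, u: np.ndarray, p: np.ndarray, h: float) -> None:
    """Write Eulerian velocity/pressure as a legacy VTK structured-points file."""
    path = Path(path)
    nx, ny = p.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "heartfsi fluid snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {h:.7g} {h:.7g} 1",
        f"POINT_DATA {nx * ny}",
        "VECTORS velocity float",
    ]
    # VTK structured points vary x fastest
    U = np.stack([u[0], u[1]], axis=-1).transpose(1, 0, 2).reshape(-1, 2)
    lines += [f"{a:.6g} {b:.6g} 0" for a, b in U]
    lines.append("SCALARS pressure float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{v:.6g}" for v in p.T.ravel()]
    path.write_text("\n".join(lines) + "\n")


def write_run_outputs(out_dir: str | Path, result) -> None:
    """Time-series CSV, phase log, metrics JSON and a config-hash manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.series.to_csv(out / "timeseries.csv", index=False)
    phase_log = result.series[["t", "phase", "P_inflow", "P_endo", "Pao"]]
    phase_log.to_csv(out / "phase_log.csv", index=False)
    try:
        metrics = result.metrics.to_dict()
    except Exception as exc:  # incomplete cycles still get a manifest
        metrics = {"error": str(exc)}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    cfg_yaml = result.config.to_yaml()
    (out / "config.yaml").write_text(cfg_yaml)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "dt0": result.dt0,
        "transition_times": result.transition_times,
        "n_samples": int(len(result.series)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
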