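"""Result export: time-series CSV, VTU field snapshots, run reports.

CSV column headers carry their units; VTU files are ASCII XML unstructured
grids readable by ParaView/VisIt, with tissue labels as cell data and the
temperature / damage / death-probability fields as point data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .damage import death_probability
from .meshing import Mesh
from .simulate import AblationResult

__all__ = ["write_timeseries_csv", "write_vtu", "write_report", "export_result"]

_FLOAT_FMT = "%.8g"


def write_timeseries_csv(result: AblationResult, path) -> Path:
    path = Path(path)
    df = result.timeseries()
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def _vtu_array(name: str, data: np.ndarray, n_comp: int = 1) -> str:
    body = " ".join(_FLOAT_FMT % v for v in np.asarray(data, float).ravel())
    return (
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{n_comp}" format="ascii">{body}</DataArray>'
    )


def write_vtu(
    mesh: Mesh,
    path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write the mesh (and optional fields) as an ASCII .vtu file."""
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_triangles
    pts = np.column_stack([mesh.nodes, np.zeros(n)])
    conn = " ".join(str(i) for i in mesh.triangles.ravel())
    offs = " ".join(str(3 * (i + 1)) for i in range(m))
    types = " ".join("5" for _ in range(m))  # VTK_TRIANGLE

    label_names = sorted(set(mesh.labels.tolist()))
    label_code = np.array([label_names.index(l) for l in mesh.labels.tolist()], float)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region_id", label_code)

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        f"<!-- region_id legend: {', '.join(f'{i}={n_}' for i, n_ in enumerate(label_names))} -->",
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        _vtu_array("coordinates", pts, 3),
        "</Points>",
        "<Cells>",
        f'<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>',
        f'<DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>',
        f'<DataArray type="UInt8" Name="types" format="ascii">{types}</DataArray>',
        "</Cells>",
    ]
    if point_data:
        parts.append("<PointData>")
        parts.extend(_vtu_array(k, v) for k, v in point_data.items())
        parts.append("</PointData>")
    parts.append("<CellData>")
    parts.extend(_vtu_array(k, v) for k, v in cell_data.items())
    parts.append("</CellData>")
    parts.extend(["</Piece>", "</UnstructuredGrid>", "</VTKFile>"])
    path.write_text("\n".join(parts))
    return path


def write_report(result: AblationResult, path) -> Path:
    path = Path(path)
    cfg = result.config
    lines = [
        "ooablate run report",
        "===================",
        f"scenario           : {cfg.scenario_id}",
        f"control temperature: {cfg.control_temperature} C",
        f"heating / cooldown : {cfg.heat_duration} s / {cfg.cool_duration} s",
        f"mesh               : {result.provenance['mesh_level']}"
        f" ({result.provenance['mesh_nodes']} nodes,"
        f" {result.provenance['mesh_triangles']} triangles)",
        f"time steps         : {cfg.dt_heat} s heat, {cfg.dt_cool} s cool",
        f"seed               : {cfg.seed}",
        "",
        f"peak temperature anywhere     : {result.peak_temperature:.2f} C",
        f"final tip temperature         : {result.tip_temperature[-1]:.2f} C",
        f"final perpendicular radius    : {result.final_radius('perpendicular'):.2f} mm",
        f"final parallel radius         : {result.final_radius('parallel'):.2f} mm",
        f"final ablation diameter (perp): {2 * result.final_radius('perpendicular'):.2f} mm",
        "",
        f"package version {result.provenance['package_version']}",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def export_result(result: AblationResult, outdir) -> dict[str, Path]:
    """Write the standard output set of one run into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {
        "timeseries": write_timeseries_csv(result, outdir / "timeseries.csv"),
        "report": write_report(result, outdir / "report.txt"),
    }
    for name, snap in result.snapshots.items():
        written[f"vtu_{name}"] = write_vtu(
            result.mesh,
            outdir / f"fields_{name}.vtu",
            point_data={
                "temperature_C": snap["T"],
                "omega": snap["omega"],
                "death_probability": death_probability(snap["omega"]),
            },
            cell_data={"q_rf_W_m3": snap["q_rf"]},
        )
    return written
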