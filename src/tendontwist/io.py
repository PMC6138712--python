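"""File formats: legacy-VTK unstructured grids for meshes and fields,
CSV for profiles/records/results, YAML study configuration, and the
packaged reference tables from the published cadaver calibration study.

Coordinate convention written into every file header comment:
x = medial(+)/lateral(-), y = anterior(+)/posterior(-),
z = distal(0) -> proximal(+); units mm, N, MPa.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constitutive import MaterialParams
from .geometry import CrossSectionProfile, TendonMesh

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_result_vtk",
    "write_euler_csv",
    "read_euler_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_record_csv",
    "read_record_csv",
    "load_config",
    "save_config",
    "config_hash",
    "load_reference_rms_table",
    "load_reference_coefficients",
    "parse_printed_tables",
]

_CONVENTION = ("units mm/N/MPa; x=medial(+)/lateral(-), "
               "y=anterior(+)/posterior(-), z=distal(0)->proximal(+)")


# ---------------------------------------------------------------- VTK I/O

def write_vtk(path, mesh: TendonMesh, point_data: dict | None = None,
              cell_data: dict | None = None, title: str = "tendon mesh"):
    """Write a hexahedral mesh with optional fields as legacy-VTK ASCII.

    ``point_data``/``cell_data`` map names to scalar (n,) or vector (n, 3)
    arrays. Compartment and sub-tendon labels are included automatically
    when present.
    """
    cell_data = dict(cell_data or {})
    if mesh.compartment_label is not None:
        cell_data.setdefault("compartment", mesh.compartment_label)
    if mesh.subtendon_label is not None:
        cell_data.setdefault("subtendon", mesh.subtendon_label)

    lines = ["# vtk DataFile Version 3.0",
             f"{title} ({_CONVENTION})",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for p in mesh.node_coords:
        lines.append(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
    lines.append(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}")
    for h in mesh.hexes:
        lines.append("8 " + " ".join(str(int(i)) for i in h))
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines.extend(["12"] * mesh.n_elems)

    def emit(block: dict, n: int, kind: str):
        out = [f"{kind} {n}"]
        for name, arr in block.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                is_int = np.issubdtype(arr.dtype, np.integer)
                out.append(f"SCALARS {name} {'int' if is_int else 'double'} 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v:d}" if is_int else f"{v:.10g}" for v in arr)
            else:
                out.append(f"VECTORS {name} double")
                out.extend(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}" for v in arr)
        return out

    if point_data:
        lines.extend(emit(point_data, mesh.n_nodes, "POINT_DATA"))
    if cell_data:
        lines.extend(emit(cell_data, mesh.n_elems, "CELL_DATA"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Read a legacy-VTK hexahedral grid written by :func:`write_vtk`.

    Returns (node_coords, hexes, point_data, cell_data); only the subset of
    the format this package emits is supported.
    """
    tok = Path(path).read_text().split("\n")
    i = 0
    coords = hexes = None
    point_data, cell_data = {}, {}
    section, n_items = None, 0
    while i < len(tok):
        line = tok[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            coords = np.array([[float(x) for x in tok[i + 1 + k].split()]
                               for k in range(n)])
            i += n
        elif line.startswith("CELLS"):
            n = int(line.split()[1])
            hexes = np.array([[int(x) for x in tok[i + 1 + k].split()[1:]]
                              for k in range(n)])
            i += n
        elif line.startswith("POINT_DATA"):
            section, n_items = point_data, int(line.split()[1])
        elif line.startswith("CELL_DATA"):
            section, n_items = cell_data, int(line.split()[1])
        elif line.startswith("SCALARS"):
            name, typ = line.split()[1:3]
            vals = [tok[i + 2 + k].strip() for k in range(n_items)]
            section[name] = (np.array([int(v) for v in vals])
                             if typ == "int" else
                             np.array([float(v) for v in vals]))
            i += n_items + 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            section[name] = np.array(
                [[float(x) for x in tok[i + 1 + k].split()]
                 for k in range(n_items)])
            i += n_items
        i += 1
    return coords, hexes, point_data, cell_data


def write_result_vtk(path, mesh, result, fiber_field=None):
    """Write a solve result (displacements, von Mises, optional fiber
    directions as cell vectors) alongside the mesh labels."""
    cell = {"von_mises_mean": result.gauss_von_mises.mean(axis=1)}
    if fiber_field is not None:
        cell["fiber_dir"] = fiber_field.gauss_fiber_dirs.mean(axis=1)
    write_vtk(path, mesh,
              point_data={"displacement": result.nodal_displacements},
              cell_data=cell, title="tendon solve result")


def write_euler_csv(path, field):
    """Euler-angle nodal field as CSV (node_id, alpha, beta, gamma), radians."""
    df = pd.DataFrame(field.nodal_euler_angles,
                      columns=["alpha", "beta", "gamma"])
    df.insert(0, "node_id", np.arange(len(df)))
    with open(path, "w") as fh:
        fh.write("# Z-Y-Z Euler angles (radians) in the local cylindrical "
                 f"material frame; {_CONVENTION}\n")
        df.to_csv(fh, index=False)


def read_euler_csv(path):
    """Read an Euler-angle CSV back into an EulerAngleField."""
    from .fiber import EulerAngleField

    df = pd.read_csv(path, comment="#").sort_values("node_id")
    return EulerAngleField(
        nodal_euler_angles=df[["alpha", "beta", "gamma"]].to_numpy())


# ---------------------------------------------------------------- CSV I/O

def write_profile_csv(path, profile: CrossSectionProfile):
    df = pd.DataFrame(profile.stations, columns=[
        "station_mm", "semi_axis_a_mm", "semi_axis_b_mm",
        "offset_x_mm", "offset_y_mm"])
    with open(path, "w") as fh:
        fh.write(f"# cross-section profile; {_CONVENTION}\n")
        df.to_csv(fh, index=False)


def read_profile_csv(path) -> CrossSectionProfile:
    df = pd.read_csv(path, comment="#")
    return CrossSectionProfile(df.to_numpy())


def write_record_csv(path, record):
    """Experiment record in long format:
    time_s, force_N, marker_id, x_mm, y_mm, z_mm."""
    rows = []
    nt, nm, _ = record.marker_trajectories.shape
    for t in range(nt):
        for m in range(nm):
            x, y, z = record.marker_trajectories[t, m]
            rows.append((record.time[t], record.applied_force[t], m, x, y, z))
    df = pd.DataFrame(rows, columns=["time_s", "force_N", "marker_id",
                                     "x_mm", "y_mm", "z_mm"])
    with open(path, "w") as fh:
        fh.write(f"# cyclic-test record; noise_sd_mm={record.noise_sd}; "
                 f"seed={record.seed}; {_CONVENTION}\n")
        df.to_csv(fh, index=False)


def read_record_csv(path):
    """Read a record CSV back into (time, force, trajectories) arrays."""
    df = pd.read_csv(path, comment="#")
    nt = df["time_s"].nunique()
    nm = df["marker_id"].nunique()
    df = df.sort_values(["time_s", "marker_id"])
    traj = df[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(nt, nm, 3)
    time = df["time_s"].to_numpy().reshape(nt, nm)[:, 0]
    force = df["force_N"].to_numpy().reshape(nt, nm)[:, 0]
    return time, force, traj


# ------------------------------------------------------------- config I/O

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict):
    clean = json.loads(json.dumps(config, default=float))
    with open(path, "w") as fh:
        yaml.safe_dump(clean, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict (embedded in outputs)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------- reference tables

def _data_path(name: str):
    return resources.files("tendontwist.data").joinpath(name)


def load_reference_rms_table() -> pd.DataFrame:
    """Published per-subject marker-RMS table (mm): 10 subjects x 5 twist
    angles, plus the printed Average and SD rows."""
    with resources.as_file(_data_path("reference_marker_rms.csv")) as p:
        return pd.read_csv(p, comment="#", index_col=0)


def load_reference_coefficients() -> pd.DataFrame:
    """Published per-subject optimized coefficients (C1, C3 MPa; C4
    dimensionless) across twist angles, plus printed Average/SD rows.

    The printed Average row of this table is not the mean of its printed
    per-subject values; the per-subject values are treated as authoritative
    and are used only to bound the optimizer."""
    with resources.as_file(_data_path("reference_coefficients.csv")) as p:
        return pd.read_csv(p, comment="#", index_col=0)


def parse_printed_tables(table: pd.DataFrame):
    """Per-subject value matrix and printed summary rows of a reference CSV.

    Returns (values: subjects x columns DataFrame, printed: dict of summary
    rows, e.g. 'Average' and 'SD'). Raises on malformed fixtures.
    """
    if table.empty:
        raise ValueError("empty reference table")
    summary_rows = [r for r in table.index if isinstance(r, str)
                    and not str(r).lstrip("-").isdigit()]
    value_rows = [r for r in table.index if r not in summary_rows]
    if not value_rows:
        raise ValueError("reference table has no per-subject rows")
    values = table.loc[value_rows].astype(float)
    if values.isna().any().any():
        raise ValueError("reference table has missing per-subject values")
    printed = {str(r): table.loc[r].astype(float) for r in summary_rows}
    return values, printed
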