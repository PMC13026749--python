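"""File readers and writers: point clouds, meshes, transforms, tables.

All interchange formats are plain text: XYZ / CSV point clouds, ASCII PLY
and STL meshes, 4x4 row-major JSON transforms, CSV tables with a mandatory
header row (comma separated, dot decimal, UTF-8).  Distances are mm.
Result tables embed the configuration hash and seed in comment lines for
reproducibility.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .agreement import CrossTab
from .cylinder import PointCloud
from .errors import PedscrewError
from .geometry import Point3, RigidTransform, TrajectoryPlan

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_points_csv",
    "write_points_csv",
    "load_mesh",
    "save_mesh",
    "read_transform_json",
    "write_transform_json",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "read_crosstab_csv",
    "load_crosstab_fixture",
    "write_table",
]


def read_xyz(path, label: str = "screw_proximal", frame: str = "CMM") -> PointCloud:
    """Whitespace-separated x y z coordinates, one point per line; '#' comments."""
    try:
        pts = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as e:
        raise PedscrewError(f"malformed XYZ file {path}: {e}") from e
    if pts.shape[1] != 3:
        raise PedscrewError(f"{path}: expected 3 columns, found {pts.shape[1]}")
    return PointCloud(pts, label=label, frame=frame)


def write_xyz(path, cloud: PointCloud, header: str = "") -> None:
    np.savetxt(path, cloud.points, fmt="%.6f", header=header, comments="# ")


def read_points_csv(path, label: str = "screw_proximal", frame: str = "CMM") -> PointCloud:
    df = pd.read_csv(path, comment="#")
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise PedscrewError(f"{path}: missing columns {sorted(missing)}")
    return PointCloud(df[["x", "y", "z"]].to_numpy(float), label=label, frame=frame)


def write_points_csv(path, cloud: PointCloud) -> None:
    pd.DataFrame(cloud.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def load_mesh(path):
    import trimesh

    mesh = trimesh.load(str(path), process=False)
    if not hasattr(mesh, "vertices"):
        raise PedscrewError(f"{path}: not a triangle mesh")
    return mesh


def save_mesh(path, mesh) -> None:
    path = str(path)
    kind = path.rsplit(".", 1)[-1].lower()
    if kind == "stl":
        mesh.export(path, file_type="stl_ascii")
    else:
        mesh.export(path, encoding="ascii")


def read_transform_json(path) -> RigidTransform:
    with open(path) as fh:
        data = json.load(fh)
    return RigidTransform.from_matrix(np.array(data["matrix"], dtype=float))


def write_transform_json(path, T: RigidTransform, meta: dict | None = None) -> None:
    data = {"matrix": T.matrix.tolist()}
    if meta:
        data.update(meta)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


_TRAJ_COLS = ["model_id", "vertebra", "side", "Pe_x", "Pe_y", "Pe_z", "Pt_x", "Pt_y", "Pt_z"]


def read_trajectories_csv(path, frame: str = "R0"):
    """Planned trajectory table -> list of (ids, TrajectoryPlan)."""
    df = pd.read_csv(path, comment="#")
    missing = set(_TRAJ_COLS) - set(df.columns)
    if missing:
        raise PedscrewError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        plan = TrajectoryPlan(
            Point3(r.Pe_x, r.Pe_y, r.Pe_z, frame),
            Point3(r.Pt_x, r.Pt_y, r.Pt_z, frame),
        )
        out.append(({"model_id": r.model_id, "vertebra": r.vertebra, "side": r.side}, plan))
    return out


def write_trajectories_csv(path, rows) -> None:
    """Inverse of :func:`read_trajectories_csv`."""
    recs = []
    for ids, plan in rows:
        rec = dict(ids)
        rec.update(
            Pe_x=plan.entry.x, Pe_y=plan.entry.y, Pe_z=plan.entry.z,
            Pt_x=plan.target.x, Pt_y=plan.target.y, Pt_z=plan.target.z,
        )
        recs.append(rec)
    pd.DataFrame(recs, columns=_TRAJ_COLS).to_csv(path, index=False)


def read_crosstab_csv(path) -> CrossTab:
    """Square grade table with optional 'Total' margins row/column."""
    df = pd.read_csv(path, comment="#", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    printed_rows = printed_cols = grand = None
    if "Total" in df.columns and "Total" in df.index:
        grand = int(df.loc["Total", "Total"])
    if "Total" in df.columns:
        col = df["Total"].drop(index="Total", errors="ignore")
        printed_rows = tuple(int(v) for v in col)
        df = df.drop(columns="Total")
    if "Total" in df.index:
        printed_cols = tuple(int(v) for v in df.loc["Total"])
        df = df.drop(index="Total")
    cells = df.astype(int)
    if list(cells.index) != list(cells.columns):
        raise PedscrewError(f"{path}: table is not square in its categories")
    return CrossTab(
        tuple(cells.columns),
        cells.to_numpy(),
        printed_row_totals=printed_rows,
        printed_col_totals=printed_cols,
        printed_grand_total=grand,
    )


_FIXTURES = {"gertzbein": "gertzbein_table2.csv", "heary": "heary_table3.csv"}


def load_crosstab_fixture(name: str) -> CrossTab:
    """Bundled dpw-vs-reference grade tables ('gertzbein' or 'heary').

    Cells and printed margins are preserved verbatim; check
    ``margins_consistent`` (the Heary table's printed margins disagree with
    its own cells).
    """
    if name not in _FIXTURES:
        raise PedscrewError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    ref = resources.files("pedscrew.data") / _FIXTURES[name]
    with resources.as_file(ref) as path:
        return read_crosstab_csv(path)


def write_table(path, df: pd.DataFrame, config_hash: str = "", seed: int | None = None) -> None:
    """CSV with provenance comment lines (config hash and seed)."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)
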