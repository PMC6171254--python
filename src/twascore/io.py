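"""Readers and writers for surface field data, annotations and results.

Two on-disk forms carry a :class:`~twascore.fields.WallFieldSeries`:

* an ``.npz`` archive with arrays ``vertices`` (N,3), ``faces`` (M,3,
  0-based), ``times`` (T,), ``wss_vectors`` (T,M,3), optional ``pressure``
  (T,M), ``sac_mask`` (M,), and scalars ``period`` / ``diastolic_index``;
* legacy-ASCII VTK polydata with per-cell ``VECTORS WSS_t<k>`` arrays (one
  per time sample), optional ``SCALARS pressure_t<k>``, a ``SCALARS
  sac_mask`` array, and the time grid in a ``FIELD`` block — the dialect
  CFD post-processors commonly export.

Annotations travel as a JSON list of ``{role, cx, cy, r}`` circles in pixel
units.  Result tables are plain CSV/JSON; the dE_m map can be written as a
16-bit grayscale PNG heatmap.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorimetry import RegionAnnotation
from .fields import SacMask, WallFieldSeries
from .mesh import SurfaceMesh

__all__ = [
    "save_field_container",
    "load_field_container",
    "write_vtk_polydata",
    "read_vtk_polydata",
    "load_annotations",
    "save_annotations",
    "read_image",
    "write_image",
    "write_delta_e_heatmap",
    "write_face_table",
]


# --------------------------------------------------------------------------
# npz container

def save_field_container(
    path, series: WallFieldSeries, sac: Optional[SacMask] = None
) -> None:
    arrays = {
        "vertices": series.mesh.vertices,
        "faces": series.mesh.faces,
        "times": series.times,
        "wss_vectors": series.wss_vectors,
    }
    if series.pressure is not None:
        arrays["pressure"] = series.pressure
    if sac is not None:
        arrays["sac_mask"] = sac.member
    if series.period is not None:
        arrays["period"] = np.array(series.period)
    if series.diastolic_index is not None:
        arrays["diastolic_index"] = np.array(series.diastolic_index)
    np.savez_compressed(path, **arrays)


def load_field_container(path) -> tuple[WallFieldSeries, Optional[SacMask]]:
    with np.load(path) as data:
        mesh = SurfaceMesh(data["vertices"], data["faces"])
        series = WallFieldSeries(
            mesh=mesh,
            times=data["times"],
            wss_vectors=data["wss_vectors"],
            pressure=data["pressure"] if "pressure" in data else None,
            period=float(data["period"]) if "period" in data else None,
            diastolic_index=(
                int(data["diastolic_index"]) if "diastolic_index" in data else None
            ),
        )
        sac = SacMask(data["sac_mask"]) if "sac_mask" in data else None
    return series, sac


# --------------------------------------------------------------------------
# legacy ASCII VTK polydata

def write_vtk_polydata(
    path, series: WallFieldSeries, sac: Optional[SacMask] = None
) -> None:
    mesh = series.mesh
    lines = [
        "# vtk DataFile Version 3.0",
        "twascore wall field series",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(mesh.vertices)} double",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    m = mesh.n_faces
    lines.append(f"POLYGONS {m} {4 * m}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    lines.append(f"CELL_DATA {m}")

    meta: list[tuple[str, str, list]] = [
        ("times", "double", [f"{t:.9g}" for t in series.times])
    ]
    if series.period is not None:
        meta.append(("period", "double", [f"{series.period:.9g}"]))
    if series.diastolic_index is not None:
        meta.append(("diastolic_index", "int", [str(series.diastolic_index)]))
    lines.append(f"FIELD metadata {len(meta)}")
    for name, dtype, vals in meta:
        lines.append(f"{name} 1 {len(vals)} {dtype}")
        lines.append(" ".join(vals))

    if sac is not None:
        lines.append("SCALARS sac_mask int 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(int(x)) for x in sac.member)
    for k in range(series.n_times):
        lines.append(f"VECTORS WSS_t{k} double")
        for vec in series.wss_vectors[k]:
            lines.append(f"{vec[0]:.9g} {vec[1]:.9g} {vec[2]:.9g}")
        if series.pressure is not None:
            lines.append(f"SCALARS pressure_t{k} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{x:.9g}" for x in series.pressure[k])
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path) -> tuple[WallFieldSeries, Optional[SacMask]]:
    tokens = Path(path).read_text().split("\n")
    # strip comments/blank lines, keep a flat token stream
    stream: list[str] = []
    for line in tokens:
        if line.startswith("#") or not line.strip():
            continue
        stream.extend(line.split())
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        out = stream[pos : pos + n]
        if len(out) < n:
            raise ValueError("truncated VTK file")
        pos += n
        return out

    def seek(keyword: str) -> bool:
        nonlocal pos
        while pos < len(stream):
            if stream[pos].upper() == keyword:
                return True
            pos += 1
        return False

    if not seek("POINTS"):
        raise ValueError("not a VTK polydata file (no POINTS)")
    pos += 1
    n_pts = int(take(1)[0])
    take(1)  # dtype
    vertices = np.array(take(3 * n_pts), dtype=float).reshape(n_pts, 3)

    if not seek("POLYGONS"):
        raise ValueError("no POLYGONS section")
    pos += 1
    n_poly = int(take(1)[0])
    take(1)  # total size
    faces = np.empty((n_poly, 3), dtype=np.int64)
    for i in range(n_poly):
        row = take(4)
        if row[0] != "3":
            raise ValueError("only triangle polydata is supported")
        faces[i] = [int(x) for x in row[1:]]

    if not seek("CELL_DATA"):
        raise ValueError("no CELL_DATA section")
    pos += 1
    m = int(take(1)[0])

    times = period = diastolic_index = None
    sac_vals = None
    wss_arrays: dict[int, np.ndarray] = {}
    pressure_arrays: dict[int, np.ndarray] = {}
    while pos < len(stream):
        tok = stream[pos].upper()
        if tok == "FIELD":
            pos += 2  # FIELD <name>
            n_arrays = int(take(1)[0])
            for _ in range(n_arrays):
                name, _comp, n_val, _dtype = take(4)
                vals = take(int(n_val))
                if name == "times":
                    times = np.array(vals, dtype=float)
                elif name == "period":
                    period = float(vals[0])
                elif name == "diastolic_index":
                    diastolic_index = int(vals[0])
        elif tok == "SCALARS":
            pos += 1
            name = take(1)[0]
            take(2)  # dtype, n_components
            take(2)  # LOOKUP_TABLE default
            vals = np.array(take(m), dtype=float)
            if name == "sac_mask":
                sac_vals = vals.astype(bool)
            elif name.startswith("pressure_t"):
                pressure_arrays[int(name[len("pressure_t"):])] = vals
        elif tok == "VECTORS":
            pos += 1
            name = take(1)[0]
            take(1)  # dtype
            vals = np.array(take(3 * m), dtype=float).reshape(m, 3)
            if name.startswith("WSS_t"):
                wss_arrays[int(name[len("WSS_t"):])] = vals
        else:
            pos += 1

    if times is None or not wss_arrays:
        raise ValueError("missing times FIELD or WSS_t<k> vector arrays")
    order = sorted(wss_arrays)
    if order != list(range(len(order))) or len(order) != times.size:
        raise ValueError("WSS_t<k> arrays do not match the time grid")
    wss = np.stack([wss_arrays[k] for k in order])
    pressure = (
        np.stack([pressure_arrays[k] for k in order]) if pressure_arrays else None
    )
    mesh = SurfaceMesh(vertices, faces)
    series = WallFieldSeries(
        mesh=mesh, times=times, wss_vectors=wss, pressure=pressure,
        period=period, diastolic_index=diastolic_index,
    )
    sac = SacMask(sac_vals) if sac_vals is not None else None
    return series, sac


# --------------------------------------------------------------------------
# annotations and images

def load_annotations(path) -> list[RegionAnnotation]:
    entries = json.loads(Path(path).read_text())
    return [
        RegionAnnotation(cx=e["cx"], cy=e["cy"], radius=e["r"], role=e["role"])
        for e in entries
    ]


def save_annotations(path, annotations) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"role": a.role, "cx": a.cx, "cy": a.cy, "r": a.radius}
                for a in annotations
            ],
            indent=2,
        )
    )


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return np.asarray(img)


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, image)


def write_delta_e_heatmap(path, values: np.ndarray) -> None:
    """dE_m map as a 16-bit grayscale PNG, linearly scaled to full range."""
    v = np.asarray(values, dtype=float)
    top = v.max() if v.max() > 0 else 1.0
    iio.imwrite(path, (v / top * 65535.0 + 0.5).astype(np.uint16))


def write_face_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
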