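"""Minimal legacy-ASCII VTK I/O for tube surfaces and lumen lattices.

Writes DATASET POLYDATA (surface + per-vertex arrays) and DATASET
STRUCTURED_GRID (lumen lattice + per-point arrays) files with FIELD point
data, plus a JSON manifest mapping times to files.  Floats are printed with
17 significant digits so a write/read round trip is bit-exact.  The reader
only targets files produced by this writer (plus benign whitespace
variation); it is not a general VTK parser.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import FormatError

__all__ = [
    "write_polydata",
    "read_polydata",
    "write_structured_grid",
    "read_structured_grid",
    "write_field_series",
    "read_field_series",
]

_FMT = "%.17g"


def _write_array_block(fh, name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    ncomp = 1 if arr.ndim == 1 else arr.shape[1]
    fh.write(f"{name} {ncomp} {arr.shape[0]} double\n")
    np.savetxt(fh, arr.reshape(arr.shape[0], -1), fmt=_FMT)


def write_polydata(path, points: np.ndarray, polygons: np.ndarray, point_data: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoroshear surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt=_FMT)
        polys = np.asarray(polygons, dtype=int)
        fh.write(f"POLYGONS {len(polys)} {len(polys) * (polys.shape[1] + 1)}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(len(polys), polys.shape[1]), polys]),
            fmt="%d",
        )
        if point_data:
            fh.write(f"POINT_DATA {len(points)}\n")
            fh.write(f"FIELD FieldData {len(point_data)}\n")
            for name, arr in point_data.items():
                _write_array_block(fh, name, arr)


def write_structured_grid(path, dims: tuple[int, int, int], points: np.ndarray, point_data: dict | None = None) -> None:
    """dims are (nx, ny, nz) with x the fastest-varying point index."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoroshear volume\nASCII\n")
        fh.write("DATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt=_FMT)
        if point_data:
            fh.write(f"POINT_DATA {len(points)}\n")
            fh.write(f"FIELD FieldData {len(point_data)}\n")
            for name, arr in point_data.items():
                _write_array_block(fh, name, arr)


def _read_floats(tokens, n):
    return np.array([float(t) for t in tokens[:n]]), tokens[n:]


def _parse_vtk(path):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing timestep file: {path}")
    text = path.read_text().split("\n")
    i = 0
    header = {"point_data": {}}
    points = polys = None
    dims = None
    npts = 0
    while i < len(text):
        line = text[i].strip()
        i += 1
        if not line or line.startswith("#") or line in ("ASCII",):
            continue
        parts = line.split()
        kw = parts[0].upper()
        if kw == "DATASET":
            header["dataset"] = parts[1]
        elif kw == "DIMENSIONS":
            dims = tuple(int(x) for x in parts[1:4])
        elif kw == "POINTS":
            npts = int(parts[1])
            vals = []
            while len(vals) < 3 * npts:
                vals.extend(text[i].split())
                i += 1
            points = np.array(vals[: 3 * npts], dtype=float).reshape(npts, 3)
        elif kw == "POLYGONS":
            ncells = int(parts[1])
            rows = []
            while len(rows) < ncells:
                row = text[i].split()
                i += 1
                if row:
                    rows.append([int(x) for x in row[1:]])
            polys = np.array(rows, dtype=int)
        elif kw == "POINT_DATA":
            npd = int(parts[1])
            if npd != npts:
                raise FormatError(f"POINT_DATA count {npd} != POINTS {npts} in {path}")
        elif kw == "FIELD":
            nfields = int(parts[2])
            for _ in range(nfields):
                while not text[i].strip():
                    i += 1
                name, ncomp, ntup, _dtype = text[i].split()
                i += 1
                ncomp, ntup = int(ncomp), int(ntup)
                vals = []
                while len(vals) < ncomp * ntup:
                    vals.extend(text[i].split())
                    i += 1
                arr = np.array(vals[: ncomp * ntup], dtype=float)
                header["point_data"][name] = (
                    arr.reshape(ntup, ncomp) if ncomp > 1 else arr
                )
        else:
            continue
    header["points"] = points
    header["polygons"] = polys
    header["dimensions"] = dims
    return header


def read_polydata(path):
    h = _parse_vtk(path)
    if h.get("dataset") != "POLYDATA":
        raise FormatError(f"{path}: expected DATASET POLYDATA")
    return h["points"], h["polygons"], h["point_data"]


def read_structured_grid(path):
    h = _parse_vtk(path)
    if h.get("dataset") != "STRUCTURED_GRID":
        raise FormatError(f"{path}: expected DATASET STRUCTURED_GRID")
    return h["dimensions"], h["points"], h["point_data"]


# ---------------------------------------------------------------------------
# field series
# ---------------------------------------------------------------------------


def write_field_series(wall, vol, outdir) -> Path:
    """Per-timestep VTK files plus ``series_manifest.json``; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "period": wall.period,
        "surface": {},
        "volume": {},
        "inlet_pressure": {},
        "vertex_s_file": "vertex_s.txt",
    }
    np.savetxt(outdir / "vertex_s.txt", wall.vertex_s, fmt=_FMT)
    geom = wall.geom
    tris = geom.triangles if geom is not None else np.zeros((0, 3), dtype=int)
    pts = geom.vertices if geom is not None else np.zeros((len(wall.vertex_s), 3))
    for it, t in enumerate(wall.times):
        fname = f"wall_{it:04d}.vtk"
        write_polydata(
            outdir / fname,
            pts,
            tris,
            {"wss": wall.wss[it], "pressure": wall.pressure[it]},
        )
        manifest["surface"][repr(float(t))] = fname
        manifest["inlet_pressure"][repr(float(t))] = float(wall.inlet_pressure[it])
    if vol is not None:
        ns, nr, ntheta = vol.lattice_shape
        params = np.column_stack([vol.param_s, vol.param_r, vol.param_theta])
        for it, t in enumerate(vol.times):
            fname = f"vol_{it:04d}.vtk"
            data = {"velocity": vol.velocity[it], "params_srt": params}
            if vol.vorticity_analytic is not None:
                data["vorticity_analytic"] = vol.vorticity_analytic[it]
            write_structured_grid(outdir / fname, (ntheta, nr, ns), vol.points, data)
            manifest["volume"][repr(float(t))] = fname
    mpath = outdir / "series_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath


def read_field_series(manifest_path):
    """Read a series written by :func:`write_field_series`.

    Timesteps are sorted by their stated time regardless of manifest order;
    topology must match across timesteps; the "wss" array is mandatory on
    every surface file.
    """
    from .hemofields import VolumeFieldSeries, WallFieldSeries

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent

    surf_items = sorted(manifest["surface"].items(), key=lambda kv: float(kv[0]))
    times = np.array([float(t) for t, _ in surf_items])
    ref_pts = ref_tris = None
    wss_list, p_list = [], []
    for t, fname in surf_items:
        pts, tris, pdata = read_polydata(base / fname)
        if ref_pts is None:
            ref_pts, ref_tris = pts, tris
        elif pts.shape != ref_pts.shape or not np.array_equal(tris, ref_tris):
            raise FormatError(f"topology mismatch at timestep file {fname}")
        if "wss" not in pdata:
            raise FormatError(f"{fname}: required point array 'wss' is missing")
        if "pressure" not in pdata:
            raise FormatError(f"{fname}: required point array 'pressure' is missing")
        wss_list.append(pdata["wss"])
        p_list.append(pdata["pressure"])
    vertex_s = np.loadtxt(base / manifest["vertex_s_file"])
    inlet = np.array(
        [manifest["inlet_pressure"][t] for t, _ in surf_items], dtype=float
    )
    wall = WallFieldSeries(
        times=times,
        wss=np.stack(wss_list),
        pressure=np.stack(p_list),
        vertex_s=vertex_s,
        inlet_pressure=inlet,
        geom=None,
    )

    vol = None
    if manifest.get("volume"):
        vol_items = sorted(manifest["volume"].items(), key=lambda kv: float(kv[0]))
        vtimes = np.array([float(t) for t, _ in vol_items])
        vel_list, vort_list = [], []
        dims = pts0 = params = None
        for t, fname in vol_items:
            d, pts, pdata = read_structured_grid(base / fname)
            if dims is None:
                dims, pts0 = d, pts
                params = pdata["params_srt"]
            elif d != dims or pts.shape != pts0.shape:
                raise FormatError(f"topology mismatch at timestep file {fname}")
            if "velocity" not in pdata:
                raise FormatError(f"{fname}: required point array 'velocity' is missing")
            vel_list.append(pdata["velocity"])
            if "vorticity_analytic" in pdata:
                vort_list.append(pdata["vorticity_analytic"])
        ntheta, nr, ns = dims
        vol = VolumeFieldSeries(
            times=vtimes,
            points=pts0,
            param_s=params[:, 0],
            param_r=params[:, 1],
            param_theta=params[:, 2],
            lattice_shape=(ns, nr, ntheta),
            velocity=np.stack(vel_list),
            vorticity_analytic=np.stack(vort_list) if vort_list else None,
            geom=None,
        )
    return wall, vol


def write_index_maps(path, geom, maps) -> None:
    """Attach the index panel (and segment ids, if present) to one polydata file."""
    data = {name: arr for name, arr in maps.surface.items()}
    write_polydata(path, geom.vertices, geom.triangles, data)
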