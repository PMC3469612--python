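"""Format glue: meshes (OFF/OBJ, optional FreeSurfer), matrices, estimates.

All internal indices are 0-based; OFF/OBJ adapters convert at the boundary
where needed (both formats are 0-based for OFF and 1-based for OBJ faces).
Positions are mm, potentials volts.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np

from .geometry import TriMesh

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_freesurfer_surface",
    "HAVE_FREESURFER_READER",
    "read_matrix",
    "write_matrix",
    "save_estimate",
    "load_estimate",
    "write_provenance",
]

try:  # capability flag: FreeSurfer binary surfaces need nibabel
    import nibabel.freesurfer  # noqa: F401

    HAVE_FREESURFER_READER = True
except Exception:  # pragma: no cover
    HAVE_FREESURFER_READER = False


def read_mesh(path) -> TriMesh:
    """Read an OFF or Wavefront OBJ triangle mesh (by file suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".off":
        return _read_off(path)
    if path.suffix.lower() == ".obj":
        return _read_obj(path)
    raise ValueError(f"unsupported mesh format: {path.suffix}")


def write_mesh(mesh: TriMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".off":
        lines = ["OFF", f"{mesh.n_vertices} {mesh.n_faces} 0"]
        lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
        lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    elif path.suffix.lower() == ".obj":
        lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")
    path.write_text("\n".join(lines) + "\n")


def _read_off(path: Path) -> TriMesh:
    tokens = path.read_text().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    i = 4
    verts = np.array(tokens[i:i + 3 * nv], dtype=float).reshape(nv, 3)
    i += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[i])
        if k != 3:
            raise ValueError("only triangle faces supported")
        faces.append([int(t) for t in tokens[i + 1:i + 4]])
        i += 1 + k
    return TriMesh(verts, np.array(faces))


def _read_obj(path: Path) -> TriMesh:
    verts, faces = [], []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:4]]
            faces.append(idx)
    return TriMesh(np.array(verts), np.array(faces))


def read_freesurfer_surface(path) -> TriMesh:
    """Read a FreeSurfer binary surface (requires nibabel; read-only)."""
    if not HAVE_FREESURFER_READER:
        raise RuntimeError("FreeSurfer surface reading requires nibabel")
    import nibabel.freesurfer as fs

    verts, faces = fs.read_geometry(str(path))
    return TriMesh(np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64))


def read_matrix(path) -> np.ndarray:
    """Delimited-text or HDF5 (dataset 'data') matrix."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return f["data"][()]
    return np.loadtxt(path, ndmin=2)


def write_matrix(x: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=np.asarray(x))
    else:
        np.savetxt(path, np.asarray(x))


def save_estimate(values: np.ndarray, path, meta: dict | None = None) -> None:
    """Source estimate as HDF5 with recipe metadata attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("estimate", data=np.asarray(values))
        for k, v in (meta or {}).items():
            d.attrs[k] = v


def load_estimate(path):
    import h5py

    with h5py.File(path, "r") as f:
        d = f["estimate"]
        return d[()], {k: d.attrs[k] for k in d.attrs}


def write_provenance(path, parameters: dict) -> None:
    """Machine-readable record sufficient to re-run a command."""
    record = {
        "parameters": parameters,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    try:
        import scipy

        record["scipy"] = scipy.__version__
    except Exception:  # pragma: no cover
        pass
    Path(path).write_text(json.dumps(record, indent=1, default=str))
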