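"""Volume and mesh file round trips.

Volumes: NRRD (``.nrrd``) and MetaImage (``.mha``/``.mhd`` with LOCAL data).
Meshes: ASCII PLY and legacy ASCII VTK polydata.  Particle sets: plain
``x y z`` point files.

Only the small header subset actually produced by this package is parsed;
a missing spacing header is a hard error, never a silent default.  Grids
are stored index-fastest-first (Fortran order on disk), matching the
``world = origin + index * spacing`` convention of :mod:`shapecorr.volumes`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .volumes import BinaryVolume, TriangleMesh

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "write_vtk_polydata",
    "read_points",
    "write_points",
]


class FormatError(ValueError):
    """A file violates the supported format subset (e.g. no spacing header)."""


_NRRD_TYPES = {
    "uint8": np.uint8, "unsigned char": np.uint8, "uchar": np.uint8,
    "int16": np.int16, "short": np.int16,
    "uint16": np.uint16,
    "int32": np.int32, "int": np.int32,
    "float": np.float32, "double": np.float64,
}
_MET_TYPES = {
    "MET_UCHAR": np.uint8, "MET_CHAR": np.int8, "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16, "MET_INT": np.int32, "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}


def _binarize(arr: np.ndarray) -> np.ndarray:
    vals = np.unique(arr)
    if not np.all(np.isin(vals, [0, 1])):
        warnings.warn("non-binary grid read; thresholding at 0.5", stacklevel=3)
        return (arr > 0.5).astype(np.uint8)
    return arr.astype(np.uint8)


def write_volume(path: str | Path, v: BinaryVolume) -> Path:
    """Write a volume as NRRD or MetaImage, chosen by file extension."""
    path = Path(path)
    if path.suffix == ".nrrd":
        return _write_nrrd(path, v)
    if path.suffix in (".mha", ".mhd"):
        return _write_metaimage(path, v)
    raise FormatError(f"unsupported volume extension: {path.suffix}")


def read_volume(path: str | Path) -> BinaryVolume:
    path = Path(path)
    if path.suffix == ".nrrd":
        return _read_nrrd(path)
    if path.suffix in (".mha", ".mhd"):
        return _read_metaimage(path)
    raise FormatError(f"unsupported volume extension: {path.suffix}")


def _write_nrrd(path: Path, v: BinaryVolume) -> Path:
    g = np.ascontiguousarray(v.grid.astype(np.uint8))
    sd = " ".join(
        "({},{},{})".format(*(v.spacing[d] if i == d else 0.0 for i in range(3)))
        for d in range(3)
    )
    header = (
        "NRRD0004\n"
        "type: uint8\n"
        "dimension: 3\n"
        "space dimension: 3\n"
        f"sizes: {g.shape[0]} {g.shape[1]} {g.shape[2]}\n"
        f"space directions: {sd}\n"
        "space origin: ({},{},{})\n".format(*v.origin)
        + "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(g.tobytes(order="F"))
    return path


def _read_nrrd(path: Path) -> BinaryVolume:
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise FormatError(f"{path}: not a NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline().decode("ascii", "replace")
            if line in ("\n", "\r\n", ""):
                break
            if line.startswith("#") or ":" not in line:
                continue
            key, _, val = line.partition(":")
            fields[key.strip().lower()] = val.lstrip(" =").strip()
        data = fh.read()
    if "sizes" not in fields or "type" not in fields:
        raise FormatError(f"{path}: missing sizes/type header")
    sizes = tuple(int(x) for x in fields["sizes"].split())
    dtype = _NRRD_TYPES.get(fields["type"])
    if dtype is None:
        raise FormatError(f"{path}: unsupported type {fields['type']!r}")
    if "space directions" in fields:
        vecs = _parse_vectors(fields["space directions"])
        spacing = np.array([np.linalg.norm(v) for v in vecs])
    elif "spacings" in fields:
        spacing = np.array([float(x) for x in fields["spacings"].split()])
    else:
        raise FormatError(f"{path}: no spacing header (space directions/spacings)")
    origin = (
        _parse_vectors(fields["space origin"])[0]
        if "space origin" in fields
        else np.zeros(3)
    )
    if fields.get("encoding", "raw") == "ascii":
        arr = np.array(data.decode("ascii").split(), dtype=dtype)
    else:
        arr = np.frombuffer(data, dtype=dtype)
    if fields.get("endian", "little") == "big":
        arr = arr.byteswap()
    grid = arr.reshape(sizes, order="F")
    return BinaryVolume(_binarize(np.asarray(grid)), spacing, origin)


def _parse_vectors(text: str) -> list[np.ndarray]:
    out = []
    for chunk in text.replace("(", " ").split(")"):
        chunk = chunk.strip()
        if chunk and chunk.lower() != "none":
            out.append(np.array([float(x) for x in chunk.split(",")]))
    return out


def _write_metaimage(path: Path, v: BinaryVolume) -> Path:
    g = np.ascontiguousarray(v.grid.astype(np.uint8))
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        f"DimSize = {g.shape[0]} {g.shape[1]} {g.shape[2]}\n"
        "ElementSpacing = {} {} {}\n".format(*v.spacing)
        + "Offset = {} {} {}\n".format(*v.origin)
        + "ElementType = MET_UCHAR\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(g.tobytes(order="F"))
    return path


def _read_metaimage(path: Path) -> BinaryVolume:
    fields: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline().decode("ascii", "replace")
            if not line:
                raise FormatError(f"{path}: truncated MetaImage header")
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
            if key.strip() == "ElementDataFile":
                break
        data = fh.read()
    if "ElementSpacing" not in fields:
        raise FormatError(f"{path}: no ElementSpacing header")
    sizes = tuple(int(x) for x in fields["DimSize"].split())
    spacing = np.array([float(x) for x in fields["ElementSpacing"].split()])
    origin = np.array([float(x) for x in fields.get("Offset", "0 0 0").split()])
    dtype = _MET_TYPES.get(fields.get("ElementType", "MET_UCHAR"))
    if dtype is None:
        raise FormatError(f"{path}: unsupported ElementType")
    if fields["ElementDataFile"] != "LOCAL":
        raw = (path.parent / fields["ElementDataFile"]).read_bytes()
    else:
        raw = data
    arr = np.frombuffer(raw, dtype=dtype)
    if fields.get("BinaryDataByteOrderMSB", "False") == "True":
        arr = arr.byteswap()
    grid = arr.reshape(sizes, order="F")
    return BinaryVolume(_binarize(np.asarray(grid)), spacing, origin)


# ---------------------------------------------------------------- meshes


def write_mesh(path: str | Path, mesh: TriangleMesh) -> Path:
    path = Path(path)
    if path.suffix == ".ply":
        return _write_ply(path, mesh)
    if path.suffix == ".vtk":
        return write_vtk_polydata(path, mesh.vertices, faces=mesh.faces)
    raise FormatError(f"unsupported mesh extension: {path.suffix}")


def read_mesh(path: str | Path) -> TriangleMesh:
    path = Path(path)
    if path.suffix == ".ply":
        return _read_ply(path)
    if path.suffix == ".vtk":
        return _read_vtk_polydata(path)
    raise FormatError(f"unsupported mesh extension: {path.suffix}")


def _write_ply(path: Path, mesh: TriangleMesh) -> Path:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    return path


def _read_ply(path: Path) -> TriangleMesh:
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise FormatError(f"{path}: not a PLY file")
        nv = nf = 0
        for line in fh:
            t = line.split()
            if t[:2] == ["element", "vertex"]:
                nv = int(t[2])
            elif t[:2] == ["element", "face"]:
                nf = int(t[2])
            elif t[0] == "end_header":
                break
        verts = np.array(
            [[float(x) for x in fh.readline().split()[:3]] for _ in range(nv)]
        )
        faces = []
        for _ in range(nf):
            t = [int(x) for x in fh.readline().split()]
            if t[0] != 3:
                raise FormatError(f"{path}: non-triangle face")
            faces.append(t[1:4])
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


def write_vtk_polydata(
    path: str | Path,
    points: np.ndarray,
    faces: np.ndarray | None = None,
    vectors: np.ndarray | None = None,
    vectors_name: str = "arrows",
) -> Path:
    """Legacy ASCII VTK polydata; ``vectors`` become point-data for glyphs."""
    path = Path(path)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nshapecorr polydata\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        if faces is not None and len(faces):
            faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
            fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        else:
            fh.write(f"VERTICES {len(pts)} {2 * len(pts)}\n")
            for i in range(len(pts)):
                fh.write(f"1 {i}\n")
        if vectors is not None:
            vec = np.asarray(vectors, dtype=float).reshape(-1, 3)
            fh.write(f"POINT_DATA {len(pts)}\n")
            fh.write(f"VECTORS {vectors_name} double\n")
            for w in vec:
                fh.write(f"{w[0]:.12g} {w[1]:.12g} {w[2]:.12g}\n")
    return path


def _read_vtk_polydata(path: Path) -> TriangleMesh:
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[4:]:
        tokens.extend(line.split())
    verts = np.zeros((0, 3))
    faces = np.zeros((0, 3), dtype=np.int64)
    i = 0
    while i < len(tokens):
        t = tokens[i]
        if t == "POINTS":
            n = int(tokens[i + 1])
            vals = [float(x) for x in tokens[i + 3 : i + 3 + 3 * n]]
            verts = np.array(vals).reshape(n, 3)
            i += 3 + 3 * n
        elif t == "POLYGONS":
            n = int(tokens[i + 1])
            total = int(tokens[i + 2])
            vals = [int(x) for x in tokens[i + 3 : i + 3 + total]]
            out = []
            j = 0
            for _ in range(n):
                cnt = vals[j]
                out.append(vals[j + 1 : j + 1 + cnt])
                j += 1 + cnt
            faces = np.array(out, dtype=np.int64)
            i += 3 + total
        else:
            i += 1
    return TriangleMesh(verts, faces)


# ---------------------------------------------------------------- points


def write_points(path: str | Path, points: np.ndarray) -> Path:
    """Plain-text point file, one ``x y z`` per line; line index = correspondence id."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    np.savetxt(path, pts, fmt="%.12g")
    return Path(path)


def read_points(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=float).reshape(-1, 3)
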