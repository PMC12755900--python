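"""Volumes, meshes and particle tables: domain containers and file formats.

All physical quantities are held in nanometres internally; Ångström appears
only at I/O boundaries (MRC headers store cell dimensions in Å, STAR tables
store coordinates in voxels).

Coordinate convention: voxel index ``i`` maps to physical position
``origin + i * voxel_size`` (voxel-centre, 0-based).  Meshes and particles
live in the same frame, and volume grids are indexed ``(x, y, z)`` with x the
fastest axis of the on-disk MRC layout.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityVolume",
    "SurfaceMesh",
    "ParticleSet",
    "read_density_volume",
    "write_density_volume",
    "read_surface_mesh",
    "write_surface_mesh",
    "compute_triangle_geometry",
    "read_particles",
    "write_particles",
    "write_table",
]

HEADS_BRIGHT = "heads_bright"
HEADS_DARK = "heads_dark"


@dataclass
class DensityVolume:
    """3D scalar grid with physical voxel size.

    grid : (nx, ny, nz) float array, x fastest on disk
    voxel_size : nm per voxel, isotropic
    origin : nm position of the centre of voxel (0, 0, 0)
    contrast : 'heads_bright' if head-group density is a maximum,
        'heads_dark' if density is inverted (samplers negate it).
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    contrast: str = HEADS_BRIGHT

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3D with every axis >= 2")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        if self.contrast not in (HEADS_BRIGHT, HEADS_DARK):
            raise ValueError(f"unknown contrast {self.contrast!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def physical_max(self) -> np.ndarray:
        return self.origin + (np.array(self.grid.shape) - 1) * self.voxel_size


@dataclass
class SurfaceMesh:
    """Triangulated membrane mid-surface with per-triangle attributes."""

    vertices: np.ndarray                   # (nv, 3) nm
    triangles: np.ndarray                  # (nt, 3) int
    label: str = ""
    normals: np.ndarray | None = None      # (nt, 3) unit vectors
    centroids: np.ndarray | None = None    # (nt, 3) nm
    areas: np.ndarray | None = None        # (nt,) nm^2
    valid: np.ndarray | None = None        # (nt,) bool, False for degenerate
    attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index exceeds vertex count")
        for name, col in self.attrs.items():
            if len(col) != len(self.triangles):
                raise ValueError(
                    f"attribute {name!r} has {len(col)} entries for "
                    f"{len(self.triangles)} triangles"
                )

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def set_attr(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values)
        if len(values) != self.n_triangles:
            raise ValueError("attribute length must equal triangle count")
        self.attrs[name] = values


@dataclass
class ParticleSet:
    """Point particles (nm frame shared with volume/mesh)."""

    ids: np.ndarray
    centers: np.ndarray                    # (n, 3) nm
    orientations: np.ndarray | None = None  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("particle ids must be unique")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("particle centers must be finite")

    def __len__(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# MRC (2014 dialect, mode 2 float)
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_density_volume(path, voxel_size_nm: float | None = None,
                        contrast: str = HEADS_BRIGHT) -> DensityVolume:
    """Read an MRC volume; header pixel size (Å) is converted to nm.

    A missing or zero header pixel size raises unless ``voxel_size_nm``
    explicitly overrides it.
    """
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(
                f"truncated MRC file {path}: header ends at byte {len(header)}, "
                "expected 1024"
            )
        nx, ny, nz, mode = struct.unpack("<4i", header[0:16])
        mx, my, mz = struct.unpack("<3i", header[28:40])
        xlen, ylen, zlen = struct.unpack("<3f", header[40:52])
        mapc, mapr, maps = struct.unpack("<3i", header[64:76])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        ox, oy, oz = struct.unpack("<3f", header[196:208])
        if mode not in _MRC_MODES:
            raise ValueError(f"unsupported MRC mode {mode}")
        if (mapc, mapr, maps) not in ((1, 2, 3), (0, 0, 0)):
            raise ValueError(f"unsupported axis order mapc,mapr,maps={mapc},{mapr},{maps}")
        if voxel_size_nm is None:
            if mx <= 0 or xlen <= 0:
                raise ValueError(
                    "MRC header has no usable pixel size; pass voxel_size_nm "
                    "to override explicitly"
                )
            voxel_size_nm = (xlen / mx) / 10.0  # Å -> nm
        dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
        fh.seek(1024 + nsymbt)
        raw = fh.read()
        expected = nx * ny * nz * dtype.itemsize
        if len(raw) < expected:
            raise ValueError(
                f"truncated MRC file {path}: data ends at byte "
                f"{1024 + nsymbt + len(raw)}, expected {1024 + nsymbt + expected}"
            )
        data = np.frombuffer(raw[:expected], dtype=dtype).reshape(nz, ny, nx)
    grid = np.ascontiguousarray(data.transpose(2, 1, 0)).astype(np.float64)
    origin = np.array([ox, oy, oz], dtype=np.float64) / 10.0
    return DensityVolume(grid, float(voxel_size_nm), origin, contrast)


def write_density_volume(vol: DensityVolume, path) -> None:
    """Write mode-2 (float32) MRC with pixel size and origin in Å."""
    nx, ny, nz = vol.grid.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    vs_ang = vol.voxel_size * 10.0
    struct.pack_into("<3f", header, 40, nx * vs_ang, ny * vs_ang, nz * vs_ang)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(vol.grid.min()),
                     float(vol.grid.max()), float(vol.grid.mean()))
    struct.pack_into("<3f", header, 196, *(vol.origin * 10.0))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(vol.grid.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(
            vol.grid.transpose(2, 1, 0), dtype="<f4").tobytes())


# ---------------------------------------------------------------------------
# PLY meshes with per-triangle attributes
# ---------------------------------------------------------------------------

def write_surface_mesh(mesh: SurfaceMesh, path) -> None:
    """Binary little-endian PLY; per-triangle attributes become face
    properties (float64/int32), string columns are stored as int codes with
    the category list in a header comment."""
    nv, nt = len(mesh.vertices), mesh.n_triangles
    prop_lines, cols, comments = [], [], []
    for name, col in mesh.attrs.items():
        col = np.asarray(col)
        if col.dtype.kind in "US":
            cats, codes = np.unique(col, return_inverse=True)
            comments.append(
                f"comment categories {name} {json.dumps(list(map(str, cats)))}")
            prop_lines.append(f"property int {name}")
            cols.append((name, codes.astype("<i4")))
        elif col.dtype.kind in "iub":
            prop_lines.append(f"property int {name}")
            cols.append((name, col.astype("<i4")))
        else:
            prop_lines.append(f"property double {name}")
            cols.append((name, col.astype("<f8")))
    header = (
        ["ply", "format binary_little_endian 1.0",
         f"comment label {mesh.label}"]
        + comments
        + [f"element vertex {nv}",
           "property double x", "property double y", "property double z",
           f"element face {nt}",
           "property list uchar int vertex_indices"]
        + prop_lines
        + ["end_header"]
    )
    face_dtype = [("n", "u1"), ("v", "<i4", (3,))] + [
        (name, arr.dtype) for name, arr in cols]
    faces = np.empty(nt, dtype=face_dtype)
    faces["n"] = 3
    faces["v"] = mesh.triangles.astype("<i4")
    for name, arr in cols:
        faces[name] = arr
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(mesh.vertices.astype("<f8").tobytes())
        fh.write(faces.tobytes())


def _ply_scalar_dtype(word: str) -> np.dtype:
    table = {"char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
             "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
             "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
             "float": "f4", "float32": "f4", "double": "f8", "float64": "f8"}
    return np.dtype("<" + table[word])


def read_surface_mesh(path) -> SurfaceMesh:
    """Read PLY (binary little-endian or ascii) with per-face attributes."""
    with open(path, "rb") as fh:
        data = fh.read()
    if not data.startswith(b"ply"):
        raise ValueError(f"{path} is not a PLY file")
    end = data.index(b"end_header\n") + len(b"end_header\n")
    lines = data[:end].decode("ascii", "replace").splitlines()
    fmt, label, categories = None, "", {}
    elements: list[tuple[str, int, list]] = []
    for ln in lines[1:]:
        parts = ln.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "comment" and len(parts) >= 2 and parts[1] == "label":
            label = " ".join(parts[2:])
        elif parts[0] == "comment" and len(parts) >= 4 and parts[1] == "categories":
            categories[parts[2]] = json.loads(" ".join(parts[3:]))
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if parts[1] == "list":
                elements[-1][2].append(("list", parts[2], parts[3], parts[4]))
            else:
                elements[-1][2].append(("scalar", parts[1], parts[2]))
    if fmt not in ("binary_little_endian", "ascii"):
        raise ValueError(f"unsupported PLY format {fmt!r}")

    vertices = triangles = None
    face_attrs: dict[str, np.ndarray] = {}
    if fmt == "binary_little_endian":
        buf = data[end:]
        off = 0
        for name, count, props in elements:
            if name == "vertex":
                dt = np.dtype([(p[2], _ply_scalar_dtype(p[1])) for p in props])
                arr = np.frombuffer(buf, dt, count, off)
                off += dt.itemsize * count
                vertices = np.column_stack([arr["x"], arr["y"], arr["z"]]).astype(float)
            elif name == "face":
                if props[0][0] != "list":
                    raise ValueError("face element must start with a list property")
                fields = [("n", _ply_scalar_dtype(props[0][1])),
                          ("v", _ply_scalar_dtype(props[0][2]), (3,))]
                fields += [(p[2], _ply_scalar_dtype(p[1])) for p in props[1:]]
                dt = np.dtype(fields)
                if off + dt.itemsize * count > len(buf):
                    raise ValueError(
                        "face records do not match a pure-triangle layout "
                        "(non-triangular faces are not supported)")
                arr = np.frombuffer(buf, dt, count, off)
                off += dt.itemsize * count
                if count and not np.all(arr["n"] == 3):
                    raise ValueError("non-triangular faces are not supported")
                triangles = arr["v"].astype(np.int64)
                for p in props[1:]:
                    face_attrs[p[2]] = np.array(arr[p[2]])
            else:  # skip unknown fixed-size element
                dt = np.dtype([(p[2], _ply_scalar_dtype(p[1])) for p in props])
                off += dt.itemsize * count
    else:
        rows = data[end:].decode("ascii").split("\n")
        cursor = 0
        for name, count, props in elements:
            chunk, cursor = rows[cursor:cursor + count], cursor + count
            if name == "vertex":
                vals = np.array([r.split()[:3] for r in chunk], dtype=float)
                vertices = vals
            elif name == "face":
                tris, extra = [], {p[2]: [] for p in props[1:]}
                for r in chunk:
                    toks = r.split()
                    n = int(toks[0])
                    if n != 3:
                        raise ValueError("non-triangular faces are not supported")
                    tris.append([int(t) for t in toks[1:4]])
                    for p, tok in zip(props[1:], toks[4:]):
                        extra[p[2]].append(float(tok))
                triangles = np.array(tris, dtype=np.int64).reshape(-1, 3)
                for p in props[1:]:
                    kind = _ply_scalar_dtype(p[1]).kind
                    arr = np.array(extra[p[2]])
                    face_attrs[p[2]] = arr.astype(int) if kind in "iu" else arr
    if vertices is None or triangles is None:
        raise ValueError("PLY file lacks vertex or face element")
    for name, cats in categories.items():
        if name in face_attrs:
            face_attrs[name] = np.array(cats, dtype=object)[
                face_attrs[name].astype(int)].astype(str)
    return SurfaceMesh(vertices, triangles, label=label, attrs=face_attrs)


# ---------------------------------------------------------------------------
# Triangle geometry
# ---------------------------------------------------------------------------

def compute_triangle_geometry(mesh: SurfaceMesh) -> SurfaceMesh:
    """Fill centroids (vertex mean), areas (cross product) and unit normals
    consistent with the stored winding.  Zero-area triangles are flagged
    invalid, not removed, so attribute alignment is preserved."""
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    mesh.centroids = (a + b + c) / 3.0
    cross = np.cross(b - a, c - a)
    norm = np.linalg.norm(cross, axis=1)
    mesh.areas = 0.5 * norm
    mesh.valid = norm > 1e-12
    normals = np.zeros_like(cross)
    nz = mesh.valid
    normals[nz] = cross[nz] / norm[nz, None]
    mesh.normals = normals
    return mesh


# ---------------------------------------------------------------------------
# STAR particle tables
# ---------------------------------------------------------------------------

def _parse_star_loop(path) -> tuple[list[str], list[list[str]]]:
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = header_done = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                if header_done and rows:
                    break
                continue
            if line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop, header_done = True, False
                columns, rows = [], []
                continue
            if in_loop and line.startswith("_"):
                if header_done:
                    break
                columns.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and columns:
                header_done = True
                rows.append(line.split())
    return columns, rows


def _find_column(columns: list[str], suffix: str) -> int | None:
    for i, c in enumerate(columns):
        if c.lower().endswith(suffix.lower()):
            return i
    return None


def read_particles(path, voxel_size_nm: float) -> ParticleSet:
    """Read particle coordinates (voxel units) from a STAR loop table and
    scale them into the nm frame.  Euler angle columns (rot/tilt/psi, ZYZ,
    degrees), when present, are converted to unit direction vectors: the
    image of the z axis under the inverse particle rotation."""
    columns, rows = _parse_star_loop(path)
    if not rows:
        return ParticleSet(np.array([], dtype=int), np.zeros((0, 3)))
    ix = _find_column(columns, "CoordinateX")
    iy = _find_column(columns, "CoordinateY")
    iz = _find_column(columns, "CoordinateZ")
    if None in (ix, iy, iz):
        raise ValueError(
            f"STAR file {path} lacks coordinate columns; found: {columns}")
    coords = np.array([[r[ix], r[iy], r[iz]] for r in rows], dtype=float)
    centers = coords * voxel_size_nm
    orientations = None
    ir = _find_column(columns, "AngleRot")
    it = _find_column(columns, "AngleTilt")
    ip = _find_column(columns, "AnglePsi")
    if None not in (ir, it, ip):
        from scipy.spatial.transform import Rotation
        ang = np.array([[r[ir], r[it], r[ip]] for r in rows], dtype=float)
        rot = Rotation.from_euler("ZYZ", ang, degrees=True)
        orientations = rot.inv().apply(np.array([0.0, 0.0, 1.0]))
    ids = np.arange(len(rows))
    return ParticleSet(ids, centers, orientations)


def write_particles(particles: ParticleSet, path, voxel_size_nm: float) -> None:
    with open(path, "w") as fh:
        fh.write("data_particles\n\nloop_\n")
        fh.write("_rlnCoordinateX #1\n_rlnCoordinateY #2\n_rlnCoordinateZ #3\n")
        for c in particles.centers / voxel_size_nm:
            fh.write(f"{c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")


def write_table(df, path, config: dict | None = None) -> None:
    """CSV with a commented metadata header (config snapshot + version)."""
    from . import __version__
    with open(path, "w") as fh:
        fh.write(f"# memthick {__version__}\n")
        fh.write(f"# config {json.dumps(config or {}, sort_keys=True)}\n")
        df.to_csv(fh, index=False)
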