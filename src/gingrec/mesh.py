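"""Triangle meshes, STL I/O, local frames and planar cross-sections.

Coordinates are millimetres throughout.  The per-tooth local frame follows
the clinical convention: z = tooth long axis (coronal is +z), x = mesio-distal,
y = bucco-oral with +y pointing buccally.  Cross-sections are cut with a plane
normal to x so the section plane contains the long axis.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateSectionError,
    EmptyMeshError,
    MeshFormatError,
    NoIntersectionError,
)

_MERGE_TOL = 1e-6  # vertex merge tolerance, mm
_CHAIN_TOL = 1e-6  # segment endpoint chaining tolerance, mm


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangleMesh:
    """An indexed triangle surface in mm."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(f) < 1:
            raise EmptyMeshError("mesh has no faces")
        if f.min(initial=0) < 0 or (len(v) and f.max(initial=-1) >= len(v)):
            raise ValueError("face index out of range")
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ValueError("face with repeated vertex index")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def edges(self) -> np.ndarray:
        """All face edges as (3m, 2) index pairs (not deduplicated)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def area(self) -> float:
        v = self.vertices[self.faces]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal per-tooth coordinate frame."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64).reshape(3))
        self.validate()

    def validate(self, tol: float = 1e-9) -> None:
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=tol):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("frame is left-handed")

    @property
    def rotation(self) -> np.ndarray:
        """Rows are the frame axes; maps world deltas into frame coords."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])

    @classmethod
    def identity(cls) -> "LocalFrame":
        return cls(np.zeros(3), np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "x_axis": self.x_axis.tolist(),
            "y_axis": self.y_axis.tolist(),
            "z_axis": self.z_axis.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LocalFrame":
        return cls(d["origin"], d["x_axis"], d["y_axis"], d["z_axis"])


@dataclass
class CrossSectionPolyline:
    """Ordered planar section chain: columns are (y, z) in mm, coronal first."""

    points: np.ndarray  # (n, 2), columns y (bucco-oral), z (corono-apical)
    plane_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    plane_normal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    site_id: str = "site"
    closed: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.points) < 3:
            raise DegenerateSectionError(f"{self.site_id}: section has < 3 points")
        gaps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(gaps <= 1e-9):
            raise ValueError("consecutive duplicate points in section")

    def length(self) -> float:
        """Chord-sum length; includes the closing edge for closed loops."""
        gaps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        total = float(gaps.sum())
        if self.closed:
            total += float(np.linalg.norm(self.points[-1] - self.points[0]))
        return total

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("s_index,y_mm,z_mm\n")
            for i, (y, z) in enumerate(self.points):
                fh.write(f"{i},{y:.17g},{z:.17g}\n")

    @classmethod
    def from_csv(cls, path, site_id: str | None = None) -> "CrossSectionPolyline":
        data = np.loadtxt(path, delimiter=",", skiprows=1, usecols=(1, 2), ndmin=2)
        return cls(points=data, site_id=site_id or Path(path).stem)

    def to_txt(self, path) -> None:
        np.savetxt(path, self.points, fmt="%.17g")


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def _merge_vertices(tri_points: np.ndarray, tol: float = _MERGE_TOL):
    """Deduplicate stacked per-triangle vertices within tol; drop degenerate faces."""
    keys = np.round(tri_points / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    vertices = tri_points[first]
    faces = inverse.reshape(-1, 3)
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return vertices, faces[ok]


def read_mesh(path) -> TriangleMesh:
    """Read a binary or ASCII STL file; duplicate vertices are merged (1e-6 mm)."""
    path = Path(path)
    if not path.is_file():
        raise MeshFormatError(f"no such file: {path}")
    raw = path.read_bytes()
    if len(raw) < 15:
        raise MeshFormatError(f"{path}: too short to be an STL file")
    tri = None
    if len(raw) >= 84:
        (n_tri,) = struct.unpack("<I", raw[80:84])
        if len(raw) == 84 + 50 * n_tri:
            if n_tri == 0:
                raise EmptyMeshError(f"{path}: binary STL with zero facets")
            tri = _parse_binary(raw, n_tri)
    if tri is None and raw[:5].lower() == b"solid":
        tri = _parse_ascii(raw, path)
    if tri is None:
        raise MeshFormatError(f"{path}: not a recognizable binary or ASCII STL")
    if len(tri) == 0:
        raise EmptyMeshError(f"{path}: STL contains zero facets")
    vertices, faces = _merge_vertices(tri.reshape(-1, 3))
    if len(faces) == 0:
        raise EmptyMeshError(f"{path}: all facets degenerate after vertex merge")
    return TriangleMesh(vertices, faces)


def _parse_binary(raw: bytes, n_tri: int) -> np.ndarray:
    rec = np.dtype([("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")])
    body = np.frombuffer(raw, dtype=rec, count=n_tri, offset=84)
    return body["verts"].astype(np.float64)


def _parse_ascii(raw: bytes, path) -> np.ndarray:
    try:
        text = raw.decode("ascii", errors="strict")
    except UnicodeDecodeError as exc:
        raise MeshFormatError(f"{path}: ASCII STL with non-ASCII bytes") from exc
    coords = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) == 4 and parts[0] == "vertex":
            try:
                coords.append([float(p) for p in parts[1:]])
            except ValueError as exc:
                raise MeshFormatError(f"{path}: bad vertex line {line!r}") from exc
    if len(coords) % 3 != 0:
        raise MeshFormatError(f"{path}: truncated ASCII STL ({len(coords)} vertex lines)")
    return np.asarray(coords, dtype=np.float64).reshape(-1, 3, 3)


def write_mesh(mesh: TriangleMesh, path, binary: bool = True) -> None:
    """Write STL (binary by default); used for fixtures and synthetic ribbons."""
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norms, out=np.zeros_like(normals), where=norms > 0)
    path = Path(path)
    if binary:
        rec = np.dtype([("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")])
        body = np.zeros(len(tri), dtype=rec)
        body["normal"] = normals
        body["verts"] = tri
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", len(tri)))
            fh.write(body.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid gingrec\n")
            for nrm, t in zip(normals, tri):
                fh.write(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid gingrec\n")


# ---------------------------------------------------------------------------
# refinement and frames
# ---------------------------------------------------------------------------


def refine_mesh(mesh: TriangleMesh, min_edge: float, max_passes: int = 10) -> TriangleMesh:
    """Longest-edge midpoint bisection until every edge is <= min_edge.

    Geometry is unchanged (new vertices are edge midpoints), mirroring a
    resolution-only "refine" step.  Stops after max_passes even if some edges
    still exceed the bound.
    """
    if min_edge <= 0:
        raise ValueError("min_edge must be positive")
    current = mesh
    for _ in range(max_passes):
        v, f = current.vertices, current.faces
        tri = v[f]
        side = np.stack(
            [
                np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
                np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
                np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
            ],
            axis=1,
        )
        needs = side.max(axis=1) > min_edge
        if not needs.any():
            return current
        keep = f[~needs]
        split_faces = f[needs]
        longest = side[needs].argmax(axis=1)
        # edge k of face (a,b,c): k=0 -> (a,b), k=1 -> (b,c), k=2 -> (c,a)
        ia = split_faces[np.arange(len(split_faces)), longest]
        ib = split_faces[np.arange(len(split_faces)), (longest + 1) % 3]
        ic = split_faces[np.arange(len(split_faces)), (longest + 2) % 3]
        mid = 0.5 * (v[ia] + v[ib])
        mid_idx = len(v) + np.arange(len(mid))
        new_faces = np.concatenate(
            [
                keep,
                np.stack([ia, mid_idx, ic], axis=1),
                np.stack([mid_idx, ib, ic], axis=1),
            ]
        )
        merged_v, merged_f = _merge_vertices(np.concatenate([v, mid])[new_faces].reshape(-1, 3))
        current = TriangleMesh(merged_v, merged_f)
    return current


def apply_frame(mesh: TriangleMesh, frame: LocalFrame) -> TriangleMesh:
    """Express mesh vertices in the local frame (rigid transform)."""
    frame.validate()
    local = (mesh.vertices - frame.origin) @ frame.rotation.T
    return TriangleMesh(local, mesh.faces.copy())


# ---------------------------------------------------------------------------
# cross-section extraction
# ---------------------------------------------------------------------------


def extract_cross_section(
    mesh: TriangleMesh,
    plane_x_offset: float = 0.0,
    site_id: str = "site",
    restrict_buccal: bool = True,
) -> CrossSectionPolyline:
    """Slice a mesh (already in its local frame) with the plane x = offset.

    Intersection segments are chained into polylines; the chain with the
    greatest z-extent wins.  A closed loop is cut at its extreme-z points and
    the buccal sub-chain (larger mean y) kept, unless restrict_buccal=False.
    Points are ordered coronal -> apical (z decreasing overall).
    """
    d = mesh.vertices[:, 0] - plane_x_offset
    d = np.where(d == 0.0, 1e-12, d)  # nudge on-plane vertices off the plane
    fd = d[mesh.faces]
    crossing = (fd.min(axis=1) < 0) & (fd.max(axis=1) > 0)
    if not crossing.any():
        raise NoIntersectionError(f"{site_id}: plane x={plane_x_offset} misses the mesh")

    segments = []
    tri = mesh.vertices[mesh.faces[crossing]][:, :, 1:]  # keep (y, z)
    tfd = fd[crossing]
    for verts2d, dist in zip(tri, tfd):
        pts = []
        for i in range(3):
            j = (i + 1) % 3
            if dist[i] * dist[j] < 0:
                t = dist[i] / (dist[i] - dist[j])
                pts.append(verts2d[i] + t * (verts2d[j] - verts2d[i]))
        if len(pts) == 2 and np.linalg.norm(pts[0] - pts[1]) > _CHAIN_TOL:
            segments.append((pts[0], pts[1]))
    if not segments:
        raise DegenerateSectionError(f"{site_id}: no usable intersection segments")

    chains = _chain_segments(segments)
    spans = [pts[:, 1].max() - pts[:, 1].min() for pts, _ in chains]
    points, closed = chains[int(np.argmax(spans))]

    if closed and restrict_buccal:
        points = _cut_loop_buccal(points)
        closed = False
    if points[0, 1] < points[-1, 1]:
        points = points[::-1]
    if len(points) < 3:
        raise DegenerateSectionError(f"{site_id}: section chain has < 3 points")
    return CrossSectionPolyline(
        points=points,
        plane_origin=np.array([plane_x_offset, 0.0, 0.0]),
        plane_normal=np.array([1.0, 0.0, 0.0]),
        site_id=site_id,
        closed=closed,
    )


def _chain_segments(segments) -> list[tuple[np.ndarray, bool]]:
    """Chain 2D segments into (points, closed) polylines via endpoint matching."""
    nodes: dict[tuple, int] = {}
    coords: list[np.ndarray] = []

    def node_id(p) -> int:
        key = tuple(np.round(p / _CHAIN_TOL).astype(np.int64))
        if key not in nodes:
            nodes[key] = len(coords)
            coords.append(np.asarray(p, dtype=np.float64))
        return nodes[key]

    adjacency: dict[int, list[int]] = {}
    seen_edges = set()
    for a, b in segments:
        ia, ib = node_id(a), node_id(b)
        if ia == ib or (min(ia, ib), max(ia, ib)) in seen_edges:
            continue
        seen_edges.add((min(ia, ib), max(ia, ib)))
        adjacency.setdefault(ia, []).append(ib)
        adjacency.setdefault(ib, []).append(ia)

    visited = set()
    chains = []
    # open chains first (start from degree-1 nodes), then remaining cycles
    starts = [n for n, nb in adjacency.items() if len(nb) == 1]
    starts += [n for n in adjacency if n not in starts]
    for start in starts:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        prev = None
        current = start
        while True:
            nxt = [n for n in adjacency[current] if n != prev and n not in visited]
            if not nxt:
                closed = start in adjacency[current] and len(path) > 2
                break
            prev, current = current, nxt[0]
            visited.add(current)
            path.append(current)
        chains.append((np.array([coords[i] for i in path]), closed))
    return chains


def _cut_loop_buccal(points: np.ndarray) -> np.ndarray:
    """Cut a closed loop at its extreme-z nodes, keep the larger-mean-y arc."""
    i_top = int(points[:, 1].argmax())
    i_bot = int(points[:, 1].argmin())
    lo, hi = sorted((i_top, i_bot))
    arc1 = points[lo : hi + 1]
    arc2 = np.concatenate([points[hi:], points[: lo + 1]])
    return arc1 if arc1[:, 0].mean() >= arc2[:, 0].mean() else arc2


# ---------------------------------------------------------------------------
# site configuration
# ---------------------------------------------------------------------------


def load_site_config(path) -> dict:
    """Load a YAML/JSON site table: site_id -> {mesh, frame, plane_x_offset}."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
    sites = {}
    for site_id, entry in doc.get("sites", doc).items():
        frame = LocalFrame.from_dict(entry["frame"]) if "frame" in entry else LocalFrame.identity()
        sites[site_id] = {
            "mesh": entry.get("mesh"),
            "frame": frame,
            "plane_x_offset": float(entry.get("plane_x_offset", 0.0)),
        }
    return sites


# small analytic meshes, used by tests and the synthetic ribbon writer


def make_box(size: float = 1.0, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned cube with 12 facets."""
    c = np.asarray(center, dtype=np.float64)
    h = size / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-h, h) for sy in (-h, h) for sz in (-h, h)]
    ) + c
    quads = [
        (0, 1, 3, 2), (4, 6, 7, 5), (0, 4, 5, 1),
        (2, 3, 7, 6), (0, 2, 6, 4), (1, 5, 7, 3),
    ]
    faces = []
    for a, b, cc, dd in quads:
        faces += [(a, b, cc), (a, cc, dd)]
    return TriangleMesh(corners, np.array(faces))


def make_sphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Icosphere: subdivided icosahedron with vertices projected to the sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        tri = verts[faces]
        mids = 0.5 * (tri + np.roll(tri, -1, axis=1))  # midpoints of (01,12,20)
        mids /= np.linalg.norm(mids, axis=2, keepdims=True)
        stacked = np.concatenate([tri, mids], axis=1).reshape(-1, 3)
        n = len(faces)
        base = np.arange(n) * 6
        a, b, c, mab, mbc, mca = (base, base + 1, base + 2, base + 3, base + 4, base + 5)
        faces = np.concatenate(
            [
                np.stack([a, mab, mca], axis=1),
                np.stack([mab, b, mbc], axis=1),
                np.stack([mca, mbc, c], axis=1),
                np.stack([mab, mbc, mca], axis=1),
            ]
        )
        verts, faces = _merge_vertices(stacked[faces].reshape(-1, 3))
    return TriangleMesh(verts * radius, faces)
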