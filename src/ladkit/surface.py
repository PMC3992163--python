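"""Molecular surface meshing and vertex-to-atom association.

The surface is the isosurface of the signed distance field of the union of
probe-inflated van der Waals spheres around the backbone atoms, extracted by
marching cubes on a regular grid.  This is the distance-transform family of
solvent-surface constructions: every atom contributes a sphere of radius
``r_vdw + probe`` and the zero level set of ``min_a(|x - c_a| - R_a)`` is
triangulated.  An import path for externally computed MSMS meshes is
provided for users who want the exact solvent-excluded surface.

Each mesh vertex is owned by its closest backbone atom; a residue is a
*surface residue* if at least one vertex is owned by one of its atoms.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .structure import ATOM_ORDER, BackboneStructure

#: Fixed van der Waals radii in Å (united backbone atoms; CA is carbon).
VDW_RADII = {"N": 1.55, "CA": 1.70, "C": 1.70, "O": 1.52}

DEFAULT_PROBE_RADIUS = 1.5  # water probe, Å
DEFAULT_GRID_RESOLUTION = 0.7  # Å
DEFAULT_FACE_FRACTION = 0.15  # keep 15% of faces when simplifying


class MeshingError(RuntimeError):
    pass


@dataclass
class TriMesh:
    """A triangulated surface: ``vertices`` (n, 3) in Å, ``faces`` (m, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise ValueError("degenerate faces present")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, shape (e, 2), sorted pairs."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_graph(self):
        """Sparse symmetric adjacency weighted by Euclidean edge length."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        g = coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
        return g.tocsr()

    def vertex_components(self) -> np.ndarray:
        """Connected-component label per vertex."""
        _, labels = connected_components(self.edge_graph(), directed=False)
        return labels

    def n_components(self) -> int:
        n, _ = connected_components(self.edge_graph(), directed=False)
        return int(n)

    def area(self) -> float:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class VertexAssociation:
    """Partition of mesh vertices over backbone atoms.

    ``owner[v] = (residue seq_pos, atom tag)`` for every vertex ``v``;
    ``atom_vertices`` is the exact inverse map.
    """

    owner: dict[int, tuple[int, str]]
    atom_vertices: dict[tuple[int, str], list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.atom_vertices:
            inv: dict[tuple[int, str], list[int]] = {}
            for v, key in self.owner.items():
                inv.setdefault(key, []).append(v)
            self.atom_vertices = {k: sorted(v) for k, v in inv.items()}

    def residue_vertices(self, seq_pos: int) -> list[int]:
        out: list[int] = []
        for (pos, _tag), verts in self.atom_vertices.items():
            if pos == seq_pos:
                out.extend(verts)
        return sorted(out)


def atom_radii(structure: BackboneStructure, probe_radius: float) -> np.ndarray:
    tags = [tag for _, tag in structure.atom_index()]
    return np.array([VDW_RADII[t] + probe_radius for t in tags])


def build_surface(
    structure: BackboneStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    grid_resolution: float = DEFAULT_GRID_RESOLUTION,
) -> TriMesh:
    """Triangulate the probe-inflated surface of the backbone atoms.

    The signed distance to the union of inflated spheres is sampled on a
    regular grid with spacing ``grid_resolution`` and the zero isosurface is
    extracted with marching cubes.  The result is a closed surface (or
    several closed components if atom clusters are far apart) enclosing
    every atom.

    Parameters
    ----------
    probe_radius:
        Solvent probe radius added to each van der Waals radius, Å.
    grid_resolution:
        Grid spacing in Å; smaller values give denser, more accurate meshes.
    """
    if len(structure) == 0:
        raise MeshingError("empty structure")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    centers = structure.all_coords()
    radii = atom_radii(structure, probe_radius)
    h = float(grid_resolution)
    pad = radii.max() + 2.5 * h
    lo = centers.min(axis=0) - pad
    hi = centers.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int) + 1, 8)

    # signed distance field, updated locally around each atom
    field_arr = np.full(shape, np.inf, dtype=np.float64)
    axes = [lo[k] + h * np.arange(shape[k]) for k in range(3)]
    for c, r in zip(centers, radii):
        margin = r + 2.0 * h
        idx_lo = np.maximum(((c - margin - lo) / h).astype(int), 0)
        idx_hi = np.minimum(((c + margin - lo) / h).astype(int) + 2, shape)
        sub = [axes[k][idx_lo[k]:idx_hi[k]] - c[k] for k in range(3)]
        d = np.sqrt(
            sub[0][:, None, None] ** 2 + sub[1][None, :, None] ** 2 + sub[2][None, None, :] ** 2
        ) - r
        region = field_arr[idx_lo[0]:idx_hi[0], idx_lo[1]:idx_hi[1], idx_lo[2]:idx_hi[2]]
        np.minimum(region, d, out=region)

    if not (field_arr.min() < 0 < field_arr[np.isfinite(field_arr)].max()):
        raise MeshingError("no isosurface crossing found; check grid resolution")
    # cap the far field so marching cubes sees finite values everywhere
    np.nan_to_num(field_arr, copy=False, posinf=4.0 * pad)
    try:
        verts, faces, _, _ = marching_cubes(field_arr, level=0.0, spacing=(h, h, h))
    except Exception as exc:  # pragma: no cover - defensive
        raise MeshingError(f"marching cubes failed: {exc}") from exc
    verts = verts + lo
    mesh = TriMesh(verts, faces)
    if mesh.n_faces < 4:
        raise MeshingError("degenerate geometry produced a collapsed mesh")
    return mesh


# ---------------------------------------------------------------------------
# Quadric error metric edge-collapse simplification
# ---------------------------------------------------------------------------


def _face_quadric(p0, p1, p2):
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return np.zeros((4, 4))
    n = n / norm
    d = -float(n @ p0)
    plane = np.array([n[0], n[1], n[2], d])
    return np.outer(plane, plane) * norm  # area-weighted

def _collapse_target(q, p_u, p_v):
    """Optimal placement for an edge collapse under quadric ``q``."""
    a = q[:3, :3]
    b = -q[:3, 3]
    try:
        if np.linalg.cond(a) < 1e7:
            return np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        pass
    # fall back to the best of endpoints and midpoint
    candidates = [p_u, p_v, 0.5 * (p_u + p_v)]
    errs = [float(np.r_[p, 1.0] @ q @ np.r_[p, 1.0]) for p in candidates]
    return candidates[int(np.argmin(errs))]


def simplify_mesh(mesh: TriMesh, face_fraction: float = DEFAULT_FACE_FRACTION) -> TriMesh:
    """Reduce face count by quadric error metric edge collapses.

    Collapses the cheapest edges first, placing the merged vertex at the
    quadric-optimal point, until at most ``ceil(face_fraction * n_faces)``
    faces remain.  Collapses that would flip a face normal are rejected.
    ``face_fraction=1.0`` is a no-op.
    """
    if not (0 < face_fraction <= 1):
        raise ValueError("face_fraction must be in (0, 1]")
    target = math.ceil(face_fraction * mesh.n_faces)
    if target < 4:
        raise ValueError(
            f"face_fraction {face_fraction} would leave {target} faces (< 4); mesh would collapse"
        )
    if target >= mesh.n_faces:
        return TriMesh(mesh.vertices.copy(), mesh.faces.copy())

    verts = [v.copy() for v in mesh.vertices]
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces)}
    vert_faces: dict[int, set[int]] = {i: set() for i in range(len(verts))}
    for fi, f in faces.items():
        for v in f:
            vert_faces[v].add(fi)

    quadrics = [np.zeros((4, 4)) for _ in verts]
    for f in faces.values():
        q = _face_quadric(verts[f[0]], verts[f[1]], verts[f[2]])
        for v in f:
            quadrics[v] += q

    version = [0] * len(verts)
    alive = [True] * len(verts)

    def push_edge(heap, u, v):
        if u == v:
            return
        a, b = (u, v) if u < v else (v, u)
        q = quadrics[a] + quadrics[b]
        p = _collapse_target(q, verts[a], verts[b])
        cost = float(np.r_[p, 1.0] @ q @ np.r_[p, 1.0])
        heapq.heappush(heap, (cost, a, b, version[a], version[b], tuple(p)))

    heap: list = []
    edge_set = set()
    for f in faces.values():
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[0], f[2])):
            e = (u, v) if u < v else (v, u)
            if e not in edge_set:
                edge_set.add(e)
                push_edge(heap, *e)

    n_faces = len(faces)
    while n_faces > target and heap:
        cost, a, b, va, vb, p = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or version[a] != va or version[b] != vb:
            continue
        p = np.asarray(p)
        shared = vert_faces[a] & vert_faces[b]
        if not shared:
            continue
        # reject collapses that flip any surviving face normal
        bad = False
        for fi in (vert_faces[a] | vert_faces[b]) - shared:
            f = faces[fi]
            tri_old = [verts[x] for x in f]
            tri_new = [p if x in (a, b) else verts[x] for x in f]
            n_old = np.cross(tri_old[1] - tri_old[0], tri_old[2] - tri_old[0])
            n_new = np.cross(tri_new[1] - tri_new[0], tri_new[2] - tri_new[0])
            if float(n_old @ n_new) <= 0:
                bad = True
                break
        if bad:
            continue

        # merge b into a at position p
        verts[a] = p
        quadrics[a] = quadrics[a] + quadrics[b]
        alive[b] = False
        for fi in shared:
            f = faces.pop(fi)
            n_faces -= 1
            for v in f:
                vert_faces[v].discard(fi)
        for fi in list(vert_faces[b]):
            f = faces[fi]
            faces[fi] = tuple(a if x == b else x for x in f)
            vert_faces[b].discard(fi)
            vert_faces[a].add(fi)
        vert_faces[b] = set()
        version[a] += 1
        version[b] += 1

        neighbors = set()
        for fi in vert_faces[a]:
            neighbors.update(faces[fi])
        neighbors.discard(a)
        for v in neighbors:
            push_edge(heap, a, v)

    # compact
    used = sorted({v for f in faces.values() for v in f})
    remap = {v: i for i, v in enumerate(used)}
    new_verts = np.array([verts[v] for v in used])
    new_faces = np.array([[remap[v] for v in f] for f in faces.values()], dtype=np.int64)
    out = TriMesh(new_verts, new_faces)
    if out.n_faces < 4:
        raise ValueError("simplification collapsed the mesh below 4 faces")
    return out


def _point_triangle_distances(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest point on any triangle.

    Brute-force closest-point-on-triangle (Ericson's barycentric region
    method) broadcast over all point/triangle pairs; adequate for the
    mesh sizes the tests use.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, bc = b - a, c - a, c - b

    def safe_div(num, den):
        return num / np.where(np.abs(den) < 1e-30, 1.0, den)

    out = np.empty(len(points))
    for i, p in enumerate(points):
        d1 = (ab * (p - a)).sum(1)
        d2 = (ac * (p - a)).sum(1)
        d3 = (ab * (p - b)).sum(1)
        d4 = (ac * (p - b)).sum(1)
        d5 = (ab * (p - c)).sum(1)
        d6 = (ac * (p - c)).sum(1)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2

        # interior (lowest priority), then overwrite by regions in reverse
        # priority so vertex regions win last
        denom = va + vb + vc
        v = safe_div(vb, denom)[:, None]
        w = safe_div(vc, denom)[:, None]
        closest = a + v * ab + w * ac

        m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
        t = np.clip(safe_div(d4 - d3, (d4 - d3) + (d5 - d6)), 0, 1)[:, None]
        closest = np.where(m_bc[:, None], b + t * bc, closest)

        m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        t = np.clip(safe_div(d2, d2 - d6), 0, 1)[:, None]
        closest = np.where(m_ac[:, None], a + t * ac, closest)

        m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        t = np.clip(safe_div(d1, d1 - d3), 0, 1)[:, None]
        closest = np.where(m_ab[:, None], a + t * ab, closest)

        closest = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, closest)
        closest = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, closest)
        closest = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, closest)

        out[i] = np.sqrt(((p - closest) ** 2).sum(1).min())
    return out


def hausdorff_distance(a: TriMesh, b: TriMesh) -> float:
    """Symmetric Hausdorff distance over vertex samples against surfaces (Å).

    Each mesh's vertices are measured against the other mesh's *surface*
    (closest point on any triangle), so the value reflects geometric
    deviation rather than sampling density.
    """
    tri_a = a.vertices[a.faces]
    tri_b = b.vertices[b.faces]
    d_ab = _point_triangle_distances(a.vertices, tri_b)
    d_ba = _point_triangle_distances(b.vertices, tri_a)
    return float(max(d_ab.max(), d_ba.max()))


# ---------------------------------------------------------------------------
# Association and surface residues
# ---------------------------------------------------------------------------


def associate_vertices(mesh: TriMesh, structure: BackboneStructure) -> VertexAssociation:
    """Assign every vertex to its nearest backbone atom.

    Ties are broken deterministically in favour of the earlier residue and,
    within a residue, atom order N < CA < C < O.
    """
    if mesh.n_vertices == 0 or len(structure) == 0:
        raise ValueError("mesh and structure must be non-empty")
    index = structure.atom_index()  # already (residue order, atom order)
    centers = structure.all_coords()
    owner: dict[int, tuple[int, str]] = {}
    chunk = 4096
    for start in range(0, mesh.n_vertices, chunk):
        block = mesh.vertices[start : start + chunk]
        d2 = ((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        # argmin returns the first minimum: exactly the required tie-break
        nearest = np.argmin(d2, axis=1)
        for i, a in enumerate(nearest):
            owner[start + i] = index[a]
    return VertexAssociation(owner=owner)


def surface_residues(assoc: VertexAssociation) -> list[int]:
    """Sequence positions of residues owning at least one vertex, in order."""
    return sorted({pos for (pos, _tag), verts in assoc.atom_vertices.items() if verts})


# ---------------------------------------------------------------------------
# Interchange formats
# ---------------------------------------------------------------------------


class MSMSFormatError(ValueError):
    pass


def import_msms(vert_source, face_source) -> TriMesh:
    """Read an MSMS ``.vert``/``.face`` pair into a :class:`TriMesh`.

    MSMS files carry three header lines (the third stating the record
    count) followed by fixed-column records; face indices are 1-based and
    converted to 0-based here.
    """

    def read_text(src):
        if hasattr(src, "read"):
            return src.read()
        with open(src) as fh:
            return fh.read()

    def parse(text, n_fields, label):
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if len(lines) < 3:
            raise MSMSFormatError(f"{label}: fewer than 3 header lines")
        try:
            count = int(lines[2].split()[0])
        except (ValueError, IndexError) as exc:
            raise MSMSFormatError(f"{label}: bad count header") from exc
        records = lines[3:]
        if len(records) != count:
            raise MSMSFormatError(
                f"{label}: header promises {count} records, found {len(records)}"
            )
        out = []
        for ln in records:
            parts = ln.split()
            if len(parts) < n_fields:
                raise MSMSFormatError(f"{label}: record with fewer than {n_fields} fields")
            out.append(parts[:n_fields])
        return out

    vrec = parse(read_text(vert_source), 3, "vert")
    frec = parse(read_text(face_source), 3, "face")
    vertices = np.array([[float(x) for x in r] for r in vrec])
    faces = np.array([[int(x) - 1 for x in r] for r in frec], dtype=np.int64)
    return TriMesh(vertices, faces)


def save_mesh(mesh: TriMesh, dest, file_type: str | None = None) -> None:
    """Write a mesh as OFF or PLY (inferred from the path suffix)."""
    tm = mesh.to_trimesh()
    if file_type is None and isinstance(dest, str):
        file_type = dest.rsplit(".", 1)[-1].lower()
    tm.export(dest, file_type=file_type)


def load_mesh(src, file_type: str | None = None) -> TriMesh:
    """Read an OFF or PLY mesh."""
    import trimesh

    tm = trimesh.load(src, file_type=file_type, process=False)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
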