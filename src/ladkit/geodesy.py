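"""Surface distances: vertex geodesics and averaged atom/residue matrices.

Two distance metrics feed the descriptor:

* **ED** — Euclidean distance between atom centers, straight from the
  coordinates.
* **GD** — geodesic distance: the shortest path along the triangulated
  surface between mesh vertices, computed here as shortest paths on the
  mesh edge graph weighted by Euclidean edge lengths (an upper bound on
  the exact polyhedral geodesic that tightens with mesh density).

Atom-level GD between atoms ``a_i`` and ``a_j`` with associated vertex sets
of sizes M and N is the arithmetic mean of all M x N vertex-pair geodesics;
residue-level distances average the atom-level values over all atom pairs.
Pairs of vertices on different mesh components have no geodesic; they are
flagged as NaN, never silently treated as infinite.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .structure import BackboneStructure
from .surface import TriMesh, VertexAssociation


@dataclass
class ResidueDistanceMatrix:
    """Symmetric averaged pairwise distance matrix over surface residues.

    ``values[i, j]`` is the ED or GD between ``residue_ids[i]`` and
    ``residue_ids[j]`` in Å; NaN flags residue pairs separated by a mesh
    component boundary (GD only).
    """

    metric: str  # "ED" or "GD"
    residue_ids: list[int]
    values: np.ndarray
    resnames: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match residue count")
        if self.metric not in ("ED", "GD"):
            raise ValueError("metric must be 'ED' or 'GD'")

    def __len__(self) -> int:
        return len(self.residue_ids)

    def to_tsv(self, dest) -> None:
        header = "\t".join(["residue"] + [str(r) for r in self.residue_ids])
        lines = [header]
        for rid, row in zip(self.residue_ids, self.values):
            lines.append("\t".join([str(rid)] + [f"{v:.6f}" for v in row]))
        text = "\n".join(lines) + "\n"
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)


def _unfolded_shortcuts(mesh: TriMesh):
    """Extra graph edges from unfolding face pairs across shared edges.

    For two faces sharing edge (a, b), the second face is unfolded into
    the plane of the first; if the straight segment between the two
    opposite vertices crosses the shared edge, its unfolded length is a
    genuine surface-path length and is added as a shortcut edge.  This
    tightens Dijkstra's upper bound on the polyhedral geodesic (sphere
    error drops from several percent to well under one percent) without
    ever dropping below the true geodesic.
    """
    v = mesh.vertices
    edge_opposite: dict[tuple[int, int], list[int]] = defaultdict(list)
    for f in mesh.faces:
        for k in range(3):
            a, b = f[k], f[(k + 1) % 3]
            key = (a, b) if a < b else (b, a)
            edge_opposite[key].append(f[(k + 2) % 3])

    rows, cols, weights = [], [], []
    for (a, b), opposite in edge_opposite.items():
        if len(opposite) != 2:
            continue  # boundary or non-manifold edge
        c, d = opposite
        L = float(np.linalg.norm(v[a] - v[b]))
        if L < 1e-12:
            continue

        def embed(p: int, sign: float) -> np.ndarray:
            da = float(np.linalg.norm(v[p] - v[a]))
            db = float(np.linalg.norm(v[p] - v[b]))
            x = (da * da - db * db + L * L) / (2 * L)
            y2 = max(da * da - x * x, 0.0)
            return np.array([x, sign * np.sqrt(y2)])

        C, D = embed(c, 1.0), embed(d, -1.0)
        denom = C[1] - D[1]
        if denom <= 1e-12:
            continue
        x_cross = C[0] + (D[0] - C[0]) * C[1] / denom
        if 0.0 < x_cross < L:
            rows.append(c)
            cols.append(d)
            weights.append(float(np.linalg.norm(C - D)))
    return rows, cols, weights


def geodesic_graph(mesh: TriMesh, shortcuts: bool = True):
    """Sparse graph whose shortest paths approximate surface geodesics."""
    g = mesh.edge_graph().tocoo()
    if not shortcuts:
        return g.tocsr()
    r, c, w = _unfolded_shortcuts(mesh)
    rows = np.concatenate([g.row, r, c])
    cols = np.concatenate([g.col, c, r])
    data = np.concatenate([g.data, w, w])
    return coo_matrix((data, (rows, cols)), shape=g.shape).tocsr()


def vertex_geodesics(mesh: TriMesh, sources, targets, shortcuts: bool = True) -> np.ndarray:
    """Geodesic distance table between vertex index lists.

    Shortest paths are computed with Dijkstra on the mesh edge graph,
    augmented by default with unfolded-face shortcut edges (see
    :func:`geodesic_graph`).  Returns an array of shape
    ``(len(sources), len(targets))``; unreachable pairs (different mesh
    components) are flagged NaN.
    """
    sources = np.asarray(sources, dtype=int)
    targets = np.asarray(targets, dtype=int)
    n = mesh.n_vertices
    for idx in (sources, targets):
        if len(idx) and (idx.min() < 0 or idx.max() >= n):
            raise IndexError("vertex index out of range")
    graph = geodesic_graph(mesh, shortcuts=shortcuts)
    dist = dijkstra(graph, directed=False, indices=sources)
    table = dist[:, targets]
    table[~np.isfinite(table)] = np.nan
    return table


def atom_gd(assoc: VertexAssociation, vgd: dict[tuple[int, int], float] | np.ndarray,
            atom_i: tuple[int, str], atom_j: tuple[int, str],
            vertex_index: dict[int, int] | None = None) -> float:
    """Averaged geodesic distance between two atoms.

    ``vgd`` is either a dense vertex-geodesic matrix over all mesh vertices
    (then ``vertex_index`` is None and vertex ids index it directly) or a
    sub-matrix over associated vertices with ``vertex_index`` mapping vertex
    id to row/column.
    """
    vi = assoc.atom_vertices.get(atom_i, [])
    vj = assoc.atom_vertices.get(atom_j, [])
    if not vi:
        raise ValueError(f"atom {atom_i} has no associated vertices")
    if not vj:
        raise ValueError(f"atom {atom_j} has no associated vertices")
    if vertex_index is not None:
        rows = [vertex_index[v] for v in vi]
        cols = [vertex_index[v] for v in vj]
    else:
        rows, cols = vi, vj
    block = np.asarray(vgd)[np.ix_(rows, cols)]
    return float(np.mean(block))


def _atom_level_euclidean(ci: np.ndarray, cj: np.ndarray) -> float:
    """Residue-level ED: mean over atom pairs of center-to-center distance."""
    d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)
    return float(d.mean())


def residue_distance_matrix(
    structure: BackboneStructure,
    assoc: VertexAssociation | None = None,
    mesh: TriMesh | None = None,
    metric: str = "ED",
    residues: list[int] | None = None,
) -> ResidueDistanceMatrix:
    """Averaged residue-by-residue distance matrix.

    For GD, ``mesh`` and ``assoc`` are required and distances average the
    vertex geodesics up through atoms to residues.  For ED, distances are
    averaged Euclidean atom-center distances; when an association is given
    only vertex-owning atoms enter the average (keeping the ED and GD
    matrices comparable over identical atom sets), otherwise all backbone
    atoms are used.

    ``residues`` restricts and orders the rows explicitly; by default the
    surface-residue set from ``assoc`` (or all residues without one) is used.
    """
    from .surface import surface_residues as _surf

    metric = metric.upper()
    if metric not in ("ED", "GD"):
        raise ValueError("metric must be 'ED' or 'GD'")
    if metric == "GD" and (assoc is None or mesh is None):
        raise ValueError("GD requires a mesh and a vertex association")

    res_by_pos = {r.seq_pos: r for r in structure.residues}
    if residues is None:
        residues = _surf(assoc) if assoc is not None else sorted(res_by_pos)
    missing = [p for p in residues if p not in res_by_pos]
    if missing:
        raise ValueError(f"residues not in structure: {missing}")
    resnames = [res_by_pos[p].resname for p in residues]

    # per residue: the atoms entering the average, with coordinates
    atom_sets: list[list[tuple[int, str]]] = []
    for pos in residues:
        tags = res_by_pos[pos].atom_tags()
        if assoc is not None:
            tags = [t for t in tags if assoc.atom_vertices.get((pos, t))]
        if not tags:
            raise ValueError(f"residue {pos} has no contributing atoms")
        atom_sets.append([(pos, t) for t in tags])

    n = len(residues)
    values = np.zeros((n, n))

    if metric == "ED":
        coords = [
            np.array([res_by_pos[pos].atoms[t] for (pos, t) in atoms])
            for atoms in atom_sets
        ]
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = _atom_level_euclidean(coords[i], coords[j])
    else:
        all_assoc = sorted({v for atoms in atom_sets for a in atoms for v in assoc.atom_vertices[a]})
        vidx = {v: k for k, v in enumerate(all_assoc)}
        table = vertex_geodesics(mesh, all_assoc, all_assoc)
        # atom-level means first, then residue-level mean over atom pairs
        for i in range(n):
            for j in range(i + 1, n):
                vals = [
                    atom_gd(assoc, table, ai, aj, vertex_index=vidx)
                    for ai in atom_sets[i]
                    for aj in atom_sets[j]
                ]
                values[i, j] = values[j, i] = float(np.mean(vals))

    return ResidueDistanceMatrix(metric=metric, residue_ids=list(residues), values=values,
                                 resnames=resnames)
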