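"""Deterministic synthetic structures, morphs and meshes for testing.

Real morph sets — groups of conformers of one protein spanning a hinge
motion, two end states plus interpolated frames — come from morph servers
and are not downloadable here; these generators emulate their geometry at
reduced scale.  A toy backbone chain (helix, extended or zigzag C-alpha
trace with ideal 3.8 Å spacing and deterministic N/C/O placement) is bent
rigidly at one or more hinge residues, frames interpolate the bend angle
linearly, and a small Gaussian coordinate jitter (default sigma 0.05 Å,
seeded) makes conformers homologous-but-not-identical.

Everything here is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import BackboneStructure, Residue
from .surface import TriMesh

GEOMETRIES = ("helix", "extended", "zigzag")
CA_SPACING = 3.8  # Å, ideal consecutive C-alpha distance

DEFAULT_JITTER_SIGMA = 0.05  # Å

# default desk-scale benchmark: 5 hinge-morph groups of 10 frames each
BENCHMARK_LENGTHS = (30, 50, 60, 80, 100)
BENCHMARK_FRAMES = 10
BENCHMARK_MAX_ANGLE = 60.0


@dataclass
class MorphGroup:
    """A group of conformers of one chain related by a hinge bend."""

    group_id: str
    conformers: list[BackboneStructure]
    hinge_positions: list[int]
    bend_angle_range: tuple[float, float]

    def __post_init__(self):
        lengths = {len(c) for c in self.conformers}
        if len(lengths) != 1:
            raise ValueError("conformers differ in residue count")


def _ca_trace(n: int, geometry: str) -> np.ndarray:
    if geometry == "helix":
        # ideal alpha-helix: rise 1.5 Å, 100 deg per residue, radius chosen
        # so consecutive C-alphas sit CA_SPACING apart
        rise, twist = 1.5, np.deg2rad(100.0)
        chord = 2.0 * np.sin(twist / 2.0)
        radius = np.sqrt(CA_SPACING**2 - rise**2) / chord
        k = np.arange(n)
        return np.c_[radius * np.cos(twist * k), radius * np.sin(twist * k), rise * k]
    if geometry == "extended":
        dy = 0.25
        dx = np.sqrt(CA_SPACING**2 - (2 * dy) ** 2)
        k = np.arange(n)
        return np.c_[dx * k, dy * (-1.0) ** k, np.zeros(n)]
    if geometry == "zigzag":
        dy = 1.3
        dx = np.sqrt(CA_SPACING**2 - (2 * dy) ** 2)
        k = np.arange(n)
        return np.c_[dx * k, dy * (-1.0) ** k, np.zeros(n)]
    raise ValueError(f"unknown geometry {geometry!r}; choose from {GEOMETRIES}")


def make_toy_chain(n_residues: int, geometry: str = "helix", seed: int = 0,
                   chain_id: str | None = None) -> BackboneStructure:
    """Ideal toy backbone chain with ``n_residues`` residues.

    C-alpha atoms follow the requested geometry at 3.8 Å spacing; N, C and
    O are placed deterministically in the local frame of the trace so every
    residue carries all four backbone atoms.  ``seed`` is part of the
    identity (toy chains are ideal, so it only labels the chain) and the
    output is bit-identical for equal arguments.
    """
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5")
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}")
    ca = _ca_trace(n_residues, geometry)

    residues = []
    for i in range(n_residues):
        # local frame: tangent along the trace, deterministic normal
        fwd = ca[min(i + 1, n_residues - 1)] - ca[max(i - 1, 0)]
        t = fwd / np.linalg.norm(fwd)
        ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        atoms = {
            "N": ca[i] - 1.46 * t + 0.30 * u,
            "CA": ca[i].copy(),
            "C": ca[i] + 1.52 * t + 0.30 * v,
            "O": ca[i] + 1.52 * t + 0.30 * v + 1.23 * u,
        }
        residues.append(Residue(seq_pos=i + 1, resname="ALA", atoms=atoms))
    cid = chain_id or f"toy-{geometry}-{n_residues}-s{seed}"
    return BackboneStructure(id=cid, residues=residues)


def _transform(structure: BackboneStructure, fn, new_id: str | None = None) -> BackboneStructure:
    residues = [
        Residue(
            seq_pos=r.seq_pos,
            resname=r.resname,
            insertion_code=r.insertion_code,
            atoms={t: fn(r, np.asarray(c, dtype=float)) for t, c in r.atoms.items()},
        )
        for r in structure.residues
    ]
    return BackboneStructure(id=new_id or structure.id, residues=residues)


def rigid_transform(structure: BackboneStructure, rotation: Rotation,
                    translation=np.zeros(3), new_id: str | None = None) -> BackboneStructure:
    """Apply a whole-body rotation + translation (test utility)."""
    translation = np.asarray(translation, dtype=float)
    return _transform(structure, lambda r, c: rotation.apply(c) + translation, new_id)


def apply_hinge_bend(structure: BackboneStructure, hinge: int, angle: float,
                     axis=(0.0, 0.0, 1.0), new_id: str | None = None) -> BackboneStructure:
    """Rotate all residues past ``hinge`` rigidly about an axis through its CA.

    ``hinge`` is a residue sequence position strictly inside the chain;
    residues with ``seq_pos <= hinge`` are untouched, the rest rotate by
    ``angle`` degrees about ``axis`` anchored at the hinge residue's
    C-alpha.  Both sides stay internally rigid, so all intra-side pairwise
    distances are preserved exactly.
    """
    positions = structure.seq_positions
    if not (positions[0] < hinge < positions[-1]):
        raise ValueError(f"hinge {hinge} outside the chain interior {positions[0]}..{positions[-1]}")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("axis must be non-zero")
    rot = Rotation.from_rotvec(np.deg2rad(angle) * axis / norm)
    hinge_res = next(r for r in structure.residues if r.seq_pos == hinge)
    pivot = np.asarray(hinge_res.atoms["CA"], dtype=float)

    def move(res, coord):
        if res.seq_pos <= hinge:
            return coord.copy()
        return rot.apply(coord - pivot) + pivot

    return _transform(structure, move, new_id)


def jitter(structure: BackboneStructure, sigma: float, rng: np.random.Generator,
           new_id: str | None = None) -> BackboneStructure:
    """Add isotropic Gaussian coordinate noise of scale ``sigma`` Å."""
    return _transform(structure, lambda r, c: c + rng.normal(0.0, sigma, 3), new_id)


def make_morph_group(
    base: BackboneStructure,
    hinge: int | list[int],
    max_angle: float,
    n_frames: int,
    seed: int = 0,
    jitter_sigma: float = DEFAULT_JITTER_SIGMA,
    axes=None,
    group_id: str | None = None,
) -> MorphGroup:
    """Hinge-bend morph: frames interpolate the bend angle 0 → max_angle.

    One to three hinge positions are supported; each hinge bends by the
    frame's angle about its own axis (defaults derived deterministically
    from the hinge index).  Per-frame Gaussian jitter (seeded) keeps
    conformers homologous but not identical; frame 0 is the jittered base.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    hinges = [hinge] if isinstance(hinge, int) else list(hinge)
    if not 1 <= len(hinges) <= 3:
        raise ValueError("1 to 3 hinge positions supported")
    if axes is None:
        base_axes = [(0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 1.0, 0.0)]
        axes = [base_axes[k % 3] for k in range(len(hinges))]
    gid = group_id or f"{base.id}-morph"
    angles = np.linspace(0.0, max_angle, n_frames)
    conformers = []
    for f, ang in enumerate(angles):
        conf = base
        for h, ax in zip(hinges, axes):
            conf = apply_hinge_bend(conf, h, float(ang), axis=ax)
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, f])
        conf = jitter(conf, jitter_sigma, rng, new_id=f"{gid}:f{f:02d}")
        conformers.append(conf)
    return MorphGroup(
        group_id=gid,
        conformers=conformers,
        hinge_positions=hinges,
        bend_angle_range=(0.0, float(max_angle)),
    )


def make_benchmark(
    n_groups: int = 5,
    n_frames: int = BENCHMARK_FRAMES,
    max_angle: float = BENCHMARK_MAX_ANGLE,
    seed: int = 42,
    jitter_sigma: float = DEFAULT_JITTER_SIGMA,
) -> list[MorphGroup]:
    """Default retrieval benchmark: hinge-morph groups of distinct chains.

    Groups use distinct base geometries and lengths (30, 50, 60, 80, 100
    residues, cycling) with a single hinge at mid-chain, echoing real morph
    sets at reduced scale.
    """
    groups = []
    for g in range(n_groups):
        n = BENCHMARK_LENGTHS[g % len(BENCHMARK_LENGTHS)]
        geometry = GEOMETRIES[g % len(GEOMETRIES)]
        base = make_toy_chain(n, geometry=geometry, seed=seed, chain_id=f"g{g}-{geometry}{n}")
        hinge = n // 2
        groups.append(
            make_morph_group(
                base,
                hinge=hinge,
                max_angle=max_angle,
                n_frames=n_frames,
                seed=(int(seed) * 1000 + g) & 0x7FFFFFFF,
                jitter_sigma=jitter_sigma,
                group_id=f"group{g}",
            )
        )
    return groups


@dataclass(frozen=True)
class LabeledPair:
    """Alignment statistics of one structure pair with a similarity label."""

    label: str  # "pos" or "neg"
    Ne: int
    lad_rmsd: float
    NQ: int
    NS: int

    def __iter__(self):
        return iter((self.Ne, self.lad_rmsd, self.NQ, self.NS))


def make_labeled_pairs(
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    pos_rmsd=(0.3, 0.1),
    neg_rmsd=(2.0, 0.5),
    pos_coverage=(8.0, 2.0),
    neg_coverage=(2.0, 5.0),
    length_range=(50, 200),
) -> list[LabeledPair]:
    """Labelled (Ne, lad_rmsd, NQ, NS) pairs for diversity-parameter tuning.

    Positives mimic homologous pairs: low LAD-RMSD (folded normal around
    ``pos_rmsd``) and high alignment coverage Ne/mean (Beta(8, 2));
    negatives mimic non-homologous pairs: high RMSD and Beta(2, 5)
    coverage.  Deterministic given the seed.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("pair counts must be >= 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    out: list[LabeledPair] = []
    for label, count, rmsd_p, cov_ab in (
        ("pos", n_pos, pos_rmsd, pos_coverage),
        ("neg", n_neg, neg_rmsd, neg_coverage),
    ):
        for _ in range(count):
            nq = int(rng.integers(length_range[0], length_range[1] + 1))
            ns = int(rng.integers(length_range[0], length_range[1] + 1))
            coverage = float(rng.beta(*cov_ab))
            ne = max(0, min(min(nq, ns), round(coverage * 0.5 * (nq + ns))))
            rmsd = float(abs(rng.normal(*rmsd_p)))
            out.append(LabeledPair(label, ne, rmsd, nq, ns))
    return out


def make_analytic_mesh(kind: str, **params) -> TriMesh:
    """Meshes with known geodesics: icosphere, plane grid, torus.

    * ``icosphere``: ``radius`` (default 1), ``subdivisions`` (default 4;
      20 * 4^s faces); geodesics are great-circle arcs.
    * ``plane``: unit-square grid, ``n`` points per side (default 11);
      geodesics along grid-aligned convex paths equal Euclidean distances.
    * ``torus``: ``major_radius`` (default 3), ``minor_radius`` (default 1).
    """
    import trimesh

    if kind == "icosphere":
        tm = trimesh.creation.icosphere(
            subdivisions=int(params.get("subdivisions", 4)),
            radius=float(params.get("radius", 1.0)),
        )
    elif kind == "plane":
        n = int(params.get("n", 11))
        xs = np.linspace(0.0, 1.0, n)
        xv, yv = np.meshgrid(xs, xs, indexing="ij")
        vertices = np.c_[xv.ravel(), yv.ravel(), np.zeros(n * n)]
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + n, a + 1])
                faces.append([a + 1, a + n, a + n + 1])
        return TriMesh(vertices, np.asarray(faces))
    elif kind == "torus":
        tm = trimesh.creation.torus(
            major_radius=float(params.get("major_radius", 3.0)),
            minor_radius=float(params.get("minor_radius", 1.0)),
        )
    else:
        raise ValueError(f"unknown analytic mesh kind {kind!r}")
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
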