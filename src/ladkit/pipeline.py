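"""End-to-end convenience layer: structure -> mesh -> matrix -> profile.

This is the path the command-line interface and the benchmark drive.  For
GD profiles the mesh is simplified (default: keep 15% of faces) before
geodesics are computed, which is what makes shortest-path computation
affordable; ED profiles only need the mesh to decide which residues are on
the surface, so no simplification is applied there by default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .align import DiversityParams, align_profiles
from .evaluate import RetrievalRun, rank_database
from .geodesy import residue_distance_matrix
from .profile import DEFAULT_WINDOW, LADProfile, build_lad_profile
from .structure import BackboneStructure
from .surface import (
    DEFAULT_FACE_FRACTION,
    DEFAULT_GRID_RESOLUTION,
    DEFAULT_PROBE_RADIUS,
    associate_vertices,
    build_surface,
    simplify_mesh,
    surface_residues,
)


@dataclass
class SurfaceParams:
    """Mesh-construction knobs shared across the pipeline."""

    probe_radius: float = DEFAULT_PROBE_RADIUS
    grid_resolution: float = DEFAULT_GRID_RESOLUTION
    face_fraction: float = DEFAULT_FACE_FRACTION


def compute_profile(
    structure: BackboneStructure,
    metric: str = "ED",
    window: int = DEFAULT_WINDOW,
    surface: SurfaceParams | None = None,
    residues: list[int] | None = None,
    mesh=None,
) -> LADProfile:
    """Full descriptor pipeline for one chain.

    A precomputed ``mesh`` (e.g. an imported MSMS surface) bypasses the
    built-in surface construction.  ``residues`` pins the residue set
    explicitly — with metric ED this skips meshing entirely and uses all
    backbone atoms of those residues, which is how a fixed surface set can
    be imposed across conformers of the same chain.
    """
    metric = metric.upper()
    surface = surface or SurfaceParams()
    meta = {
        "probe_radius": surface.probe_radius,
        "grid_resolution": surface.grid_resolution,
    }
    if metric == "ED" and residues is not None:
        dmat = residue_distance_matrix(structure, metric="ED", residues=residues)
        meta["surface_set"] = "fixed"
    else:
        if mesh is None:
            mesh = build_surface(structure, surface.probe_radius, surface.grid_resolution)
        if metric == "GD":
            mesh = simplify_mesh(mesh, surface.face_fraction)
            meta["face_fraction"] = surface.face_fraction
        assoc = associate_vertices(mesh, structure)
        dmat = residue_distance_matrix(
            structure, assoc=assoc, mesh=mesh, metric=metric, residues=residues
        )
    return build_lad_profile(dmat, window=window, structure_id=structure.id, meta=meta)


def compare_structures(
    a: BackboneStructure,
    b: BackboneStructure,
    metric: str = "ED",
    window: int = DEFAULT_WINDOW,
    surface: SurfaceParams | None = None,
    params: DiversityParams | None = None,
    **align_kwargs,
):
    """Profile both chains and align them; returns the ProfileAlignment."""
    pa = compute_profile(a, metric=metric, window=window, surface=surface)
    pb = compute_profile(b, metric=metric, window=window, surface=surface)
    return align_profiles(pa, pb, params=params, **align_kwargs)


def benchmark_profiles(groups, metric: str = "ED", window: int = DEFAULT_WINDOW,
                       surface: SurfaceParams | None = None) -> dict[str, LADProfile]:
    """Profiles for every conformer of every morph group, keyed by id."""
    out: dict[str, LADProfile] = {}
    for group in groups:
        for conf in group.conformers:
            out[conf.id] = compute_profile(conf, metric=metric, window=window, surface=surface)
    return out


def benchmark_runs(
    groups,
    profiles: dict[str, LADProfile],
    params: DiversityParams | None = None,
    representatives: dict[str, str] | None = None,
) -> tuple[list[RetrievalRun], list[RetrievalRun], dict[str, str]]:
    """Retrieval runs over the benchmark database, under both protocols.

    Returns ``(runs, rep_runs, rep_of_query)``: ``runs`` rank each
    conformer against all other conformers (relevance = same-group
    membership; feeds PR/MAP/F1), while ``rep_runs`` rank each conformer
    against the group representatives only (one per group, frame 0 by
    default), the protocol under which rank-1 success is scored.
    """
    group_of = {c.id: g.group_id for g in groups for c in g.conformers}
    members = {g.group_id: [c.id for c in g.conformers] for g in groups}
    if representatives is None:
        representatives = {g.group_id: g.conformers[0].id for g in groups}
    db = list(profiles.values())
    rep_db = [profiles[rid] for rid in representatives.values()]
    runs, rep_runs = [], []
    for query_id, prof in profiles.items():
        gid = group_of[query_id]
        relevant = set(members[gid]) - {query_id}
        runs.append(rank_database(prof, db, params=params, relevant=relevant))
        if query_id not in representatives.values():
            # representatives are the database of the rank-1 protocol, so
            # only non-representative conformers act as queries there
            rep_runs.append(
                rank_database(prof, rep_db, params=params,
                              relevant={representatives[gid]})
            )
    rep_of_query = {qid: representatives[group_of[qid]] for qid in profiles}
    return runs, rep_runs, rep_of_query
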