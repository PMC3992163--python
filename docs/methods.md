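# Methods

## The descriptor

A chain is reduced to its backbone atoms (N, Cα, C, O); side chains are
discarded so the descriptor reflects fold-level surface shape and stays
cheap to mesh.  The comparison unit is one chain.

**Surface construction.** The built-in backend samples the signed
distance to the union of probe-inflated van der Waals spheres on a
regular grid and extracts the zero isosurface with marching cubes.  Van
der Waals radii are fixed (N 1.55, C/Cα 1.70, O 1.52 Å) and the default
probe radius is 1.5 Å (water).  The default grid spacing is 0.7 Å;
halving it roughly doubles mesh fidelity at 8× the voxel count.  This
distance-transform surface is a well-established stand-in for the
solvent-excluded surface; an import path for MSMS `.vert`/`.face` output
is provided for users who want the exact SES, and OFF/PLY I/O for
debugging.

**Simplification.** Quadric error metric edge collapse with
optimal-position placement and normal-flip rejection, to a target face
fraction (default 0.15).  Simplification exists to make geodesic
computation affordable, so the ED pipeline skips it by default; the GD
pipeline applies it before computing shortest paths.  Geometric drift is
monitored as a vertex-to-surface Hausdorff distance (exact closest
point on triangle, brute force over faces).

**Vertex association and surface residues.** Every mesh vertex belongs
to the nearest backbone atom (ties: earlier residue, then N < CA < C < O).
A residue is a surface residue iff it owns at least one vertex.  The
association is a partition, which the tests assert.

**Distances.** Atom-level GD averages all M×N vertex-pair geodesics of
the two atoms' vertex sets (M, N ≥ 1 by construction); residue-level
distances average atom-level values over atom pairs.  Residue-level ED
averages Euclidean atom-center distances over the same vertex-owning
atom sets, so the ED and GD matrices are computed over identical atoms;
when no mesh is supplied, ED falls back to all backbone atoms of an
explicit residue list — that mode is what lets tests hold the
surface-residue set fixed across conformers.  Geodesics between
different mesh components are flagged NaN, never silently infinite, and
window averages skip them.

**Geodesic computation.** Dijkstra on the mesh edge graph (weights =
edge lengths), augmented with *unfolded-face shortcuts*: for each pair
of faces sharing an edge, the far vertices are connected by their
straight-line distance in the common unfolded plane whenever that
segment crosses the shared edge.  Both edge paths and shortcut paths are
genuine surface paths, so the estimate always upper-bounds the exact
polyhedral geodesic and never drops below the Euclidean chord; on a
subdivision-4 icosphere the antipodal error is ≈0.04 % versus ≈6 % for
plain edge Dijkstra.  An exact polyhedral solver can be swapped in by
passing `shortcuts=False` and replacing `geodesic_graph`, but the
default is dependency-free and deterministic.

**Profile.** LADᵢ = mean distance from surface residue *i* to the up to
(window−1) neighbours within ±(window−1)/2 positions *in the
surface-residue ordering* (buried residues are skipped, not gapped, so
profiles stay dense and alignable; a `window_sweep` utility covers odd
sizes 3–21 for re-tuning).  Terminal windows are truncated, not padded —
padding would fabricate distances.  The default window is 9 residues.

## Alignment and scoring

Profiles are aligned by Smith–Waterman with substitution score
σ(i,j) = s_max − |LADᵢ − LADⱼ|/m₀ and a linear gap penalty g
(defaults s_max = 1.0, m₀ = 1.0 Å, g = 0.5, all configurable — the
linear form keeps optimality transparent and lets the tests compare
against exhaustive enumeration of all monotone local alignments).  The
forward pass is vectorised per row: with linear gaps the within-row
recurrence m[j] = max(c[j], m[j−1] − g) equals cummax(c[j] + g·j) − g·j.
Traceback ties prefer diagonal, then up, then left, giving deterministic
alignments; the best-cell tie resolves to the first cell in row-major
order.  An alignment with no positive-scoring cell returns Nₑ = 0 (and
LAD_div = 1), not an error.

LAD_div combines coverage and the RMSD of aligned LAD values,
1 − (Nₑ/mean(N_Q,N_S)) · 1/(1 + (RMSD/D)^α), clamped to [0, 1].  N_Q and
N_S are profile (surface-residue) lengths, since the alignment operates
on profiles.  The RMSD here is of LAD values; `struct_div`'s RMSD is of
aligned Cα coordinates from an external structural aligner — the two
must not be conflated.  `struct_div` maps Nₑ = 0 to +inf (worst).

`tune_diversity_params` grid-searches D ∈ {0.1,…,20 step 0.1} × α ∈
{1,…,5 step 0.5} (1800 combinations), maximising the count of positive
pairs below 0.5 plus negative pairs at or above it; ties resolve to the
smallest D, then smallest α.

## Retrieval evaluation

Rankings are by ascending LAD_div with lexicographic subject-id
tie-breaks; a query is never compared to itself.  Two protocols are
supported, driven by a TSV manifest (`structure_id, group_id,
is_representative`): rank-1 success is scored on rankings against the
group representatives only (non-representative conformers as queries),
while R-precision, AP/MAP, the 11-point interpolated PR curve and F1@k
(default k = 64) use all-vs-all rankings with same-group relevance.

## Synthetic data

The generators emulate morph groups — conformers of one chain related by
rigid hinge motions — at desk scale, since the real morph collections
are external downloads.  Toy chains place Cα atoms on ideal helix /
extended / zigzag traces with exact 3.8 Å spacing and deterministic
N/C/O placement in the local frame.  `apply_hinge_bend` rotates all
residues past a hinge rigidly about an axis through the hinge Cα, so
intra-side distance matrices are preserved exactly — which is what makes
the hinge-invariance property testable to floating-point precision.
Morph groups interpolate the bend angle linearly over frames (1–3 hinges
supported) and add Gaussian coordinate jitter of σ = 0.05 Å, large
enough to break exact self-identity yet small against the 3.8 Å backbone
scale.  The default benchmark uses 5 groups × 10 frames with lengths
30–100 residues and a mid-chain hinge up to 60°; it exercises every
pipeline stage in well under five minutes on one CPU.

What the synthetic data does *not* emulate: side chains, real
morph-server interpolation (which relaxes geometry rather than rotating
rigidly), sequence divergence between homologs, and surface topology
changes such as genuine self-contacts.  Passing the synthetic benchmark
therefore demonstrates hinge robustness and pipeline correctness, not
retrieval performance on real flexible-protein databases.

`make_labeled_pairs` draws alignment statistics directly: positives with
low LAD-RMSD (|N(0.3, 0.1²)|) and high coverage (Beta(8,2)), negatives
with |N(2.0, 0.5²)| and Beta(2,5), lengths uniform in 50–200.  These
target the regimes observed for homologous vs non-homologous pairs and
make parameter recovery a well-posed simulation.

## Numerical choices and degenerate inputs

- Alternate locations in PDB input resolve to highest occupancy; first
  MODEL only; residues with ≥1 backbone atom are kept and averages use
  the atoms present.
- Profile TSV stores values to six decimals; round-trip equality is
  asserted at 1e-6.
- Score-equality tolerance in the alignment traceback is 1e-9; LAD
  values are O(1–20 Å) so this is far below data scale.
- Meshing a single atom yields a sphere (area within a few percent of
  analytic at 0.5 Å grids); widely separated atoms yield multiple closed
  components; an all-collinear chain still meshes (the distance field of
  a union of spheres is never degenerate on a padded grid).
- `simplify_mesh` refuses targets below 4 faces; `face_fraction = 1` is
  a no-op.

## Known limitations

- Graph geodesics (even with shortcuts) are upper bounds; GD profiles
  built on very coarse meshes inherit that bias.  The built-in surface
  differs geometrically from MSMS output, so absolute GD values are
  backend-dependent; comparisons should use profiles from the same
  backend.
- The substitution score and gap model are configurable conventions; the
  published operating points for (D, α) were trained under one such
  convention, and re-tuning via `tune_diversity_params` is recommended
  when the scoring defaults are changed.
- Window positions are counted in surface-residue space; a
  sequence-space dialect (buried residues leaving holes) would change
  profiles for heavily buried chains.
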