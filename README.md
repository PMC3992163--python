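# ladkit — Local Average Distance descriptors for flexible protein structure comparison

Proteins are not rigid: hinge motions, domain swaps and other
conformational changes can make two structures of the *same* chain look
very different to rigid-body superposition, while surface self-contacts
defeat global shape descriptors such as inner distances.  `ladkit`
implements the **Local Average Distance (LAD)** descriptor for this
setting: a 1-D profile per chain that captures *local* surface geometry
and is therefore insensitive to rigid motions of whole subdomains.

It is intended for structural bioinformaticians who need to retrieve or
compare conformers of flexible proteins from standard PDB files.

## The method

1. **Surface.** A triangular surface mesh is built over the backbone
   atoms (N, Cα, C, O) — either with the built-in distance-field /
   marching-cubes backend, or imported from MSMS `.vert`/`.face` files —
   and optionally simplified to ~15 % of its faces by quadric
   edge collapse.  Each mesh vertex belongs to its closest backbone atom;
   a residue with at least one vertex is a *surface residue*.

2. **Distances.** Two metrics are averaged up from atoms to residues:
   Euclidean distance (ED) between atom centers, and geodesic distance
   (GD) along the surface.  The GD between atoms *aᵢ*, *aⱼ* with
   associated vertex sets of sizes M, N is

   GD(aᵢ,aⱼ) = (Σₓ Σᵧ GD(vᵢₓ, vⱼᵧ)) / (M·N).

3. **Profile.** For surface residue *i*, LADᵢ is the mean distance from
   residue *i* to its neighbours within a sliding window (default 9
   residues) scanned from the N- to the C-terminus.

4. **Comparison.** Profiles are aligned with a Smith–Waterman local
   alignment whose substitution score decreases with |LADᵢ − LADⱼ|, and
   the pair is scored with the diversity

   LAD_div = 1 − (Nₑ / mean(N_Q, N_S)) · 1 / (1 + (RMSD/D)^α) ∈ [0, 1],

   where Nₑ is the number of aligned residues and RMSD is the RMSD of the
   aligned LAD values.  Lower = more similar.  Trained defaults:
   (D, α) = (1, 4.5) for ED profiles and (1.1, 5) for GD profiles.
   `struct_div` (RMSD / (Nₑ/mean(N_Q,N_S))^1.5) is provided for scoring
   external coordinate-level alignments, and `tune_diversity_params`
   re-fits (D, α) on labelled pair sets over the standard 200 × 9 grid.

Retrieval experiments are evaluated with rank-1 success rate against
group representatives, R-precision, mean average precision, the 11-point
interpolated precision–recall curve, and F1 on the top-64 ranks.

## Worked example

Generate a 60-residue toy helix, bend it 90° at residue 30 (a pure hinge
motion), and compare the two conformers:

```python
import pathlib
import ladkit as lk
from ladkit.structure import to_pdb

chain = lk.make_toy_chain(60, "helix", chain_id="open")
bent  = lk.apply_hinge_bend(chain, 30, 90.0, axis=(0, 1, 0), new_id="closed")
pathlib.Path("open.pdb").write_text(to_pdb(chain))
pathlib.Path("closed.pdb").write_text(to_pdb(bent))
```

```bash
lad compare open.pdb closed.pdb
```

```json
{
  "query": "open:A",
  "subject": "closed:A",
  "metric": "ED",
  "Ne": 60,
  "lad_rmsd": 0.1967487982239081,
  "lad_div": 0.0006642259395768235,
  "NQ": 60,
  "NS": 60
}
```

All 60 residues align (Nₑ = N_Q = N_S), the aligned LAD values differ by
only 0.20 Å RMS — entirely from the handful of windows that straddle the
hinge — and LAD_div ≈ 0.0007 declares the two conformers near-identical
despite the large global motion.  Comparing the helix against an
extended chain of the same length instead yields Nₑ = 0 and
LAD_div = 1.0.

Other entry points: `lad profile` (write a profile TSV), `lad search`
(rank a profile database), `lad synth morph` + `lad eval` (synthetic
hinge-morph benchmark and retrieval metrics), `lad tune` (re-fit D, α).

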