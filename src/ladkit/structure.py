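"""Backbone structure parsing and the profile text format.

The comparison unit throughout the package is a single protein chain reduced
to its backbone atoms (N, CA, C, O).  Side chains are deliberately discarded:
the surface descriptor is built over the backbone only, which makes it
insensitive to side-chain rearrangements and keeps surface meshing cheap.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

BACKBONE_ATOMS = ("N", "CA", "C", "O")
# order used for deterministic tie-breaking when a vertex is equidistant
ATOM_ORDER = {name: i for i, name in enumerate(BACKBONE_ATOMS)}


class ChainNotFoundError(ValueError):
    """Requested chain id has no ATOM records in the input."""


class EmptyStructureError(ValueError):
    """No backbone atoms survive filtering."""


class ProfileFormatError(ValueError):
    """Malformed profile TSV; message names the offending line."""


@dataclass(frozen=True)
class Residue:
    """One residue's backbone atoms.

    ``atoms`` maps an atom tag from {N, CA, C, O} to a 3-vector in Å.
    """

    seq_pos: int
    resname: str
    atoms: dict[str, np.ndarray]
    insertion_code: str = ""

    def __post_init__(self):
        for tag in self.atoms:
            if tag not in ATOM_ORDER:
                raise ValueError(f"unknown backbone atom tag {tag!r}")

    def coords(self) -> np.ndarray:
        """Atom coordinates stacked in N < CA < C < O order, shape (k, 3)."""
        tags = sorted(self.atoms, key=ATOM_ORDER.__getitem__)
        return np.asarray([self.atoms[t] for t in tags], dtype=float)

    def atom_tags(self) -> list[str]:
        return sorted(self.atoms, key=ATOM_ORDER.__getitem__)


@dataclass
class BackboneStructure:
    """An ordered chain of backbone residues, e.g. ``5rsa:A``."""

    id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def seq_positions(self) -> list[int]:
        return [r.seq_pos for r in self.residues]

    def all_coords(self) -> np.ndarray:
        """All backbone atom coordinates, shape (n_atoms, 3)."""
        return np.concatenate([r.coords() for r in self.residues], axis=0)

    def atom_index(self) -> list[tuple[int, str]]:
        """(seq_pos, atom tag) per row of :meth:`all_coords`, same order."""
        out: list[tuple[int, str]] = []
        for r in self.residues:
            out.extend((r.seq_pos, t) for t in r.atom_tags())
        return out

    def validate(self) -> None:
        pos = self.seq_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            # equal seq numbers are allowed only with differing insertion codes
            for a, b in zip(self.residues, self.residues[1:]):
                if (b.seq_pos, b.insertion_code) <= (a.seq_pos, a.insertion_code):
                    raise ValueError("residues out of sequence order")
        if not all(np.isfinite(r.coords()).all() for r in self.residues):
            raise ValueError("non-finite coordinates")


def read_backbone(pdb_source: str, chain: str) -> BackboneStructure:
    """Parse a PDB text into a backbone-only structure for one chain.

    Only standard ``ATOM`` records with atom names N/CA/C/O are kept;
    HETATM records, hydrogens and side chains are dropped.  Alternate
    locations are resolved by highest occupancy and only the first MODEL
    is read.  Residues are ordered by (sequence number, insertion code).

    Parameters
    ----------
    pdb_source:
        PDB-format text (wwPDB v3.3 fixed-width ATOM records).
    chain:
        Chain identifier, e.g. ``"A"``.
    """
    pdb = PDBFile.read(io.StringIO(pdb_source))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    if chain not in set(atoms.chain_id):
        raise ChainNotFoundError(f"chain {chain!r} not found in PDB input")
    mask = (
        (atoms.chain_id == chain)
        & ~atoms.hetero
        & np.isin(atoms.atom_name, BACKBONE_ATOMS)
        & (atoms.element != "H")
    )
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"chain {chain!r} has no backbone atoms")

    by_res: dict[tuple[int, str], dict] = {}
    for i in range(atoms.array_length()):
        key = (int(atoms.res_id[i]), str(atoms.ins_code[i]).strip())
        entry = by_res.setdefault(key, {"resname": str(atoms.res_name[i]), "atoms": {}})
        tag = str(atoms.atom_name[i])
        # altloc duplicates are already resolved; keep first on any residual dup
        entry["atoms"].setdefault(tag, np.array(atoms.coord[i], dtype=float))

    residues = [
        Residue(seq_pos=k[0], resname=v["resname"], atoms=v["atoms"], insertion_code=k[1])
        for k, v in sorted(by_res.items())
    ]
    struct = BackboneStructure(id=chain, residues=residues)
    struct.validate()
    return struct


def to_pdb(structure: BackboneStructure, chain: str = "A") -> str:
    """Serialize a backbone structure as PDB text (for interoperability)."""
    n = sum(len(r.atoms) for r in structure.residues)
    arr = bst.AtomArray(n)
    i = 0
    for r in structure.residues:
        for tag in r.atom_tags():
            arr.coord[i] = r.atoms[tag]
            arr.chain_id[i] = chain
            arr.res_id[i] = r.seq_pos
            arr.ins_code[i] = r.insertion_code
            arr.res_name[i] = r.resname
            arr.atom_name[i] = tag
            arr.element[i] = tag[0]
            arr.hetero[i] = False
            i += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Profile text format
#
# TSV with "#"-prefixed key=value header lines carrying metadata, then a
# column-name row and one row per surface residue.  Chosen for diff-ability.
# ---------------------------------------------------------------------------

_COLUMNS = "seq_pos\tresname\tlad_angstrom"


def write_profile(profile, dest) -> None:
    """Write a LAD profile as TSV.  ``dest`` is a path or text file object."""
    lines = [
        f"# structure_id={profile.structure_id}",
        f"# metric={profile.metric}",
        f"# window={profile.window}",
    ]
    for key, val in sorted(profile.meta.items()):
        lines.append(f"# {key}={val}")
    lines.append(_COLUMNS)
    resnames = profile.resnames or ["UNK"] * len(profile)
    for (pos, value), rn in zip(profile.entries, resnames):
        lines.append(f"{pos}\t{rn}\t{value:.6f}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)


def read_profile(src):
    """Read a profile TSV written by :func:`write_profile`.

    Raises :class:`ProfileFormatError` naming the line number on any
    malformed header or non-numeric value.
    """
    from .profile import LADProfile  # local import to avoid a cycle

    if hasattr(src, "read"):
        text = src.read()
    else:
        with open(src) as fh:
            text = fh.read()

    meta: dict[str, str] = {}
    entries: list[tuple[int, float]] = []
    resnames: list[str] = []
    seen_columns = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise ProfileFormatError(f"line {lineno}: malformed header {line!r}")
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
            continue
        if not seen_columns:
            if line.strip() != _COLUMNS.replace("\t", "\t").strip() and \
               line.split("\t") != _COLUMNS.split("\t"):
                raise ProfileFormatError(f"line {lineno}: expected column header")
            seen_columns = True
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ProfileFormatError(f"line {lineno}: expected 3 columns")
        try:
            pos = int(parts[0])
            value = float(parts[2])
        except ValueError as exc:
            raise ProfileFormatError(f"line {lineno}: non-numeric value") from exc
        entries.append((pos, value))
        resnames.append(parts[1])

    required = {"structure_id", "metric", "window"}
    missing = required - meta.keys()
    if missing:
        raise ProfileFormatError(f"missing header keys: {sorted(missing)}")
    extra = {k: v for k, v in meta.items() if k not in required}
    return LADProfile(
        structure_id=meta["structure_id"],
        metric=meta["metric"],
        window=int(meta["window"]),
        entries=entries,
        resnames=resnames or None,
        meta=extra,
    )
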