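"""PDB-format structure parsing and domain slicing.

Policies (fixed across the pipeline):

* first model only (NMR ensembles collapse to model 1)
* HETATM records, waters and hydrogens are excluded
* for alternate locations the first-listed copy is kept
* residues are keyed by author numbering, insertion code appended
* residue ranges are 1-based and inclusive
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}

_WATERS = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    residue_number: int
    residue_name: str
    coords: tuple[float, float, float]
    b_factor: float
    altloc: str = ""
    icode: str = ""

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class Residue:
    number: int
    icode: str
    name: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """Ordered residues of one chain, with coordinates and B-factors."""

    pdb_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def sequence(self) -> str:
        return domain_sequence(self)

    def coordinates(self) -> np.ndarray:
        """(N_atoms, 3) array of all atom coordinates."""
        return np.array([a.coords for a in self.atoms], dtype=float)


def _is_hydrogen(bio_atom) -> bool:
    elem = (bio_atom.element or "").strip().upper()
    if elem:
        return elem in ("H", "D")
    return bio_atom.get_name().lstrip("0123456789").startswith("H")


def parse_structure(path: str | Path, chain: str) -> Structure:
    """Parse one chain of a PDB file into a :class:`Structure`.

    Only the first model is read; HETATM/waters/hydrogens are dropped and
    the first-listed altloc is kept for disordered atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(parser.get_structure(path.stem, str(path)).get_models())
    chains = {c.id for c in model}
    if chain not in chains:
        raise StructureError(
            f"{path.name}: chain {chain!r} not found; available: {sorted(chains)}"
        )
    residues: list[Residue] = []
    for res in model[chain]:
        hetflag, resseq, icode = res.get_id()
        if hetflag != " " or res.get_resname().strip() in _WATERS:
            continue
        atoms = []
        for at in res.get_unpacked_list():
            if _is_hydrogen(at):
                continue
            altloc = at.get_altloc().strip()
            atoms.append(
                Atom(
                    name=at.get_name(),
                    residue_number=resseq,
                    residue_name=res.get_resname().strip(),
                    coords=tuple(float(x) for x in at.get_coord()),
                    b_factor=float(at.get_bfactor()),
                    altloc=altloc,
                    icode=icode.strip(),
                )
            )
        # keep first-listed altloc copy per atom name
        seen: dict[str, Atom] = {}
        for a in atoms:
            seen.setdefault(a.name, a)
        kept = tuple(seen.values())
        if kept:
            residues.append(
                Residue(
                    number=resseq,
                    icode=icode.strip(),
                    name=res.get_resname().strip(),
                    atoms=kept,
                )
            )
    return Structure(pdb_id=path.stem.lower(), chain_id=chain, residues=residues)


def slice_domain(s: Structure, start: int, end: int) -> Structure:
    """Residues with start <= author number <= end (inclusive).

    Missing residues inside the range are tolerated; an empty result is an
    error ("range outside chain").
    """
    if start > end:
        raise StructureError(f"invalid range {start}..{end}")
    kept = [r for r in s.residues if start <= r.number <= end]
    if not kept:
        raise StructureError(
            f"{s.pdb_id}/{s.chain_id}: range {start}..{end} outside chain"
        )
    return Structure(pdb_id=s.pdb_id, chain_id=s.chain_id, residues=kept)


def domain_sequence(s: Structure) -> str:
    """One-letter sequence; nonstandard residues (e.g. MSE) map to 'X'."""
    if not s.residues:
        raise StructureError("empty structure")
    return "".join(r.one_letter for r in s.residues)


def ca_coordinates(s: Structure) -> list[tuple[int, np.ndarray]]:
    """(residue_number, xyz) for every residue that has a CA atom, in order."""
    out = []
    for r in s.residues:
        ca = r.atom("CA")
        if ca is not None:
            out.append((r.number, ca.xyz))
    return out


def write_pdb(s: Structure, path: str | Path) -> None:
    """Serialize a structure as minimal fixed-column PDB ATOM records."""
    with open(path, "w") as fh:
        serial = 1
        for res in s.residues:
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.coords
                fh.write(
                    f"ATOM  {serial:5d} {name}{a.altloc or ' '}"
                    f"{res.name:>3s} {s.chain_id}{res.number:4d}{res.icode or ' '}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{a.b_factor:6.2f}"
                    f"          {a.name[0]:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


def write_fasta(s: Structure, path: str | Path, start: int | None = None, end: int | None = None) -> None:
    start = start if start is not None else s.residues[0].number
    end = end if end is not None else s.residues[-1].number
    with open(path, "w") as fh:
        fh.write(f">{s.pdb_id}_{s.chain_id}/{start}-{end}\n")
        seq = domain_sequence(s)
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
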