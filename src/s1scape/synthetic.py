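"""Synthetic fixtures with exactly known ground truth.

Generated structures are geometric toys, not proteins: only the measured
quantities matter (radius of gyration, B-factor class counts, sequence).
All generators are deterministic under an explicit seed.

PDB coordinate fields carry three decimals, so a free-form random cloud
rescaled to a target radius of gyration would drift by ~1e-3 Å once
written and re-parsed.  Toy structures therefore place every atom at
exactly ``target_rg`` from the centroid, in antipodal pairs along the
coordinate axes: the centroid is exactly zero and the parsed Rg equals the
target to floating-point precision, provided the target itself is
representable at three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from s1scape.structure import Atom, Residue, Structure

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

_ATOM_NAMES = ("N", "CA", "C", "O")


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    n_residues: int = 70
    target_rg: float = 12.0
    flexible_fraction: float = 0.2
    seed: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise FixtureError("need at least 5 residues")
        if not 0.0 <= self.flexible_fraction <= 1.0:
            raise FixtureError("flexible_fraction must be in [0, 1]")
        if self.target_rg <= 0:
            raise FixtureError("target_rg must be positive")
        if self.target_rg >= 999.0:
            raise FixtureError("target_rg too large for PDB coordinate fields")
        if round(self.target_rg, 3) != self.target_rg:
            raise FixtureError(
                "target_rg must be representable at PDB precision (3 decimals)"
            )


def _bfactor_column(
    n: int, flexible_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """B-factors whose within-domain z-scores flag exactly k residues flexible.

    With k high values and n-k low values the high-value z-score is
    sqrt((n-k)/k), which exceeds 1 only for k < n/2; larger fractions are
    unreachable under the z > 1 rule and raise.
    """
    k = round(flexible_fraction * n)
    if k >= n / 2.0 and k > 0:
        raise FixtureError(
            f"flexible_fraction {flexible_fraction} gives {k}/{n} flexible "
            "residues; z > 1 cannot flag half the domain or more"
        )
    b = np.empty(n)
    if k == 0:
        # two-level split p >= q puts the high z at sqrt(q/p) <= 1 (moderate)
        p = (n + 1) // 2
        b[:p] = 30.0
        b[p:] = 10.0
    else:
        b[:] = 10.0
        b[:k] = 60.0
    order = rng.permutation(n)
    return b[order], k


def _exact_rg_coordinates(n_atoms: int, rg: float, rng: np.random.Generator) -> np.ndarray:
    """Antipodal axis-aligned points, all at distance rg from an exact centroid."""
    if n_atoms % 2:
        raise FixtureError("internal: atom count must be even")
    half = n_atoms // 2
    axes = rng.integers(0, 3, size=half)
    pts = np.zeros((n_atoms, 3))
    for i, ax in enumerate(axes):
        pts[2 * i, ax] = rg
        pts[2 * i + 1, ax] = -rg
    order = rng.permutation(n_atoms)
    return pts[order]


def make_toy_structure(
    spec: FixtureSpec, path: str | Path | None = None
) -> tuple[Structure, dict]:
    """Toy single-chain structure with exactly known Rg, sequence and B-factors.

    Returns the structure plus a ground-truth dict; writes a PDB file (and a
    sidecar ``.truth.tsv``) when ``path`` is given.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    seq = spec.sequence or "".join(rng.choice(list(AMINO_ACIDS), size=n))
    if len(seq) != n:
        raise FixtureError("sequence length must equal n_residues")

    coords = _exact_rg_coordinates(4 * n, spec.target_rg, rng)
    bfac, k = _bfactor_column(n, spec.flexible_fraction, rng)

    residues = []
    for i in range(n):
        resname = _ONE_TO_THREE[seq[i]]
        atoms = tuple(
            Atom(
                name=name,
                residue_number=i + 1,
                residue_name=resname,
                coords=tuple(float(x) for x in coords[4 * i + j]),
                b_factor=float(bfac[i]),
            )
            for j, name in enumerate(_ATOM_NAMES)
        )
        residues.append(Residue(number=i + 1, icode="", name=resname, atoms=atoms))
    s = Structure(pdb_id=f"toy{spec.seed}", chain_id="A", residues=residues)

    truth = {
        "n_residues": n,
        "sequence": seq,
        "target_rg": spec.target_rg,
        "n_flexible": k,
        "flexible_fraction": spec.flexible_fraction,
        "seed": spec.seed,
    }
    if path is not None:
        write_fixture_pdb(s, path)
        Path(str(path) + ".truth.tsv").write_text(
            "".join(f"{key}\t{val}\n" for key, val in truth.items())
        )
    return s, truth


def write_fixture_pdb(s: Structure, path: str | Path) -> None:
    """Serialize a toy structure as standard fixed-column PDB ATOM records."""
    with open(path, "w") as fh:
        serial = 1
        for res in s.residues:
            for a in res.atoms:
                x, y, z = a.coords
                fh.write(
                    f"ATOM  {serial:5d}  {a.name:<3s} {res.name:>3s} {s.chain_id}"
                    f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.0:6.2f}{a.b_factor:6.2f}          {a.name[0]:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


def make_sequence_pair(
    length: int, pair_identity: float, seed: int = 0
) -> tuple[str, str]:
    """Equal-length pair differing at exactly round((1-identity)*length) sites."""
    if not 0.0 <= pair_identity <= 1.0:
        raise FixtureError("pair_identity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    first = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    n_mut = round((1.0 - pair_identity) * length)
    positions = rng.choice(length, size=n_mut, replace=False)
    second = list(first)
    for pos in positions:
        choices = [c for c in AMINO_ACIDS if c != first[pos]]
        second[pos] = choices[rng.integers(len(choices))]
    return first, "".join(second)


def make_group_samples(
    sizes: list[int], shift: float = 0.0, seed: int = 0
) -> list[np.ndarray]:
    """Groups drawn from a normal distribution, group i location-shifted by i*shift."""
    if len(sizes) < 2:
        raise FixtureError("need at least two groups")
    rng = np.random.default_rng(seed)
    return [rng.normal(loc=i * shift, size=sz) for i, sz in enumerate(sizes)]
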