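"""Rigid-body superposition, RMSD matrices and radius of gyration.

Superposition is the closed-form least-squares (Kabsch) solution via SVD of
the cross-covariance matrix, with the determinant sign fixed so the result
is a proper rotation.  Residue correspondence for structure pairs comes
from the ungapped columns of a global sequence alignment of the two
domains' one-letter sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from s1scape.seqcompare import GAP, ScoringScheme, global_align
from s1scape.structure import Structure, ca_coordinates, domain_sequence

log = logging.getLogger(__name__)

MIN_MATCHED_PAIRS = 10


class SuperpositionError(ValueError):
    pass


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_pairs: int
    warning: str | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(x: np.ndarray, y: np.ndarray) -> Superposition:
    """Least-squares superposition of paired point sets; moves x onto y.

    Requires >= 3 non-collinear pairs.  The returned transform minimizes
    sum ||R x_i + t - y_i||^2; rmsd is evaluated after transforming.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise SuperpositionError("inputs must be matching (N, 3) arrays")
    n = x.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 pairs, got {n}")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) point set")
    cov = x0.T @ y0
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def pairwise_rmsd(
    a: Structure, b: Structure, sc: ScoringScheme | None = None
) -> Superposition:
    """CA RMSD of two domains with sequence-alignment correspondence.

    CA pairs are taken at columns of the global alignment where both rows
    carry a residue (and both residues have a CA atom).  Fewer than
    ``MIN_MATCHED_PAIRS`` matches attaches a warning but still returns.
    """
    sc = sc or ScoringScheme()
    aln = global_align(domain_sequence(a), domain_sequence(b), sc)
    ca_a = ca_coordinates(a)
    ca_b = ca_coordinates(b)
    # map sequence index -> CA xyz (sequence order == residue order; residues
    # without CA are absent from ca_coordinates, so index via residue walk)
    idx_a = _ca_by_sequence_index(a)
    idx_b = _ca_by_sequence_index(b)
    del ca_a, ca_b
    pa, pb = [], []
    i = j = 0
    for x, y in zip(aln.gapped_a, aln.gapped_b):
        if x != GAP and y != GAP:
            if i in idx_a and j in idx_b:
                pa.append(idx_a[i])
                pb.append(idx_b[j])
        if x != GAP:
            i += 1
        if y != GAP:
            j += 1
    sup = kabsch_superpose(np.array(pa), np.array(pb))
    if sup.n_pairs < MIN_MATCHED_PAIRS:
        sup.warning = (
            f"{a.pdb_id}/{b.pdb_id}: only {sup.n_pairs} matched CA pairs"
        )
        log.warning(sup.warning)
    return sup


def _ca_by_sequence_index(s: Structure) -> dict[int, np.ndarray]:
    out = {}
    for i, res in enumerate(s.residues):
        ca = res.atom("CA")
        if ca is not None:
            out[i] = ca.xyz
    return out


@dataclass
class RmsdMatrix:
    labels: list[str]
    matrix: np.ndarray
    reference: str | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_pairwise(self) -> float:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return float(self.matrix[iu].mean())

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def multiple_superpose(
    group: dict[str, Structure], sc: ScoringScheme | None = None
) -> tuple[RmsdMatrix, dict[str, np.ndarray]]:
    """All-vs-all CA RMSD; everything superposed onto the medoid reference.

    Returns the symmetric matrix plus CA coordinates of each structure in
    the medoid's frame.
    """
    if len(group) < 2:
        raise ValueError("need at least two structures")
    sc = sc or ScoringScheme()
    labels = list(group)
    n = len(labels)
    mat = np.zeros((n, n))
    warns: list[str] = []
    sups: dict[tuple[int, int], Superposition] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sup = pairwise_rmsd(group[labels[i]], group[labels[j]], sc)
            mat[i, j] = mat[j, i] = sup.rmsd
            sups[(i, j)] = sup
            if sup.warning:
                warns.append(sup.warning)
    medoid = int(np.argmin(mat.sum(axis=1)))
    frames: dict[str, np.ndarray] = {}
    for i, lab in enumerate(labels):
        coords = np.array([xyz for _, xyz in ca_coordinates(group[lab])])
        if i == medoid:
            frames[lab] = coords
        else:
            a, b = min(i, medoid), max(i, medoid)
            sup = sups[(a, b)]
            if i < medoid:  # stored transform moves i onto medoid
                frames[lab] = sup.apply(coords)
            else:  # invert: transform moves medoid onto i
                frames[lab] = (coords - sup.translation) @ sup.rotation
    return (
        RmsdMatrix(labels=labels, matrix=mat, reference=labels[medoid], warnings=warns),
        frames,
    )


def radius_of_gyration(s: Structure) -> float:
    """Unweighted RMS distance of non-hydrogen atoms from their centroid (Å)."""
    coords = s.coordinates()
    if coords.size == 0:
        raise ValueError("structure has no atoms")
    center = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=1))))
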