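"""Global pairwise alignment, identity matrices, progressive MSA and logos.

The aligner is a three-state Gotoh dynamic program with affine gap
penalties.  A gap of length L costs ``gap_open + (L - 1) * gap_extend``;
end gaps are penalized (true global mode).  Traceback tie-breaking is
deterministic: diagonal, then up (gap in the second sequence), then left.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

NEG_INF = float("-inf")

GAP = "-"


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix + affine gap penalties (penalties are >= 0)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    def score(self, a: str, b: str) -> float:
        """Substitution score; 'X' scores 0 against everything."""
        if a == "X" or b == "X":
            return 0.0
        m = _load_matrix(self.matrix_name)
        try:
            return float(m[a, b])
        except (KeyError, IndexError):
            return 0.0


@dataclass(frozen=True)
class PairwiseAlignment:
    gapped_a: str
    gapped_b: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped rows differ in length")

    @property
    def length(self) -> int:
        return len(self.gapped_a)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for x, y in zip(self.gapped_a, self.gapped_b) if x == y and x != GAP
        )


def percent_identity(gapped_a: str, gapped_b: str, denominator: str = "alignment") -> float:
    """Percent identity of two gapped rows.

    denominator 'alignment' uses full alignment length (including gap
    columns); 'shorter' uses the shorter ungapped sequence length.
    """
    n_id = sum(1 for x, y in zip(gapped_a, gapped_b) if x == y and x != GAP)
    if denominator == "alignment":
        denom = len(gapped_a)
    elif denominator == "shorter":
        denom = min(
            len(gapped_a.replace(GAP, "")), len(gapped_b.replace(GAP, ""))
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * n_id / denom


def global_align(
    a: str, b: str, sc: ScoringScheme | None = None, denominator: str = "alignment"
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine gap penalties."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    sc = sc or ScoringScheme()
    n, m = len(a), len(b)
    go, ge = sc.gap_open, sc.gap_extend

    # state matrices: M diagonal, X gap-in-b (up), Y gap-in-a (left)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + (j - 1) * ge)

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sc.score(ai, b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)

    # traceback; state priority M > X > Y realizes diagonal > up > left
    i, j = n, m
    finals = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}
    best = max(finals.values())
    state = next(k for k in ("M", "X", "Y") if finals[k] == best)
    ga: list[str] = []
    gb: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            s = sc.score(a[i - 1], b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            cands = {"M": M[i, j], "X": X[i, j], "Y": Y[i, j]}
        elif state == "X":
            ga.append(a[i - 1])
            gb.append(GAP)
            here = X[i, j]
            i -= 1
            cands = {"M": M[i, j] - go, "X": X[i, j] - ge, "Y": Y[i, j] - go}
            target = here
        else:
            ga.append(GAP)
            gb.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            cands = {"M": M[i, j] - go, "X": X[i, j] - go, "Y": Y[i, j] - ge}
            target = here
        if i == 0 and j == 0:
            break
        state = next(
            k
            for k in ("M", "X", "Y")
            if np.isfinite(cands[k]) and abs(cands[k] - target) < 1e-9
        )
    ga.reverse()
    gb.reverse()
    gapped_a, gapped_b = "".join(ga), "".join(gb)
    return PairwiseAlignment(
        gapped_a=gapped_a,
        gapped_b=gapped_b,
        score=float(best),
        identity_pct=percent_identity(gapped_a, gapped_b, denominator),
    )


@dataclass
class IdentityReport:
    """Symmetric percent-identity matrix with same-protein-aware extrema."""

    labels: list[str]
    matrix: np.ndarray
    max_pair: tuple[str, str, float] | None = None
    min_pair: tuple[str, str, float] | None = None

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def identity_matrix(
    seqs: dict[str, str],
    sc: ScoringScheme | None = None,
    exclusions: dict[str, str | None] | None = None,
    denominator: str = "alignment",
) -> IdentityReport:
    """All-vs-all percent identity.

    ``exclusions`` maps label -> same-protein group; pairs sharing a
    non-None group are skipped when reporting the max/min pair (their
    matrix entries are still computed).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    sc = sc or ScoringScheme()
    labels = list(seqs)
    n = len(labels)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[labels[i]], seqs[labels[j]], sc, denominator)
            mat[i, j] = mat[j, i] = aln.identity_pct
    groups = exclusions or {}
    max_pair = min_pair = None
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = groups.get(labels[i]), groups.get(labels[j])
            if gi is not None and gi == gj:
                continue
            v = mat[i, j]
            if max_pair is None or v > max_pair[2]:
                max_pair = (labels[i], labels[j], float(v))
            if min_pair is None or v < min_pair[2]:
                min_pair = (labels[i], labels[j], float(v))
    return IdentityReport(labels=labels, matrix=mat, max_pair=max_pair, min_pair=min_pair)


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile_align(
    rows_a: list[str], rows_b: list[str], sc: ScoringScheme
) -> tuple[list[str], list[str]]:
    """Gotoh profile-profile alignment; column score = mean of residue-pair scores."""
    na, nb = len(rows_a[0]), len(rows_b[0])
    cols_a = [[r[i] for r in rows_a] for i in range(na)]
    cols_b = [[r[j] for r in rows_b] for j in range(nb)]

    def colscore(ca: list[str], cb: list[str]) -> float:
        tot, cnt = 0.0, 0
        for x in ca:
            for y in cb:
                cnt += 1
                if x != GAP and y != GAP:
                    tot += sc.score(x, y)
        return tot / cnt if cnt else 0.0

    go, ge = sc.gap_open, sc.gap_extend
    M = np.full((na + 1, nb + 1), NEG_INF)
    X = np.full((na + 1, nb + 1), NEG_INF)
    Y = np.full((na + 1, nb + 1), NEG_INF)
    ptr = np.zeros((na + 1, nb + 1, 3), dtype=np.int8)  # back-state per state
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = -(go + (i - 1) * ge)
        ptr[i, 0, 1] = 1 if i > 1 else 0
    for j in range(1, nb + 1):
        Y[0, j] = -(go + (j - 1) * ge)
        ptr[0, j, 2] = 2 if j > 1 else 0
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = colscore(cols_a[i - 1], cols_b[j - 1])
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(prev))
            M[i, j] = prev[k] + s
            ptr[i, j, 0] = k
            up = (M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            k = int(np.argmax(up))
            X[i, j] = up[k]
            ptr[i, j, 1] = k
            left = (M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
            k = int(np.argmax(left))
            Y[i, j] = left[k]
            ptr[i, j, 2] = k

    finals = (M[na, nb], X[na, nb], Y[na, nb])
    state = int(np.argmax(finals))
    i, j = na, nb
    ops: list[int] = []  # 0 diag, 1 up, 2 left
    while i > 0 or j > 0:
        ops.append(state)
        prev_state = int(ptr[i, j, state])
        if state == 0:
            i, j = i - 1, j - 1
        elif state == 1:
            i -= 1
        else:
            j -= 1
        state = prev_state
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in (0, 1):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in (0, 2):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def progressive_msa(
    seqs: dict[str, str], sc: ScoringScheme | None = None
) -> dict[str, str]:
    """Progressive multiple alignment guided by a UPGMA tree on identity distances.

    Returns a mapping label -> gapped row (all rows equal length; ungapping a
    row recovers its input sequence).
    """
    from s1scape.phylo import DistanceMatrix, upgma_tree

    sc = sc or ScoringScheme()
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    if len(labels) == 2:
        aln = global_align(seqs[labels[0]], seqs[labels[1]], sc)
        return {labels[0]: aln.gapped_a, labels[1]: aln.gapped_b}

    rep = identity_matrix(seqs, sc)
    dist = DistanceMatrix(labels=rep.labels, matrix=1.0 - rep.matrix / 100.0)
    np.fill_diagonal(dist.matrix, 0.0)
    tree = upgma_tree(dist)

    def build(node) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [node.label], [seqs[node.label]]
        (la, ra), (lb, rb) = build(node.children[0]), build(node.children[1])
        out_a, out_b = _profile_align(ra, rb, sc)
        return la + lb, out_a + out_b

    names, rows = build(tree)
    return dict(zip(names, rows))


# ---------------------------------------------------------------------------
# logos and conservation

LOG2_20 = float(np.log2(20.0))


@dataclass
class LogoMatrix:
    """Per-column non-gap residue frequencies and information content (bits)."""

    frequencies: list[dict[str, float]]
    information: np.ndarray

    def __len__(self) -> int:
        return len(self.frequencies)


def logo_information(msa: dict[str, str] | list[str]) -> LogoMatrix:
    rows = list(msa.values()) if isinstance(msa, dict) else list(msa)
    if not rows or not rows[0]:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows differ in length")
    freqs: list[dict[str, float]] = []
    info = np.zeros(width)
    for c in range(width):
        col = [r[c] for r in rows if r[c] != GAP]
        if not col:
            freqs.append({})
            info[c] = 0.0
            continue
        counts: dict[str, int] = {}
        for x in col:
            counts[x] = counts.get(x, 0) + 1
        f = {k: v / len(col) for k, v in sorted(counts.items())}
        h = -sum(p * np.log2(p) for p in f.values())
        freqs.append(f)
        info[c] = max(0.0, LOG2_20 - h)
    return LogoMatrix(frequencies=freqs, information=info)


def conserved_positions(
    msa: dict[str, str] | list[str], threshold: float = 0.8
) -> list[tuple[int, str, float]]:
    """Columns (1-based) whose modal non-gap residue frequency >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    logo = logo_information(msa)
    out = []
    for c, f in enumerate(logo.frequencies, start=1):
        if not f:
            continue
        residue, freq = max(f.items(), key=lambda kv: (kv[1], kv[0]))
        if freq >= threshold:
            out.append((c, residue, freq))
    return out


def sp_score(rows: list[str], sc: ScoringScheme) -> float:
    """Sum-of-pairs score of an alignment under the scheme's gap penalties.

    Every row pair is projected (gap-gap columns dropped) and scored as a
    pairwise alignment with affine gaps.
    """
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            cols = [(x, y) for x, y in zip(a, b) if not (x == GAP and y == GAP)]
            in_gap_a = in_gap_b = False
            for x, y in cols:
                if x != GAP and y != GAP:
                    total += sc.score(x, y)
                    in_gap_a = in_gap_b = False
                elif x == GAP:
                    total -= sc.gap_extend if in_gap_a else sc.gap_open
                    in_gap_a, in_gap_b = True, False
                else:
                    total -= sc.gap_extend if in_gap_b else sc.gap_open
                    in_gap_b, in_gap_a = True, False
    return total
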