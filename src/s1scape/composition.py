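"""Order/disorder-promoting residue composition and the Kruskal-Wallis test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

ORDER_SET = frozenset("CWFIYVLHTN")
DISORDER_SET = frozenset("DMARGQSPEK")

assert ORDER_SET.isdisjoint(DISORDER_SET)
assert len(ORDER_SET | DISORDER_SET) == 20


class CompositionError(ValueError):
    pass


def _classified_counts(seq: str) -> tuple[int, int]:
    seq = seq.upper()
    if not seq:
        raise CompositionError("empty sequence")
    n_dis = sum(1 for c in seq if c in DISORDER_SET)
    n_ord = sum(1 for c in seq if c in ORDER_SET)
    if n_dis + n_ord == 0:
        raise CompositionError("no classifiable residues (all 'X'?)")
    return n_dis, n_ord


def disorder_content(seq: str) -> float:
    """Percent disorder-promoting residues; 'X' excluded from both sides."""
    n_dis, n_ord = _classified_counts(seq)
    return 100.0 * n_dis / (n_dis + n_ord)


def order_content(seq: str) -> float:
    n_dis, n_ord = _classified_counts(seq)
    return 100.0 * n_ord / (n_dis + n_ord)


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float
    group_sizes: tuple[int, ...]


def kruskal_wallis(groups: list) -> KWResult:
    """Kruskal-Wallis H with mid-ranks for ties and tie correction.

    H = [12 / (N (N+1))] * sum n_i (Rbar_i - (N+1)/2)^2, divided by
    1 - sum(t^3 - t) / (N^3 - N); p is the upper tail of chi-square with
    k - 1 degrees of freedom.
    """
    if len(groups) < 2:
        raise CompositionError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise CompositionError("empty group")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise CompositionError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        raise CompositionError("no rank variation (all values identical)")
    ranks = rankdata(pooled)  # mid-ranks for ties
    h = 0.0
    pos = 0
    for a in arrays:
        r = ranks[pos : pos + a.size]
        pos += a.size
        h += a.size * (r.mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n_total**3 - n_total)
    h /= correction
    df = len(arrays) - 1
    p = float(chi2.sf(h, df))
    return KWResult(H=float(h), df=df, p=p, group_sizes=tuple(a.size for a in arrays))


def kruskal_wallis_permutation(
    groups: list, n_perm: int = 10000, seed: int = 0
) -> KWResult:
    """Permutation p-value variant for small groups (same H statistic)."""
    base = kruskal_wallis(groups)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = base.group_sizes
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts, pos = [], 0
        for sz in sizes:
            parts.append(perm[pos : pos + sz])
            pos += sz
        try:
            if kruskal_wallis(parts).H >= base.H - 1e-12:
                count += 1
        except CompositionError:
            count += 1  # all-identical permutation cannot exceed anything real
    p = (count + 1) / (n_perm + 1)
    return KWResult(H=base.H, df=base.df, p=p, group_sizes=sizes)
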