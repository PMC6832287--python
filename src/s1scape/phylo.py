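"""Identity-distance dendrograms: UPGMA clustering and Newick output."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise PhyloError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise PhyloError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise PhyloError("distance matrix must have zero diagonal")
        if np.any(self.matrix < -1e-12):
            raise PhyloError("distances must be nonnegative")

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def distance_from_identity(labels: list[str], identity_pct: np.ndarray) -> DistanceMatrix:
    """d = 1 - identity/100, with an exactly zero diagonal."""
    m = 1.0 - np.asarray(identity_pct, dtype=float) / 100.0
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels=list(labels), matrix=m)


@dataclass
class TreeNode:
    """Rooted ultrametric tree node; height is distance from the leaves."""

    label: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def newick(self, precision: int = 6) -> str:
        if self.is_leaf():
            return f"{self.label};"
        inner = ",".join(c._newick_inner(self.height, precision) for c in self.children)
        return f"({inner});"

    def _newick_inner(self, parent_height: float, precision: int) -> str:
        blen = parent_height - self.height
        if self.is_leaf():
            return f"{self.label}:{blen:.{precision}f}"
        inner = ",".join(c._newick_inner(self.height, precision) for c in self.children)
        return f"({inner}):{blen:.{precision}f}"


def upgma_tree(d: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) clustering with lexicographic tie-breaking.

    Join heights are half the average-linkage distance, so leaf-to-root
    path lengths are ultrametric and cophenetic distances reproduce an
    ultrametric input exactly.
    """
    n = len(d.labels)
    if n < 2:
        raise PhyloError("need at least two leaves")
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(label=lab, height=0.0) for lab in d.labels
    }
    sizes = {lab: 1 for lab in d.labels}
    sort_key = {lab: lab for lab in d.labels}  # lexicographically least leaf
    dist: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((d.labels[i], d.labels[j]))] = float(d.matrix[i, j])
    active = list(d.labels)
    counter = 0
    while len(active) > 1:
        best = None  # (distance, lexicographic key, a, b)
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                key = tuple(sorted((sort_key[a], sort_key[b])))
                cand = (dist[frozenset((a, b))], key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dmin, _, a, b = best
        counter += 1
        new_id = f"_internal{counter}"
        parent = TreeNode(label=None, height=dmin / 2.0, children=[nodes[a], nodes[b]])
        nodes[new_id] = parent
        sizes[new_id] = sizes[a] + sizes[b]
        sort_key[new_id] = min(sort_key[a], sort_key[b])
        for other in active:
            if other in (a, b):
                continue
            da = dist[frozenset((a, other))]
            db = dist[frozenset((b, other))]
            dist[frozenset((new_id, other))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        active = [x for x in active if x not in (a, b)] + [new_id]
    root = nodes[active[0]]
    return root


def cophenetic_matrix(tree: TreeNode, labels: list[str]) -> np.ndarray:
    """Pairwise cophenetic distances (2 x height of the lowest common ancestor)."""
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros((n, n))

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf():
            return [node.label]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la in groups[gi]:
                    for lb in groups[gj]:
                        v = 2.0 * node.height
                        out[index[la], index[lb]] = v
                        out[index[lb], index[la]] = v
        return [l for g in groups for l in g]

    walk(tree)
    return out


def write_newick(tree: TreeNode, path: str | Path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(precision) + "\n")


def read_newick(path_or_text: str | Path) -> TreeNode:
    """Parse the Newick dialect produced by :func:`write_newick`."""
    text = str(path_or_text)
    p = Path(text) if len(text) < 4096 and "\n" not in text and "(" not in text else None
    if p is not None and p.exists():
        text = p.read_text()
    text = text.strip()
    if not text.endswith(";"):
        raise PhyloError("Newick text must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        children = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child, blen = parse_node()
                child._blen = blen  # stashed; heights resolved after parse
                children.append(child)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos] or None
        blen = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            blen = float(s[start:pos])
        return TreeNode(label=label, children=children), blen

    root, _ = parse_node()

    def fix_heights(node: TreeNode) -> float:
        if node.is_leaf():
            node.height = 0.0
            return 0.0
        depths = [fix_heights(c) + c._blen for c in node.children]
        node.height = max(depths)
        return node.height

    fix_heights(root)
    return root


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Classic NJ, re-rooted at the last join; for exploratory use only.

    The result is generally NOT ultrametric; heights are set from branch
    lengths and may be unbalanced.
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise PhyloError("need at least two leaves")
    if n == 2:
        h = float(d.matrix[0, 1]) / 2.0
        return TreeNode(
            height=h,
            children=[TreeNode(label=labels[0]), TreeNode(label=labels[1])],
        )
    mat = {frozenset((a, b)): float(d.value(a, b)) for a in labels for b in labels if a != b}
    nodes = {lab: TreeNode(label=lab) for lab in labels}
    depth = {lab: 0.0 for lab in labels}
    active = list(labels)
    counter = 0
    while len(active) > 2:
        m = len(active)
        totals = {a: sum(mat[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * mat[frozenset((a, b))] - totals[a] - totals[b]
                cand = (q, tuple(sorted((a, b))))
                if best is None or cand < best[:2]:
                    best = (q, cand[1], a, b)
        _, _, a, b = best
        dab = mat[frozenset((a, b))]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        counter += 1
        new_id = f"_nj{counter}"
        parent = TreeNode(children=[nodes[a], nodes[b]])
        parent.height = max(depth[a] + la, depth[b] + lb)
        nodes[new_id] = parent
        depth[new_id] = parent.height
        for other in active:
            if other in (a, b):
                continue
            dnew = 0.5 * (
                mat[frozenset((a, other))] + mat[frozenset((b, other))] - dab
            )
            mat[frozenset((new_id, other))] = max(dnew, 0.0)
        active = [x for x in active if x not in (a, b)] + [new_id]
    a, b = active
    h = depth[a] + depth[b] + mat[frozenset((a, b))]
    root = TreeNode(children=[nodes[a], nodes[b]], height=max(depth[a], depth[b]) + mat[frozenset((a, b))] / 2)
    return root
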