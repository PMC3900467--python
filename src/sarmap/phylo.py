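"""Neighbor-joining trees, Newick I/O and patristic distances.

Classic Saitou–Nei neighbor joining: iteratively join the pair minimizing the
Q-criterion, with branch lengths from the standard formulas; the final three
nodes are joined in one unrooted trifurcation (no outgroup root).  Negative
branch lengths are retained by default; an optional mode clamps them to zero
and transfers the length to the sibling branch.

Trees are :class:`skbio.TreeNode` objects, so Newick I/O and tree comparison
interoperate with the wider phylogenetics ecosystem.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "write_newick",
    "read_newick",
    "patristic_matrix",
    "read_phylip_distances",
]


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Build an unrooted NJ tree from a distance matrix.

    Ties on the Q-criterion are broken by the lowest (i, j) pair in the
    current node order (original label order, merged nodes appended), so the
    output is deterministic.  Returns a tree whose root is the final
    degree-3 join.
    """
    n0 = len(dm)
    if n0 < 3:
        raise ValueError(f"neighbor joining needs >= 3 labels, got {n0}")
    if not np.isfinite(dm.values).all():
        raise ValueError("non-finite distance entries")

    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]

    def _attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        child.length = float(length)
        parent.append(child)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        q = (n - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(n, 1)
        flat = np.argmin(q[iu])  # first minimum in row-major (i, j) order
        i, j = int(iu[0][flat]), int(iu[1][flat])
        d_ij = D[i, j]
        li = d_ij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d_ij - li
        if clamp_negative:
            if li < 0:
                li, lj = 0.0, d_ij
            elif lj < 0:
                li, lj = d_ij, 0.0
        parent = TreeNode()
        _attach(parent, nodes[i], li)
        _attach(parent, nodes[j], lj)
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(n) if k not in (i, j)]
        m = len(keep)
        D2 = np.zeros((m + 1, m + 1))
        D2[:m, :m] = D[np.ix_(keep, keep)]
        D2[m, :m] = D2[:m, m] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    la = (d_ab + d_ac - d_bc) / 2.0
    lb = (d_ab + d_bc - d_ac) / 2.0
    lc = (d_ac + d_bc - d_ab) / 2.0
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        _attach(root, node, length)
    return root


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize to Newick; writes to ``path`` when given, always returns text."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(source) -> TreeNode:
    """Parse Newick text, a file path, or an open handle."""
    if isinstance(source, str) and "(" in source:
        source = io.StringIO(source)
    elif isinstance(source, (str, Path)):
        source = io.StringIO(Path(source).read_text())
    return TreeNode.read(source, format="newick")


def patristic_matrix(tree: TreeNode, normalize: bool = False) -> DistanceMatrix:
    """Leaf-to-leaf path-length sums; optionally scaled so the maximum is 1.

    Normalization reproduces the conventional 0–1 sequence-distance scale of
    published kinome trees.
    """
    sk = tree.tip_tip_distances()
    order = np.argsort(np.asarray(sk.ids))
    ids = tuple(np.asarray(sk.ids)[order])
    values = sk.data[np.ix_(order, order)]
    name = "patristic"
    if normalize:
        mx = values.max()
        if mx > 0:
            values = values / mx
        name = "patristic_normalized"
    return DistanceMatrix(ids, values, name)


def read_phylip_distances(source, metric_name: str = "") -> DistanceMatrix:
    """Read a square PHYLIP distance file (count line, then name + row)."""
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(tuple(labels), np.asarray(rows), metric_name)
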