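"""Pairwise genetic distances and neighbor-joining trees with Newick output.

The distance is the allele-sharing p-distance: the proportion of
mismatching calls among sites where both samples are called.  The tree is
built with the Saitou–Nei neighbor-joining algorithm; ties in the
Q-criterion are broken by the lowest index pair and negative branch
lengths are clamped to zero with the deficit moved to the sister branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants_io import ALT, GenotypeMatrix, REF

__all__ = ["DistanceMatrix", "distance_matrix", "TreeNode", "neighbor_joining"]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, proportion scale
    co_called: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")


def distance_matrix(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> DistanceMatrix:
    """Pairwise mismatch proportion over co-called sites (haploid calls)."""
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    names = [gm.samples[i] for i in sample_idx]
    calls = gm.calls[:, sample_idx]
    called = (calls == REF) | (calls == ALT)
    is_alt = (calls == ALT).astype(np.int16)
    n = len(names)
    d = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {names[i]!r} and {names[j]!r} share no co-called sites"
                )
            mism = int((is_alt[both, i] != is_alt[both, j]).sum())
            d[i, j] = d[j, i] = mism / m
            shared[i, j] = shared[j, i] = m
    return DistanceMatrix(ids=names, d=d, co_called=shared)


@dataclass
class TreeNode:
    """Node of an unrooted (stored rooted at an arbitrary internal node) tree."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def to_newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_part() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf path length matrix (for additivity checks)."""
        names = [l.name for l in self.leaves()]
        out = pd.DataFrame(0.0, index=names, columns=names)

        def walk(node):
            # returns {leaf_name: distance to this node}
            if node.is_leaf():
                return {node.name: 0.0}
            groups = []
            for c in node.children:
                sub = walk(c)
                groups.append({k: v + c.length for k, v in sub.items()})
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for n1, d1 in groups[gi].items():
                        for n2, d2 in groups[gj].items():
                            out.at[n1, n2] = out.at[n2, n1] = d1 + d2
            merged = {}
            for g in groups:
                merged.update(g)
            return merged

        walk(self)
        return out


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Consistent on additive matrices: the output path-length matrix equals
    the input exactly.  The final three lineages are joined at an unrooted
    trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    nodes = [TreeNode(name=s) for s in dm.ids]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin over row-major order
        flat = np.argmin(q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        ai, aj = active[i], active[j]
        nodes[ai].length = li
        nodes[aj].length = lj
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        # distances from the new node to the remaining ones
        new_row = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    # join the last three at an unrooted trifurcation
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(ln, 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])
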