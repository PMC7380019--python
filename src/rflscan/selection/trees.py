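"""Protein distance estimation and neighbor-joining trees.

Pairwise distances are maximum-likelihood distances under the JTT model
(optimising the expected number of substitutions per site for each pair);
topologies come from neighbor-joining with negative branch lengths clamped
to zero. For the codon-model stage the topology is only a fixed input, and
for the highly similar sequences this pipeline handles NJ on ML distances
is an adequate stand-in for a full ML tree search.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .._jtt import AA_ORDER, JTT_FREQS, spectral_decomposition

__all__ = ["PhyloTree", "jtt_ml_distance", "jtt_distance_matrix", "nj_tree"]

_AA_IDX = {a: i for i, a in enumerate(AA_ORDER)}
_DECOMP = None


def _decomp():
    global _DECOMP
    if _DECOMP is None:
        _DECOMP = spectral_decomposition()
    return _DECOMP


def jtt_ml_distance(a: str, b: str, max_d: float = 15.0) -> float:
    """ML JTT distance (expected substitutions/site) between two aligned
    protein sequences. Columns with gaps or non-standard residues are
    skipped."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal lengths)")
    ia, ib = [], []
    for x, y in zip(a.upper(), b.upper()):
        i, j = _AA_IDX.get(x), _AA_IDX.get(y)
        if i is not None and j is not None:
            ia.append(i)
            ib.append(j)
    if not ia:
        raise ValueError("no comparable columns")
    ia = np.array(ia)
    ib = np.array(ib)
    if np.all(ia == ib):
        return 0.0
    w, right, left = _decomp()

    def neg_loglik(d):
        p = (right * np.exp(w * d)[None, :]) @ left
        np.clip(p, 1e-300, None, out=p)
        return -np.log(JTT_FREQS[ia] * p[ia, ib]).sum()

    res = minimize_scalar(neg_loglik, bounds=(1e-6, max_d), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def jtt_distance_matrix(msa: dict[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(msa)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jtt_ml_distance(msa[ids[i]], msa[ids[j]])
    return ids, d


@dataclass
class PhyloTree:
    """Rooted representation of an (un)rooted tree for pruning.

    Node 0 is the root (may be a trifurcation). ``parent[i]`` is -1 for the
    root; ``blen[i]`` is the branch length above node i (expected
    substitutions per site/codon).
    """

    parent: np.ndarray
    blen: np.ndarray
    names: list[str | None]  # leaf names; None for internal nodes

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        if np.any(self.blen[1:] < 0):
            raise ValueError("negative branch length")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> list[int]:
        has_child = set(self.parent[self.parent >= 0])
        return [i for i in range(self.n_nodes) if i not in has_child]

    @property
    def taxa(self) -> list[str]:
        return sorted(self.names[i] for i in self.leaves)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            ch[self.parent[i]].append(i)
        return ch

    def postorder(self) -> list[int]:
        ch = self.children()
        out: list[int] = []
        stack = [0]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(ch[node])
        out.reverse()
        return out

    def with_branch_lengths(self, blen: np.ndarray) -> "PhyloTree":
        b = np.asarray(blen, dtype=float).copy()
        return PhyloTree(self.parent.copy(), b, list(self.names))

    def total_length(self) -> float:
        return float(self.blen[1:].sum())

    # -- newick -----------------------------------------------------------
    @classmethod
    def from_skbio(cls, tree) -> "PhyloTree":
        parent, blen, names = [], [], []
        index: dict[int, int] = {}

        for node in tree.preorder():
            idx = len(parent)
            index[id(node)] = idx
            parent.append(index[id(node.parent)] if node.parent is not None else -1)
            length = node.length if node.length is not None else 0.0
            blen.append(max(0.0, float(length)))
            names.append(node.name if node.is_tip() else None)
        return cls(np.array(parent), np.array(blen), names)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        from skbio import TreeNode

        return cls.from_skbio(TreeNode.read(io.StringIO(newick)))

    def to_newick(self) -> str:
        ch = self.children()

        def render(i: int) -> str:
            if not ch[i]:
                label = self.names[i] or f"n{i}"
            else:
                label = "(" + ",".join(render(c) for c in ch[i]) + ")"
            if i == 0:
                return label + ";"
            return f"{label}:{self.blen[i]:.6g}"

        return render(0)


def nj_tree(msa: dict[str, str]) -> PhyloTree:
    """Neighbor-joining tree on ML JTT distances.

    Negative branch lengths produced by NJ are clamped to zero.
    """
    if len(msa) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids, d = jtt_distance_matrix(msa)
    tree = nj(DistanceMatrix(d, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return PhyloTree.from_skbio(tree)
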