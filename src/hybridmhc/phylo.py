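"""Tree handling and the pruning likelihood engine.

Trees are parsed with dendropy and flattened into postorder arrays; the
likelihood is Felsenstein's pruning algorithm with per-node rescaling so
long alignments do not underflow.  For the reversible codon models used
here the likelihood does not depend on root placement, so an unrooted
Newick tree is simply evaluated from its (arbitrary) seed node.
"""

from __future__ import annotations

import io
import warnings

import dendropy
import numpy as np

from .codon import N_CODONS


class PhyloTree:
    """Flattened rooted view of a (possibly unrooted) binary tree."""

    def __init__(self, dtree: dendropy.Tree):
        dtree.suppress_unifurcations()
        self._dtree = dtree
        nodes = list(dtree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.edge_length = np.zeros(self.n_nodes)
        self.postorder = np.arange(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.taxa: list[str] = []
        self.leaf_index: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = index[id(nd.parent_node)]
                self.children[self.parent[i]].append(i)
                self.edge_length[i] = max(float(nd.edge.length or 0.0), 0.0)
            if nd.is_leaf():
                name = nd.taxon.label if nd.taxon else str(i)
                self.taxa.append(name)
                self.leaf_index[name] = i
        self.root = self.n_nodes - 1

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
        return cls(dtree)

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick",
                                     suppress_rooting=True).strip()

    @property
    def total_length(self) -> float:
        return float(self.edge_length.sum())

    def scaled(self, factor: float) -> "PhyloTree":
        clone = PhyloTree.from_newick(self.to_newick())
        clone.edge_length = self.edge_length * factor
        return clone


def jc69_codon_distances(sequences: list[str]) -> np.ndarray:
    """Pairwise JC69-corrected nucleotide distances in per-codon units.

    Saturated pairs (p >= 0.749) are capped so the correction stays finite.
    """
    n = len(sequences)
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in sequences]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[i], arrs[j]
            L = min(len(a), len(b))
            p = float(np.mean(a[:L] != b[:L]))
            p = min(p, 0.749)
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = 3.0 * d
    return D


def nj_tree(names: list[str], distances: np.ndarray) -> PhyloTree:
    """Neighbor-joining tree (scikit-bio), negative branches clamped to 0."""
    if len(names) < 3:
        raise ValueError("need at least 3 taxa for a tree")
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    if np.allclose(distances, 0):
        warnings.warn("identical sequences: zero-length branches in NJ tree")
    dm = DistanceMatrix(distances, ids=list(names))
    tr = _nj(dm)
    for node in tr.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    tr.write(buf, format="newick")
    return PhyloTree.from_newick(buf.getvalue())


def encode_leaf_codons(alignment_codons: np.ndarray) -> np.ndarray:
    """Pass-through hook: alignment already holds codon indices (-1 = missing)."""
    return np.asarray(alignment_codons, dtype=int)


class PruningEngine:
    """Per-site likelihoods on a fixed tree/alignment for arbitrary P-matrices.

    ``codon_idx``: (n_taxa, L) integer codon states aligned to ``tree.taxa``
    order; -1 marks a missing/ambiguous codon (partial of all ones).
    """

    def __init__(self, tree: PhyloTree, codon_idx: np.ndarray, taxa: list[str]):
        self.tree = tree
        codon_idx = np.asarray(codon_idx, dtype=int)
        missing = set(tree.taxa) ^ set(taxa)
        if missing:
            raise ValueError(f"tree/alignment taxon mismatch: {sorted(missing)}")
        self.L = codon_idx.shape[1]
        self._leaf_partials: dict[int, np.ndarray] = {}
        for taxon, row in zip(taxa, codon_idx):
            part = np.zeros((self.L, N_CODONS))
            ok = row >= 0
            part[np.arange(self.L)[ok], row[ok]] = 1.0
            part[~ok] = 1.0
            self._leaf_partials[tree.leaf_index[taxon]] = part

    def site_log_likelihoods(self, P_by_node: dict[int, np.ndarray],
                             pi: np.ndarray) -> np.ndarray:
        """log L(h) for one rate class; P_by_node maps node -> P(edge to parent)."""
        tree = self.tree
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.L)
        for node in tree.postorder:
            if not tree.children[node]:
                partials[node] = self._leaf_partials[node]
                continue
            prod = None
            for child in tree.children[node]:
                msg = partials.pop(child) @ P_by_node[child].T
                prod = msg if prod is None else prod * msg
            mx = prod.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            prod /= mx[:, None]
            logscale += np.log(mx)
            partials[node] = prod
        root_like = partials[tree.root] @ pi
        with np.errstate(divide="ignore"):
            return np.log(root_like) + logscale
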