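"""Distance-based phylogeny and PCA over the bi-allelic matrix.

p-distance is the proportion of sites at which two accessions differ.
Trees are built with the Saitou-Nei neighbour-joining algorithm
(deterministic lexicographic tie-break, negative branch lengths clamped
to zero with the deficit moved to the sister branch). PCA follows the
smartpca convention: columns are mean-centred and, by default, scaled by
sqrt(p(1-p)) with a shrunken allele-frequency estimate — here in its
haploid form, since each accession contributes a single allele per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BiallelicMatrix
from .matrix import _pairwise_difference_counts


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match the name list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


@dataclass
class TreeNode:
    """Node of an unrooted tree; the root is a trifurcation for >= 3 taxa."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, digits: int = 6) -> str:
        return self._newick(digits) + ";"

    def _newick(self, digits: int) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(f"{c._newick(digits)}:{l:.{digits}f}" for c, l in self.children)
        return f"({inner})"

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-or-canonical leaf set per internal edge)."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset[str]] = set()

        def visit(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(visit(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        visit(self)
        return out

    def leaf_distances(self) -> pd.DataFrame:
        """Path-length (sum of branch lengths) between every leaf pair."""
        # distances from each node down to its leaves, merged at internal nodes
        leaves = sorted(self.leaves())
        idx = {n: i for i, n in enumerate(leaves)}
        D = np.zeros((len(leaves), len(leaves)))

        def visit(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            sub = []
            for child, length in node.children:
                d = visit(child)
                sub.append({k: v + length for k, v in d.items()})
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for a, da in sub[i].items():
                        for b, db in sub[j].items():
                            D[idx[a], idx[b]] = D[idx[b], idx[a]] = da + db
            merged = {}
            for d in sub:
                merged.update(d)
            return merged

        visit(self)
        return pd.DataFrame(D, index=leaves, columns=leaves)


def p_distance(matrix: BiallelicMatrix) -> DistanceMatrix:
    """Proportion of bi-allelic sites at which two accessions differ."""
    if matrix.n_accessions < 2:
        raise ValueError("p-distance needs at least two accessions")
    if matrix.n_sites == 0:
        raise ValueError("p-distance is undefined on an empty matrix")
    diff = _pairwise_difference_counts(matrix.genotypes.astype(np.int16))
    return DistanceMatrix(list(matrix.accessions), diff / matrix.n_sites)


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Iteratively joins the pair (i, j) minimising
    Q(i, j) = (n - 2) D(i, j) - r_i - r_j, with branch lengths
    l_i = D(i, j)/2 + (r_i - r_j)/(2(n - 2)) and l_j = D(i, j) - l_i.
    Ties on Q are broken by the lexicographically smallest joined name
    pair; negative branch lengths are clamped to zero and the deficit
    moved onto the sister branch. Returns an unrooted tree whose root is
    the final trifurcation (bifurcation for 2 remaining nodes).
    """
    names = list(dist.names)
    if len(names) < 3:
        raise ValueError("neighbour joining needs at least three taxa")
    D = dist.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=n) for n in names]
    labels = list(names)  # lexicographic tie-break identity per active node

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best, best_q = None, np.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and (best is None or key < best[2])):
                    best, best_q = (i, j, key), q
        i, j, _ = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_label = min(labels[i], labels[j])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [new_label]

    # final three nodes: closed-form three-point branch lengths
    (a, b, c) = range(3)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    lengths = [max(l, 0.0) for l in (la, lb, lc)]
    order = sorted(range(3), key=lambda k: labels[k])
    return TreeNode(children=[(nodes[k], lengths[k]) for k in order])


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the deficit to the sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


@dataclass
class PCAResult:
    accessions: list[str]
    scores: np.ndarray  # accessions x components, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # decreasing
    n_sites_used: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.accessions, columns=cols)


def run_pca(matrix: BiallelicMatrix, n_components: int | None = None, patterson_normalize: bool = True) -> PCAResult:
    """Eigendecomposition of the accession covariance of the genotype matrix.

    Monomorphic columns are dropped. Each remaining column is centred by
    its mean; with Patterson normalisation it is further divided by
    sqrt(p(1-p)) where p = (1 + sum g) / (2 + n) — the shrunken
    frequency estimate in its haploid form (n alleles observed, one per
    accession). Scores are eigenvectors scaled by the square root of
    their eigenvalue, so the variance along PC k equals eigenvalue k.
    """
    if matrix.n_accessions < 2:
        raise ValueError("PCA needs at least two accessions")
    G = matrix.genotypes.astype(float)
    poly = (G.min(axis=0) != G.max(axis=0))
    if not poly.any():
        raise ValueError("all sites are monomorphic; PCA is undefined")
    G = G[:, poly]
    n, m = G.shape
    X = G - G.mean(axis=0)
    if patterson_normalize:
        p_hat = (1.0 + G.sum(axis=0)) / (2.0 + n)
        X = X / np.sqrt(p_hat * (1.0 - p_hat))
    cov = (X @ X.T) / m
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude entry of each eigenvector is positive
    for k in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[pivot, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    k = n_components if n_components is not None else max(n - 1, 1)
    k = min(k, eigvec.shape[1])
    scores = eigvec[:, :k] * np.sqrt(eigval[:k])
    return PCAResult(list(matrix.accessions), scores, eigval, m)
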