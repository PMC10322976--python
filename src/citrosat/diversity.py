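"""Distance matrices, NJ / UPGMA trees and principal coordinate analysis.

The default codominant metric is the shared-allele dissimilarity
``d(x, y) = 1 - mean over comparable loci of the proportion of alleles the two
diploid genotypes share`` (a genotype contributes two allele observations, so
the shared proportion at a locus is ``sum_a min(count_x(a), count_y(a)) / 2``).
Binary band data use simple-matching or Jaccard dissimilarity. Missing loci
are pairwise-deleted.

Trees: Saitou-Nei neighbor joining with the standard Q criterion (negative
branch lengths clamped to zero, the deficit transferred to the sister branch)
and UPGMA (arithmetic-average linkage, ultrametric output). Ties everywhere
break on the lexicographically smallest leaf label, so output is invariant to
input sample order.

PCoA is classical metric scaling: double-center -D^2/2, eigendecompose, scale
eigenvectors by the square roots of the positive eigenvalues; percent variance
is reported over the positive-eigenvalue total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from citrosat.stats import AlleleMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray
    metric: str = "shared_allele"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < -1e-12):
            raise ValueError("distances must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = self.ids.index(key[0]), self.ids.index(key[1])
        return float(self.data[i, j])


def _shared_allele_proportion(gx, gy) -> float:
    counts_x: dict = {}
    counts_y: dict = {}
    for a in gx:
        counts_x[a] = counts_x.get(a, 0) + 1
    for a in gy:
        counts_y[a] = counts_y.get(a, 0) + 1
    shared = sum(min(c, counts_y.get(a, 0)) for a, c in counts_x.items())
    return shared / 2.0


def distance_matrix(
    matrix: AlleleMatrix, metric: str = "shared_allele"
) -> DistanceMatrix:
    """Pairwise sample dissimilarities from an allele matrix."""
    ids = list(matrix.individuals)
    if len(ids) < 2:
        raise ValueError("need >= 2 samples")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = ids[i], ids[j]
            num = comp = 0.0
            inter = union = match = 0
            for locus in matrix.loci:
                gx = matrix.genotype(locus, x)
                gy = matrix.genotype(locus, y)
                if gx is None or gy is None:
                    continue
                comp += 1
                if metric == "shared_allele":
                    num += _shared_allele_proportion(gx, gy)
                elif metric == "simple_matching":
                    match += int(gx == gy)
                elif metric == "jaccard":
                    inter += int(gx == 1 and gy == 1)
                    union += int(gx == 1 or gy == 1)
                else:
                    raise ValueError(f"unknown metric {metric!r}")
            if comp == 0:
                raise ValueError(f"samples {x!r} and {y!r} share no scored loci")
            if metric == "shared_allele":
                d = 1.0 - num / comp
            elif metric == "simple_matching":
                d = 1.0 - match / comp
            else:
                d = 1.0 - (inter / union if union else 1.0)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids, D, metric=metric)


@dataclass
class TreeResult:
    newick: str
    method: str  # NJ | UPGMA


class _Node:
    __slots__ = ("label", "children", "rep")

    def __init__(self, label=None, children=None, rep=None):
        self.label = label
        self.children = children or []  # list of (node, branch_length)
        self.rep = rep if rep is not None else label  # smallest leaf label

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.17g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(D: DistanceMatrix) -> TreeResult:
    """Saitou-Nei neighbor joining; unrooted tree emitted as a trifurcating root."""
    n = len(D.ids)
    if n < 3:
        raise ValueError("NJ needs >= 3 samples")
    nodes = [_Node(label=i) for i in sorted(D.ids)]
    perm = [D.ids.index(x.label) for x in nodes]
    dist = {(a.rep, b.rep): D.data[perm[i], perm[j]]
            for i, a in enumerate(nodes) for j, b in enumerate(nodes) if i != j}

    def d(a: _Node, b: _Node) -> float:
        return dist[(a.rep, b.rep)]

    while len(nodes) > 3:
        m = len(nodes)
        r = {x.rep: sum(d(x, y) for y in nodes if y is not x) for x in nodes}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = nodes[i], nodes[j]
                q = (m - 2) * d(a, b) - r[a.rep] - r[b.rep]
                key = (q, *sorted((a.rep, b.rep)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = d(a, b)
        la = 0.5 * dab + (r[a.rep] - r[b.rep]) / (2 * (m - 2))
        lb = dab - la
        # clamp-and-transfer negative branch lengths
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        new = _Node(children=[(a, la), (b, lb)], rep=min(a.rep, b.rep))
        rest = [x for x in nodes if x is not a and x is not b]
        for x in rest:
            dxu = 0.5 * (d(a, x) + d(b, x) - dab)
            dist[(new.rep, x.rep)] = dist[(x.rep, new.rep)] = max(dxu, 0.0)
        nodes = rest + [new]

    a, b, c = nodes
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    ordered = sorted([(a, la), (b, lb), (c, lc)], key=lambda t: t[0].rep)
    root = _Node(children=ordered, rep=min(a.rep, b.rep, c.rep))
    return TreeResult(newick=root.newick() + ";", method="NJ")


def upgma_tree(D: DistanceMatrix) -> TreeResult:
    """Unweighted pair-group (arithmetic average) agglomeration; ultrametric."""
    n = len(D.ids)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 samples")
    nodes = [_Node(label=i) for i in sorted(D.ids)]
    perm = [D.ids.index(x.label) for x in nodes]
    dist = {(a.rep, b.rep): D.data[perm[i], perm[j]]
            for i, a in enumerate(nodes) for j, b in enumerate(nodes) if i != j}
    size = {x.rep: 1 for x in nodes}
    height = {x.rep: 0.0 for x in nodes}

    while len(nodes) > 1:
        best = None
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                a, b = nodes[i], nodes[j]
                key = (dist[(a.rep, b.rep)], *sorted((a.rep, b.rep)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist[(a.rep, b.rep)]
        h = dab / 2.0
        new = _Node(
            children=[(a, h - height[a.rep]), (b, h - height[b.rep])],
            rep=min(a.rep, b.rep),
        )
        rest = [x for x in nodes if x is not a and x is not b]
        na, nb = size[a.rep], size[b.rep]
        for x in rest:
            dx = (na * dist[(a.rep, x.rep)] + nb * dist[(b.rep, x.rep)]) / (na + nb)
            dist[(new.rep, x.rep)] = dist[(x.rep, new.rep)] = dx
        size[new.rep] = na + nb
        height[new.rep] = h
        nodes = rest + [new]
    return TreeResult(newick=nodes[0].newick() + ";", method="UPGMA")


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per retained axis, over positive eigenvalues


def pcoa(D: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    n = len(D.ids)
    A = -0.5 * D.data**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    positive = eigval > tol
    pos_total = eigval[positive].sum()
    keep = min(n_axes, int(positive.sum()))
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    pct = 100.0 * eigval[:keep] / pos_total if pos_total > 0 else np.zeros(keep)
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=D.ids, columns=[f"PCo{i + 1}" for i in range(keep)]
        ),
        eigenvalues=eigval,
        percent_variance=pct,
    )
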