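"""Genotype distances and neighbor-joining trees.

Individuals are compared by the allele-sharing distance:
d(i,j) = 1 - (shared alleles)/(2 L), summed over the L loci typed in
both, with 2 / 1 / 0 alleles shared per locus for identical /
half-matching / disjoint genotypes.  For grouped samples Nei's (1972)
standard genetic distance between population allele-frequency vectors is
also provided.  Trees are built with the Saitou-Nei neighbor-joining
agglomeration and emitted as standard newick with branch lengths and a
trifurcating (unrooted) root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, allele_frequencies

# shared-allele count lookup for genotype-code pairs (codes 0/1/2)
_SHARED = np.array(
    [
        [2, 1, 0],
        [1, 2, 1],
        [0, 1, 2],
    ],
    dtype=float,
)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")


def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing distance over co-typed loci."""
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    n = g.n_samples
    d = np.zeros((n, n))
    codes = g.codes
    typed = codes != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = typed[i] & typed[j]
            l_ij = int(both.sum())
            if l_ij == 0:
                raise ValueError(
                    f"samples {g.samples[i]!r} and {g.samples[j]!r} share no typed loci"
                )
            shared = _SHARED[codes[i, both], codes[j, both]].sum()
            d[i, j] = d[j, i] = 1.0 - shared / (2.0 * l_ij)
    return DistanceMatrix(list(g.samples), d)


def nei_distance(g: GenotypeMatrix, labels: Sequence[str]) -> DistanceMatrix:
    """Nei's (1972) standard genetic distance between labelled groups.

    D = -ln( J_xy / sqrt(J_x J_y) ), with J's the across-loci means of
    sum_i p_xi p_yi, sum_i p_xi^2 and sum_i p_yi^2.
    """
    if len(labels) != g.n_samples:
        raise ValueError("labels must match sample count")
    groups = sorted(set(labels))
    ps = []
    for grp in groups:
        members = [s for s, l in zip(g.samples, labels) if l == grp]
        ps.append(allele_frequencies(g.subset(samples=members)).p)
    k = len(groups)
    d = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            pa, pb = ps[a], ps[b]
            jx = np.mean(pa**2 + (1 - pa) ** 2)
            jy = np.mean(pb**2 + (1 - pb) ** 2)
            jxy = np.mean(pa * pb + (1 - pa) * (1 - pb))
            d[a, b] = d[b, a] = max(0.0, -np.log(jxy / np.sqrt(jx * jy)))
    return DistanceMatrix(groups, d)


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(d: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns newick text.

    Tie-breaks in the Q-matrix pick the lowest-index pair, so output is
    deterministic.  Negative branch lengths are clamped to zero with the
    excess transferred to the sister edge.  The root is the final
    trifurcation (unrooted tree).
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[_Node] = [_Node(name=str(t)) for t in d.ids]
    dist = d.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, None)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] < best[0]:
                    best = (q[a, b], (a, b))
        a, b = best[1]
        d_ab = sub[a, b]
        la = 0.5 * d_ab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d_ab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        ia, ib = active[a], active[b]
        new = _Node(children=[(nodes[ia], la), (nodes[ib], lb)])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(dist.shape[0] + 1)
        for c in range(m):
            if c in (a, b):
                continue
            ic = active[c]
            new_row[ic] = 0.5 * (sub[a, c] + sub[b, c] - d_ab)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [i for i in active if i not in (ia, ib)] + [len(nodes) - 1]

    # final trifurcation
    i, j, k = active
    dij, dik, djk = dist[i, j], dist[i, k], dist[j, k]
    li = max(0.0, 0.5 * (dij + dik - djk))
    lj = max(0.0, 0.5 * (dij + djk - dik))
    lk = max(0.0, 0.5 * (dik + djk - dij))
    root = _Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return root.newick() + ";"
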