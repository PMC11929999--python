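"""Population structure from the binary CNV presence/absence matrix.

Samples are embedded by classical multidimensional scaling (the cmdscale
algorithm: square the distances, double-centre, eigendecompose) and related
by a neighbour-joining tree.  Both operate on a distance matrix derived
from the binary matrix; Jaccard distance is the default metric, simple
matching the alternative.

Neighbour-joining is implemented here rather than delegated, because the
pipeline pins behaviour a library implementation leaves open: deterministic
lexicographic tie-breaking in the Q-criterion, and clamping of negative
branch-length estimates to zero with the deficit moved to the sister
branch.  scikit-bio's ``nj`` serves as an independent cross-check in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .calls import UnionLocus
from .samples import SampleSheet

__all__ = [
    "binary_matrix",
    "distance_matrix",
    "MdsResult",
    "classical_mds",
    "mds_from_binary",
    "neighbor_joining",
]


def binary_matrix(
    loci: list[UnionLocus], sheet: SampleSheet
) -> pd.DataFrame:
    """Samples x union-loci presence/absence matrix (0/1 ints).

    Rows follow sheet order; columns follow locus order.  Every locus must
    have >= 1 member, and every member sample must be on the sheet.
    """
    samples = list(sheet.samples)
    sample_set = set(samples)
    cols = {}
    for locus in loci:
        if not locus.members:
            raise ValueError(f"locus {locus.locus_id} has no members")
        extra = locus.sample_ids - sample_set
        if extra:
            raise ValueError(
                f"locus {locus.locus_id}: samples not on sheet: {sorted(extra)}"
            )
        cols[locus.locus_id] = [1 if s in locus.sample_ids else 0 for s in samples]
    m = pd.DataFrame(cols, index=samples, dtype=np.int8)
    m.index.name = "sample"
    return m


def distance_matrix(m: pd.DataFrame, metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise sample distances from the binary matrix.

    ``jaccard``: 1 - |intersection| / |union| of the presence sets; a pair
    with empty union gets distance 0 by convention (warning emitted).
    ``simple_matching``: fraction of loci where the two samples disagree.
    """
    if m.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    x = m.to_numpy(dtype=np.int64)
    inter = x @ x.T
    row = x.sum(axis=1)
    union = row[:, None] + row[None, :] - inter
    if metric == "jaccard":
        if (union == 0).any() and m.shape[0] > 1:
            warnings.warn(
                "sample pair(s) with no present loci: Jaccard distance set to 0"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 0.0)
    elif metric == "simple_matching":
        mism = row[:, None] + row[None, :] - 2 * inter
        d = mism / m.shape[1]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(m.index))


@dataclass(frozen=True)
class MdsResult:
    """Classical-MDS embedding with its eigenvalue diagnostics."""

    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, descending
    n_negative: int  # count of negative eigenvalues (axes excluded)


def classical_mds(d: DistanceMatrix, k: int = 2) -> MdsResult:
    """Classical (metric) scaling of a distance matrix.

    Squares the distances, double-centres, eigendecomposes, and returns the
    top-``k`` coordinates scaled by the square root of their eigenvalues.
    Axes with non-positive eigenvalues are excluded (their count is
    reported).  Each axis's sign is fixed by making its largest-magnitude
    coordinate positive, so runs are comparable.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = d.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    dist = d.data
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10).sum())
    use = min(k, n_pos)
    coords = evecs[:, :use] * np.sqrt(evals[:use])
    for a in range(use):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    if use < k:  # pad degenerate axes with zeros
        coords = np.hstack([coords, np.zeros((n, k - use))])
    df = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"dim{i+1}" for i in range(k)]
    )
    df.index.name = "sample"
    return MdsResult(df, evals, int((evals < -1e-10).sum()))


def mds_from_binary(
    m: pd.DataFrame, k: int = 2, metric: str = "jaccard"
) -> MdsResult:
    """MDS entry point straight from the binary matrix.

    ``metric='euclidean'`` treats matrix rows as coordinates (classical MDS
    on Euclidean row distances, i.e. a PCA-style embedding); the set-based
    metrics go through :func:`distance_matrix`.
    """
    if metric == "euclidean":
        x = m.to_numpy(dtype=float)
        sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        d = DistanceMatrix(np.sqrt(sq), ids=list(m.index))
    else:
        d = distance_matrix(m, metric)
    return classical_mds(d, k)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a distance matrix.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - R_i - R_j is
    joined (R = row sums over active nodes); ties are broken by the
    lexicographically smallest pair of subtree labels (a subtree's label is
    its smallest leaf name).  Branch lengths come from the canonical closed
    forms; negative estimates are clamped to zero with the deficit moved to
    the sister branch (a warning is emitted).  The result is the standard
    unrooted tree, emitted with a trifurcating root for >= 3 taxa.
    """
    ids = list(d.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    dist = np.asarray(d.data, dtype=float)
    if (dist < 0).any():
        raise ValueError("negative distances")
    if not np.allclose(dist, dist.T):
        raise ValueError("asymmetric distance matrix")

    if n == 2:
        a, b = TreeNode(name=ids[0]), TreeNode(name=ids[1])
        a.length = float(dist[0, 1])
        b.length = 0.0
        return TreeNode(children=[a, b])

    nodes: dict[str, TreeNode] = {x: TreeNode(name=x) for x in ids}
    labels: dict[str, str] = {x: x for x in ids}  # subtree key -> min leaf name
    dm: dict[frozenset, float] = {
        frozenset((ids[i], ids[j])): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    active = list(ids)
    clamped = 0
    counter = 0

    def get(a: str, b: str) -> float:
        return dm[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * get(a, b) - r[a] - r[b]
                key = tuple(sorted((labels[a], labels[b])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        dab = get(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            la, lb, clamped = 0.0, dab, clamped + 1
        elif lb < 0:
            la, lb, clamped = dab, 0.0, clamped + 1
        counter += 1
        u = f"__internal{counter}"
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = float(la), float(lb)
        nodes[u] = TreeNode(children=[na, nb])
        labels[u] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            dm[frozenset((u, c))] = 0.5 * (get(a, c) + get(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = active
    la = (get(a, b) + get(a, c) - get(b, c)) / 2
    lb = (get(a, b) + get(b, c) - get(a, c)) / 2
    lc = (get(a, c) + get(b, c) - get(a, b)) / 2
    lens = [la, lb, lc]
    for i, l in enumerate(lens):
        if l < 0:
            lens[i] = 0.0
            clamped += 1
    root = TreeNode(children=[nodes.pop(a), nodes.pop(b), nodes.pop(c)])
    for child, l in zip(root.children, lens):
        child.length = float(l)
    if clamped:
        warnings.warn(f"{clamped} negative branch-length estimate(s) clamped to 0")
    return root
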