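"""Binary matrix, distances, classical MDS and neighbour-joining."""

from __future__ import annotations

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from cnvrpipe.calls import CnvCall, build_union_loci
from cnvrpipe.popstruct import (
    binary_matrix,
    classical_mds,
    distance_matrix,
    mds_from_binary,
    neighbor_joining,
)
from cnvrpipe.samples import SampleSheet


@pytest.fixture
def sheet3():
    return SampleSheet((
        ("s1", "A", "America"), ("s2", "A", "America"), ("s3", "B", "Europe"),
    ))


def loci_for(sample_sets):
    """One union locus per sample set, at well-separated positions."""
    calls = []
    for k, samples in enumerate(sample_sets):
        start = 10_000 * (k + 1)
        for s in samples:
            calls.append(CnvCall(s, "toolA", "1", start, start + 999, "loss"))
    return build_union_loci(calls)


class TestBinaryMatrix:
    def test_cells_and_shape(self, sheet3):
        m = binary_matrix(loci_for([("s1", "s2"), ("s2", "s3")]), sheet3)
        assert m.shape == (3, 2)
        assert m.iloc[0].tolist() == [1, 0]
        assert m.iloc[2].tolist() == [0, 1]

    def test_unknown_sample_fatal(self, sheet3):
        with pytest.raises(ValueError, match="not on sheet"):
            binary_matrix(loci_for([("s1", "ghost")]), sheet3)


class TestDistances:
    def test_jaccard_examples(self, sheet3):
        m = binary_matrix(
            loci_for([("s1", "s2"), ("s1", "s3"), ("s2",)]), sheet3
        )
        d = distance_matrix(m, "jaccard")
        # s1={l0,l1}, s2={l0,l2}: intersection 1, union 3 -> 1 - 1/3
        assert d["s1", "s2"] == pytest.approx(2 / 3)
        assert d["s1", "s1"] == 0.0

    def test_identical_and_disjoint_rows(self, sheet3):
        m = binary_matrix(loci_for([("s1", "s2"), ("s3",)]), sheet3)
        d = distance_matrix(m)
        assert d["s1", "s2"] == 0.0
        assert d["s1", "s3"] == 1.0

    def test_column_order_invariance(self, sheet3):
        m = binary_matrix(
            loci_for([("s1", "s2"), ("s1", "s3"), ("s2", "s3")]), sheet3
        )
        d1 = distance_matrix(m)
        d2 = distance_matrix(m[list(m.columns[::-1])])
        np.testing.assert_allclose(d1.data, d2.data)

    def test_empty_pair_warns_and_zeroes(self, sheet3):
        m = binary_matrix(loci_for([("s1",)]), sheet3)
        with pytest.warns(UserWarning, match="no present loci"):
            d = distance_matrix(m)
        assert d["s2", "s3"] == 0.0

    def test_simple_matching(self, sheet3):
        m = binary_matrix(loci_for([("s1", "s2"), ("s1", "s3")]), sheet3)
        d = distance_matrix(m, "simple_matching")
        assert d["s1", "s2"] == pytest.approx(0.5)


class TestClassicalMds:
    def test_collinear_three_points(self):
        d = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        res = classical_mds(d, k=1)
        x = res.coordinates["dim1"].to_numpy()
        np.testing.assert_allclose(sorted(x), [-1, 0, 1], atol=1e-9)
        # sign convention: largest-magnitude coordinate is positive
        assert x[np.argmax(np.abs(x))] > 0

    def test_equilateral_recovery(self):
        d = DistanceMatrix((np.ones((4, 4)) - np.eye(4)), ids=list("abcd"))
        res = classical_mds(d, k=3)
        pts = res.coordinates.to_numpy()
        dists = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        off = dists[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-9)

    def test_planted_configuration_recovered_up_to_rigid_motion(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        pts -= pts.mean(axis=0)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix(d, ids=[str(i) for i in range(12)]), 2)
        got = res.coordinates.to_numpy()
        # orthogonal Procrustes (no scaling): residual ~ 0
        u, _, vt = np.linalg.svd(got.T @ pts)
        rot = u @ vt
        residual = np.abs(got @ rot - pts).max()
        assert residual < 1e-8

    def test_agreement_with_skbio_pcoa(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        dmat = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        d = DistanceMatrix(dmat, ids=[str(i) for i in range(10)])
        mine = classical_mds(d, k=2).coordinates.to_numpy()
        ref = pcoa(d, number_of_dimensions=2).samples.to_numpy()
        for axis in range(2):
            r = ref[:, axis]
            m = mine[:, axis]
            assert min(np.abs(m - r).max(), np.abs(m + r).max()) < 1e-8

    def test_coincident_samples_embed_together(self):
        d = DistanceMatrix(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0]], ids=list("abc")
        )
        res = classical_mds(d, k=1)
        a, b, _ = res.coordinates["dim1"].to_numpy()
        assert a == pytest.approx(b, abs=1e-12)

    def test_bad_k_fatal(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            classical_mds(d, k=0)

    def test_matrix_entry_point(self, sheet3):
        m = binary_matrix(
            loci_for([("s1", "s2"), ("s1", "s3"), ("s2", "s3")]), sheet3
        )
        res = mds_from_binary(m, k=2, metric="euclidean")
        assert res.coordinates.shape == (3, 2)


def random_additive_matrix(rng, n):
    """Distances from a random binary tree with positive branch lengths."""
    import itertools

    nodes = [([i], 0.0) for i in range(n)]  # (leaf ids, unused)
    children: dict[int, list[tuple[int, float]]] = {}
    ids = list(range(n))
    next_id = n
    parent_edges: dict[int, tuple[int, float]] = {}
    active = ids[:]
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        u = next_id
        next_id += 1
        parent_edges[a] = (u, float(rng.uniform(0.1, 2.0)))
        parent_edges[b] = (u, float(rng.uniform(0.1, 2.0)))
        active = [x for x in active if x not in (a, b)] + [u]
    root = active[0]

    def path_to_root(x):
        path = {}
        total = 0.0
        while x in parent_edges:
            p, w = parent_edges[x]
            total += w
            path[p] = total
            x = p
        return path

    d = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        pa, pb = path_to_root(a), path_to_root(b)
        shared = set(pa) & set(pb)
        dist = min(pa[s] + pb[s] for s in shared)
        d[a, b] = d[b, a] = dist
    return d


def tree_tip_distances(tree, ids):
    tips = {t.name: t for t in tree.tips()}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tips[ids[i]].distance(tips[ids[j]])
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("ABC"))
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_two_taxa_single_edge(self):
        d = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=list("AB"))
        tree = neighbor_joining(d)
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].distance(tips["B"]) == pytest.approx(0.4)

    def test_additive_matrices_reproduced_exactly(self):
        rng = np.random.default_rng(12)
        for n in (4, 6, 9, 12):
            dmat = random_additive_matrix(rng, n)
            ids = [f"t{i}" for i in range(n)]
            tree = neighbor_joining(DistanceMatrix(dmat, ids=ids))
            got = tree_tip_distances(tree, ids)
            np.testing.assert_allclose(got, dmat, atol=1e-9)

    def test_agreement_with_skbio_nj_on_additive_input(self):
        rng = np.random.default_rng(21)
        dmat = random_additive_matrix(rng, 8)
        ids = [f"t{i}" for i in range(8)]
        d = DistanceMatrix(dmat, ids=ids)
        mine = tree_tip_distances(neighbor_joining(d), ids)
        ref = tree_tip_distances(skbio_nj(d), ids)
        np.testing.assert_allclose(mine, ref, atol=1e-9)

    def test_negative_input_fatal(self):
        d = DistanceMatrix(
            [[0, -1, 1], [-1, 0, 1], [1, 1, 0]], ids=list("abc")
        )
        with pytest.raises(ValueError, match="negative"):
            neighbor_joining(d)

    def test_newick_round_trip_isomorphic(self, tmp_path):
        from cnvrpipe.io import read_newick, write_newick

        rng = np.random.default_rng(2)
        dmat = random_additive_matrix(rng, 6)
        ids = [f"t{i}" for i in range(6)]
        tree = neighbor_joining(DistanceMatrix(dmat, ids=ids))
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        np.testing.assert_allclose(
            tree_tip_distances(back, ids), dmat, atol=1e-6
        )

    def test_region_structure_separates_in_distance(self, default_run):
        """Planted region-structured CNVRs: between-region distance exceeds
        within-breed distance on average."""
        m = default_run.matrix
        d = distance_matrix(m)
        sheet = default_run.sheet
        within, between = [], []
        ids = list(m.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if sheet.breed_of(a) == sheet.breed_of(b):
                    within.append(d[a, b])
                elif sheet.region_of(a) != sheet.region_of(b):
                    between.append(d[a, b])
        assert np.mean(between) > np.mean(within)
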