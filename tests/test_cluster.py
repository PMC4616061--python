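"""Nearest-neighbour clustering against exhaustive and graph oracles."""

import numpy as np
import pytest

from msamd.cluster import (
    central_structure,
    nn_cluster,
    recluster_excluding_termini,
    rmsd_matrix,
    termini_excluded_region,
)
from msamd.geometry import kabsch_superpose
from msamd.structio import Ensemble
from msamd.synthetic import helix_decoy_ensemble, noisy_torsion_copy

from _oracles import exhaustive_central, single_linkage_partition
from conftest import ALA11


def partitions_equal(a, b):
    """Same partition up to label renaming."""
    mapping = {}
    for x, y in zip(a, b):
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)


def block_matrix(rng, sizes, intra=0.4, inter=6.0):
    n = sum(sizes)
    mat = np.full((n, n), 0.0)
    start = 0
    blocks = []
    for s in sizes:
        blocks.append(list(range(start, start + s)))
        start += s
    for i in range(n):
        for j in range(i + 1, n):
            same = any(i in b and j in b for b in blocks)
            base = intra if same else inter
            mat[i, j] = mat[j, i] = base + rng.uniform(-0.05, 0.05)
    return mat


class TestRmsdMatrix:
    def test_identical_members_zero(self, helix11):
        ens = Ensemble(members=[helix11.copy() for _ in range(4)])
        mat = rmsd_matrix(ens)
        np.testing.assert_allclose(mat, 0.0, atol=1e-10)

    def test_matches_elementwise_kabsch(self):
        ens = helix_decoy_ensemble(ALA11, n_helix=2, n_decoy=1, seed=5)
        mat = rmsd_matrix(ens, selection="CA")
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else kabsch_superpose(
                    ens[i].coords["CA"], ens[j].coords["CA"]).rmsd
                assert mat[i, j] == pytest.approx(expected, abs=1e-10)

    def test_exact_symmetry(self):
        ens = helix_decoy_ensemble(ALA11, n_helix=3, n_decoy=2, seed=6)
        mat = rmsd_matrix(ens)
        np.testing.assert_array_equal(mat, mat.T)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd_matrix(Ensemble(members=[]))


class TestNNCluster:
    def test_two_distant_singletons(self):
        mat = np.array([[0.0, 5.0], [5.0, 0.0]])
        res = nn_cluster(mat, threshold=1.0)
        assert res.n_clusters == 2
        assert res.n_clusters_nonsingleton == 0

    def test_all_within_one_cluster(self):
        rng = np.random.default_rng(0)
        mat = block_matrix(rng, [5], intra=0.3)
        res = nn_cluster(mat, threshold=1.0)
        assert res.n_clusters == 1
        assert len(res.largest_cluster) == 5

    def test_two_triplets_match_components_oracle(self):
        rng = np.random.default_rng(1)
        mat = block_matrix(rng, [3, 3], intra=0.4, inter=6.0)
        res = nn_cluster(mat, threshold=1.0)
        assert sorted(res.cluster_sizes()) == [3, 3]
        assert partitions_equal(res.assignment,
                                single_linkage_partition(mat, 1.0))

    def test_well_separated_blocks_match_oracle(self):
        rng = np.random.default_rng(2)
        for sizes in ([4, 2], [5, 3, 2], [6, 1, 1], [2, 2, 2, 2]):
            mat = block_matrix(rng, sizes, intra=0.5, inter=8.0)
            res = nn_cluster(mat, threshold=1.5)
            assert partitions_equal(res.assignment,
                                    single_linkage_partition(mat, 1.5))

    def test_threshold_is_inclusive(self):
        mat = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert nn_cluster(mat, threshold=1.0).n_clusters == 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nn_cluster(np.zeros((3, 3)), threshold=0.0)
        with pytest.raises(ValueError):
            nn_cluster(np.zeros((2, 3)), threshold=1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.3, (5, 4)), rng.normal(5, 0.3, (4, 4))])
        mat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = nn_cluster(mat, threshold=2.0)
        perm = rng.permutation(len(pts))
        mat_p = mat[np.ix_(perm, perm)]
        res_p = nn_cluster(mat_p, threshold=2.0)
        assert partitions_equal(res_p.assignment, res.assignment[perm])

    def test_monotone_coarsening_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            pts = rng.normal(size=(rng.integers(6, 20), 3)) * rng.uniform(0.5, 3)
            mat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            t1, t2 = sorted(rng.uniform(0.2, 6.0, size=2))
            assert nn_cluster(mat, t2).n_clusters <= nn_cluster(mat, t1).n_clusters


class TestCentralStructure:
    def test_singleton(self):
        mat = np.zeros((3, 3))
        assert central_structure([2], mat) == 2

    def test_direct_argmin(self):
        mat = np.array([[0.0, 0.5, 1.5],
                        [0.5, 0.0, 0.5],
                        [1.5, 0.5, 0.0]])
        assert central_structure([0, 1, 2], mat) == 1

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 20
            m = rng.uniform(0.1, 5.0, (n, n))
            mat = (m + m.T) / 2
            np.fill_diagonal(mat, 0.0)
            members = rng.choice(n, size=12, replace=False)
            assert central_structure(members, mat) == exhaustive_central(members, mat)


class TestTerminiExclusion:
    def test_no_exclusion_is_identity(self):
        ens = helix_decoy_ensemble(ALA11, n_helix=4, n_decoy=3, seed=7)
        mat = rmsd_matrix(ens)
        direct = nn_cluster(mat, 1.0)
        re = recluster_excluding_termini(ens, 1.0, n_terminal=0, c_terminal=0)
        assert partitions_equal(re.assignment, direct.assignment)

    def test_terminal_noise_merges_after_exclusion(self):
        # members identical except for their terminal residues: one cluster
        # only once termini are excluded
        rng = np.random.default_rng(8)
        base = noisy_torsion_copy(ALA11, -57, -47, 0.0, rng)
        members = []
        for k in range(6):
            m = base.copy()
            m.label = f"m{k}"
            shift = rng.normal(0, 1.2, 3)
            for name in ("N", "CA", "C", "O"):
                m.coords[name] = m.coords[name].copy()
                m.coords[name][0] += shift
                m.coords[name][-1] -= shift
            members.append(m)
        ens = Ensemble(members=members)
        before = nn_cluster(rmsd_matrix(ens), 0.4)
        after = recluster_excluding_termini(ens, 0.4)
        assert before.n_clusters > 1
        assert after.n_clusters == 1

    def test_region_too_small(self, helix11):
        ens = Ensemble(members=[helix11.copy(), helix11.copy()])
        with pytest.raises(ValueError):
            recluster_excluding_termini(ens, 1.0, n_terminal=5, c_terminal=5)

    def test_region_helper(self):
        np.testing.assert_array_equal(termini_excluded_region(11), np.arange(1, 10))
        np.testing.assert_array_equal(
            termini_excluded_region(40, region=np.arange(3, 34)), np.arange(4, 33))
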