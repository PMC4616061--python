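"""Superposition, RMSD and dihedral mathematics against independent oracles."""

import numpy as np
import pytest

from msamd.builder import build_from_torsions, build_ideal_helix, place_atom
from msamd.geometry import (
    backbone_rmsd,
    ca_rmsd,
    dihedral,
    heavy_atom_rmsd,
    kabsch_superpose,
    rmsd_series_std,
)

from _oracles import quaternion_rmsd, two_pass_std
from conftest import ALA11, random_rotation


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd < 1e-10
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-8)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pts = rng.normal(size=(12, 3)) * 3
            rot = random_rotation(rng)
            t = rng.normal(size=3) * 10
            target = pts @ rot.T + t
            sup = kabsch_superpose(pts, target)
            assert sup.rmsd <= 1e-8
            np.testing.assert_allclose(sup.rotation, rot, atol=1e-6)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_is_never_used(self):
        # a chiral 4-point set vs its mirror image cannot be superposed by
        # any proper rotation; brute-force sampling confirms the residual
        rng = np.random.default_rng(2)
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1.3, 0], [0.2, 0.4, 1.7]])
        mirror = pts * np.array([1, 1, -1])
        sup = kabsch_superpose(pts, mirror)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1
        c_p = pts - pts.mean(0)
        c_m = mirror - mirror.mean(0)
        for _ in range(500):
            rot = random_rotation(rng)
            trial = np.sqrt(np.mean(np.sum((c_p @ rot.T - c_m) ** 2, axis=1)))
            assert trial >= sup.rmsd - 1e-9

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(4, 30)
            a = rng.normal(size=(n, 3)) * 2
            b = a + rng.normal(size=(n, 3)) * rng.uniform(0.1, 2.0)
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-6)

    def test_mass_weighted_matches_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(15, 3))
        b = a + rng.normal(size=(15, 3)) * 0.5
        w = rng.uniform(1, 16, size=15)
        assert kabsch_superpose(a, b, weights=w).rmsd == pytest.approx(
            quaternion_rmsd(a, b, weights=w), abs=1e-8)

    def test_optimality_spot_check(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(size=(10, 3)) * 0.7
        sup = kabsch_superpose(a, b)
        ca = a - a.mean(0)
        cb = b - b.mean(0)
        for _ in range(1000):
            rot = random_rotation(rng)
            trial = np.sqrt(np.mean(np.sum((ca @ rot.T - cb) ** 2, axis=1)))
            assert trial >= sup.rmsd - 1e-9

    @pytest.mark.parametrize("bad", [2, 0])
    def test_too_few_points(self, bad):
        pts = np.zeros((bad, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestStructureRmsd:
    def test_self_and_translation(self, helix11):
        assert ca_rmsd(helix11, helix11) == pytest.approx(0.0, abs=1e-10)
        moved = helix11.transformed(np.eye(3), np.array([5.0, -3.0, 12.0]))
        assert ca_rmsd(helix11, moved) == pytest.approx(0.0, abs=1e-8)

    def test_symmetry(self, helix11):
        rng = np.random.default_rng(6)
        other = build_from_torsions(ALA11, phi=-57 + rng.normal(0, 10, 11),
                                    psi=-47 + rng.normal(0, 10, 11))
        assert ca_rmsd(helix11, other) == pytest.approx(
            ca_rmsd(other, helix11), abs=1e-8)

    def test_rigid_transform_invariance(self, helix11, extended11):
        rng = np.random.default_rng(7)
        base = ca_rmsd(helix11, extended11)
        for _ in range(100):
            rot = random_rotation(rng)
            t = rng.normal(size=3) * 20
            a = helix11.transformed(rot, t)
            rot2 = random_rotation(rng)
            b = extended11.transformed(rot2, rng.normal(size=3) * 20)
            assert ca_rmsd(a, b) == pytest.approx(base, abs=1e-6)

    def test_noisy_helix_vs_oracle(self, helix11):
        rng = np.random.default_rng(8)
        noisy = helix11.copy()
        noisy.coords["CA"] = noisy.coords["CA"] + rng.normal(0, 0.5 / np.sqrt(3), (11, 3))
        r = ca_rmsd(helix11, noisy)
        assert 0.2 <= r <= 0.9
        assert r == pytest.approx(
            quaternion_rmsd(noisy.coords["CA"], helix11.coords["CA"]), abs=1e-6)

    def test_backbone_rmsd_vs_oracle(self, helix11):
        rng = np.random.default_rng(9)
        other = build_from_torsions(ALA11, phi=-57 + rng.normal(0, 6, 11),
                                    psi=-47 + rng.normal(0, 6, 11))
        got = backbone_rmsd(helix11, other)
        a = np.stack([helix11.coords[n] for n in ("N", "CA", "C", "O")], 1).reshape(-1, 3)
        b = np.stack([other.coords[n] for n in ("N", "CA", "C", "O")], 1).reshape(-1, 3)
        assert got == pytest.approx(quaternion_rmsd(a, b), abs=1e-6)
        assert backbone_rmsd(helix11, other) == pytest.approx(0.0, abs=1e-10) or got > 0

    def test_region_full_equals_default(self, helix11, extended11):
        full = ca_rmsd(helix11, extended11)
        explicit = ca_rmsd(helix11, extended11, region=range(11))
        assert full == pytest.approx(explicit, abs=1e-12)

    def test_heavy_atom_unavailable(self, helix11, extended11):
        with pytest.raises(ValueError, match="atoms unavailable"):
            heavy_atom_rmsd(helix11, extended11)

    def test_empty_region_rejected(self, helix11):
        with pytest.raises(ValueError):
            ca_rmsd(helix11, helix11, region=[])


class TestDihedral:
    def test_planar_cases(self):
        assert dihedral([1, 1, 0], [0, 0, 0], [2, 0, 0], [3, 1, 0]) == pytest.approx(0.0)
        assert dihedral([1, 1, 0], [0, 0, 0], [2, 0, 0], [3, -1, 0]) == pytest.approx(180.0)

    @pytest.mark.parametrize("tau", [60.0, -60.0, 90.0, 179.5, -179.5, 1.0])
    def test_construct_then_measure(self, tau):
        a = np.array([0.0, 1.4, 0.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([1.5, 0.0, 0.0])
        d = place_atom(a, b, c, bond=1.5, angle_deg=109.5, torsion_deg=tau)
        assert dihedral(a, b, c, d) == pytest.approx(tau, abs=1e-6)

    def test_degenerate_rejected(self):
        p = np.zeros(3)
        with pytest.raises(ValueError):
            dihedral(p, p, [1, 0, 0], [1, 1, 0])


class TestRmsdSeriesStd:
    def test_constant_series(self):
        assert rmsd_series_std([1.5] * 10) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        assert rmsd_series_std([1.0, 2.0]) == pytest.approx(0.70710678, abs=1e-6)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            vals = rng.uniform(0, 5, size=rng.integers(2, 100))
            assert rmsd_series_std(vals) == pytest.approx(two_pass_std(vals), abs=1e-10)

    def test_too_short(self):
        with pytest.raises(ValueError):
            rmsd_series_std([1.0])
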