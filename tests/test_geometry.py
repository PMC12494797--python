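import numpy as np
import pytest

from saxsfit.core import Atom, StructureModel
from saxsfit.geometry import (align_axes, buried_interface_area, find_c2_axis,
                              inter_ca_distance, sasa, sequence_mass)
from saxsfit.synth import SyntheticSpec, make_model


def _atom(chain, resnum, name, xyz, element="C", resname="ALA"):
    return Atom(chain, resnum, resname, name, element, tuple(xyz))


class TestSasa:
    def test_isolated_atom_full_sphere(self):
        st = StructureModel([_atom("A", 1, "CA", (0, 0, 0))])
        total, _ = sasa(st)
        assert total == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=0.01)

    def test_enclosed_atom_zero_area(self):
        shell = [_atom("A", 2 + i, "C", 2.0 * v) for i, v in enumerate(
            np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                      [0, 0, 1], [0, 0, -1],
                      [0.7, 0.7, 0], [-0.7, 0.7, 0], [0.7, -0.7, 0],
                      [-0.7, -0.7, 0], [0.7, 0, 0.7], [-0.7, 0, 0.7],
                      [0.7, 0, -0.7], [-0.7, 0, -0.7], [0, 0.7, 0.7],
                      [0, -0.7, 0.7], [0, 0.7, -0.7], [0, -0.7, -0.7]]))]
        st = StructureModel([_atom("A", 1, "CA", (0, 0, 0))] + shell)
        _, per_atom = sasa(st)
        assert per_atom[0] == pytest.approx(0.0, abs=1.0)

    def test_quadrature_convergence(self):
        rng = np.random.default_rng(0)
        atoms = [_atom("A", i + 1, "CA", 6.0 * rng.normal(size=3))
                 for i in range(50)]
        st = StructureModel(atoms)
        t1, _ = sasa(st, n_points=960)
        t2, _ = sasa(st, n_points=1920)
        assert abs(t2 / t1 - 1.0) < 0.005

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(1)
        atoms = [_atom("A", i + 1, "CA", 5.0 * rng.normal(size=3))
                 for i in range(30)]
        st = StructureModel(atoms)
        theta = 0.9
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        t1, _ = sasa(st)
        t2, _ = sasa(st.transformed(R, np.array([3.0, 4.0, 5.0])))
        assert abs(t2 / t1 - 1.0) < 0.001


class TestInterface:
    def _two_chains(self, gap):
        a = [_atom("A", i + 1, "CA", (3.0 * i, 0, 0)) for i in range(5)]
        b = [_atom("B", i + 1, "CA", (3.0 * i, gap, 0)) for i in range(5)]
        return StructureModel(a + b)

    def test_distant_chains_zero_interface(self):
        st = self._two_chains(100.0)
        r = buried_interface_area(st, {"chain": "A"}, {"chain": "B"})
        assert r.interface_area == pytest.approx(0.0, abs=1e-6)

    def test_contacting_chains_positive_and_symmetric(self):
        st = self._two_chains(4.5)
        r1 = buried_interface_area(st, {"chain": "A"}, {"chain": "B"})
        r2 = buried_interface_area(st, {"chain": "B"}, {"chain": "A"})
        assert r1.interface_area > 10.0
        assert r1.interface_area == pytest.approx(r2.interface_area, rel=1e-9)
        assert r1.buried_area == pytest.approx(2 * r1.interface_area)

    def test_overlapping_selection_raises(self):
        st = self._two_chains(4.5)
        with pytest.raises(ValueError):
            buried_interface_area(st, {"chain": "A"},
                                  {"chain": "A", "res_range": (1, 3)})


class TestInterCa:
    def test_same_residue_zero(self):
        st = StructureModel([_atom("A", 1, "CA", (1, 2, 3))])
        assert inter_ca_distance(st, ("A", 1), ("A", 1)) == 0.0

    def test_known_distance(self):
        st = StructureModel([_atom("A", 1, "CA", (0, 0, 0)),
                             _atom("B", 1, "CA", (3, 4, 0))])
        assert inter_ca_distance(st, ("A", 1), ("B", 1)) == pytest.approx(5.0)

    def test_missing_ca_names_residue(self):
        st = StructureModel([_atom("A", 1, "CB", (0, 0, 0))])
        with pytest.raises(ValueError, match="A:1"):
            inter_ca_distance(st, ("A", 1), ("A", 1))


class TestSequenceMass:
    def test_polyglycine_hand_sum(self):
        # 10 × 57.0519 + 18.0153 water
        assert sequence_mass("G" * 10) * 1e3 == pytest.approx(588.53, abs=0.1)

    def test_three_letter_and_dimer(self):
        m1 = sequence_mass(["GLY"] * 10)
        m2 = sequence_mass("G" * 10, n_chains=2)
        assert m2 == pytest.approx(2 * m1)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            sequence_mass("")

    def test_unknown_code_raises(self):
        with pytest.raises(ValueError):
            sequence_mass("GAZ")


class TestC2Axis:
    def _dimer(self, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(scale=10.0, size=(20, 3)) + np.array([15.0, 5.0, 0.0])
        mirrored = base * np.array([-1.0, -1.0, 1.0])  # 180° about z
        base = base + jitter * rng.normal(size=base.shape)
        atoms = [_atom("A", i + 1, "CA", base[i]) for i in range(20)]
        atoms += [_atom("B", i + 1, "CA", mirrored[i]) for i in range(20)]
        return StructureModel(atoms)

    def test_constructed_dimer_axis(self):
        ax = find_c2_axis(self._dimer(), "A", "B")
        assert ax.rotation_angle == pytest.approx(180.0, abs=1e-6)
        assert abs(ax.direction[2]) == pytest.approx(1.0, abs=1e-9)
        assert ax.is_twofold

    def test_jittered_dimer_axis_stable(self):
        ax = find_c2_axis(self._dimer(jitter=0.5), "A", "B")
        assert 179.0 <= ax.rotation_angle <= 181.0
        angle_to_z = np.degrees(np.arccos(abs(ax.direction[2])))
        assert angle_to_z < 2.0

    def test_translated_copy_flagged_non_twofold(self):
        rng = np.random.default_rng(1)
        base = rng.normal(scale=10.0, size=(15, 3))
        atoms = [_atom("A", i + 1, "CA", base[i]) for i in range(15)]
        atoms += [_atom("B", i + 1, "CA", base[i] + np.array([50.0, 0, 0]))
                  for i in range(15)]
        ax = find_c2_axis(StructureModel(atoms), "A", "B")
        assert ax.rotation_angle < 10.0
        assert not ax.is_twofold

    def test_generator_dimer_is_twofold(self):
        st = make_model(SyntheticSpec(shape="multidomain_dimer", n_domains=2,
                                      n_res_domain=40, n_linker=6, seed=3))
        ax = find_c2_axis(st, "A", "B")
        assert ax.rotation_angle == pytest.approx(180.0, abs=1.0)


class TestAlignAxes:
    def test_already_aligned_identity(self):
        st = TestC2Axis()._dimer()
        ax = find_c2_axis(st, "A", "B")
        moved, R, t = align_axes(st, ax, ax, spin_angle=0.0)
        np.testing.assert_allclose(moved.xyz, st.xyz, atol=1e-8)

    def test_perpendicular_axes_become_colinear(self):
        st = TestC2Axis()._dimer()
        ax = find_c2_axis(st, "A", "B")
        from saxsfit.geometry import SymmetryAxis
        target = SymmetryAxis(np.array([10.0, 0.0, 0.0]),
                              np.array([1.0, 0.0, 0.0]), 180.0)
        moved, R, t = align_axes(st, ax, target)
        ax2 = find_c2_axis(moved, "A", "B")
        cosang = abs(np.dot(ax2.direction, target.direction))
        assert np.arccos(np.clip(cosang, -1, 1)) < 1e-6

    def test_idempotence(self):
        """Aligning an already-aligned structure is the identity."""
        st = TestC2Axis()._dimer()
        ax = find_c2_axis(st, "A", "B")
        from saxsfit.geometry import SymmetryAxis
        target = SymmetryAxis(np.array([5.0, -2.0, 1.0]),
                              np.array([0.0, 1.0, 0.0]), 180.0)
        moved, _, _ = align_axes(st, ax, target)
        ax_m = find_c2_axis(moved, "A", "B")
        moved2, _, _ = align_axes(moved, ax_m, target)
        np.testing.assert_allclose(moved2.xyz, moved.xyz, atol=1e-6)
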