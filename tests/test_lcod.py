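"""LCOD collective variables, gradients and restraints."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import steerpmf as sp
from steerpmf.lcod import lcod_value_and_gradient


def finite_difference_gradient(frame, spec, h=1e-6):
    """Central-difference oracle for the LCOD gradient."""
    grad = np.zeros_like(frame)
    for atom in range(frame.shape[0]):
        for axis in range(3):
            plus = frame.copy()
            minus = frame.copy()
            plus[atom, axis] += h
            minus[atom, axis] -= h
            grad[atom, axis] = (
                sp.eval_lcod(plus, spec) - sp.eval_lcod(minus, spec)
            ) / (2 * h)
    return grad


def random_frames(n_atoms=5):
    """Random frames with a minimum pairwise separation (FD-safe)."""
    def build(seed):
        rng = np.random.default_rng(seed)
        while True:
            frame = rng.uniform(-3, 3, size=(n_atoms, 3))
            d = np.linalg.norm(frame[:, None] - frame[None, :], axis=-1)
            if np.min(d[np.triu_indices(n_atoms, 1)]) > 0.3:
                return frame
    return st.integers(0, 10**6).map(build)


class TestEvalLcod:
    @pytest.mark.parametrize(
        "frame, pairs, coeffs, expected",
        [
            # single 3-4-5 pair: plain Euclidean distance
            ([[0, 0, 0], [3, 4, 0]], [(0, 1)], [1.0], 5.0),
            # proton-transfer CV with H at the donor-acceptor midpoint
            ([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]],
             [(0, 1), (2, 1)], [1.0, -1.0], 0.0),
            # three unit-coefficient pairs: distances sum
            ([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3]],
             [(0, 1), (0, 2), (0, 3)], [1.0, 1.0, 1.0], 6.0),
        ],
    )
    def test_examples(self, frame, pairs, coeffs, expected):
        spec = sp.LCODSpec(pairs, coeffs)
        assert sp.eval_lcod(np.asarray(frame, float), spec) == pytest.approx(expected)

    def test_identical_atom_pair_contributes_zero_with_warning(self):
        spec = sp.LCODSpec([(0, 0), (0, 1)], [1.0, 1.0])
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        with pytest.warns(UserWarning, match="identical atoms"):
            assert sp.eval_lcod(frame, spec) == pytest.approx(2.0)

    def test_out_of_range_index_raises(self):
        spec = sp.LCODSpec([(0, 5)], [1.0])
        with pytest.raises(IndexError):
            sp.eval_lcod(np.zeros((3, 3)), spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            sp.LCODSpec([], [])
        with pytest.raises(ValueError):
            sp.LCODSpec([(0, 1)], [1.0, 2.0])
        with pytest.raises(IndexError):
            sp.LCODSpec([(-1, 0)], [1.0])

    @given(random_frames(), st.integers(1, 4))
    @settings(max_examples=25, deadline=None)
    def test_negating_coefficients_negates_value(self, frame, n_pairs):
        rng = np.random.default_rng(n_pairs)
        pairs = [tuple(rng.choice(5, 2, replace=False)) for _ in range(n_pairs)]
        coeffs = rng.uniform(-2, 2, n_pairs)
        spec = sp.LCODSpec(pairs, coeffs)
        assert sp.eval_lcod(frame, spec.negated()) == pytest.approx(
            -sp.eval_lcod(frame, spec), abs=1e-12
        )

    @given(random_frames(), st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_rigid_rotation_invariance(self, frame, seed):
        from scipy.spatial.transform import Rotation

        spec = sp.LCODSpec([(0, 1), (2, 3)], [1.0, -0.5])
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        rotated = frame @ rot.T
        assert sp.eval_lcod(rotated, spec) == pytest.approx(
            sp.eval_lcod(frame, spec), abs=1e-9
        )


class TestLcodGradient:
    def test_single_pair_unit_vectors(self):
        spec = sp.LCODSpec([(0, 1)], [1.0])
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        grad = sp.lcod_gradient(frame, spec)
        np.testing.assert_allclose(grad[0], [-1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(grad[1], [1, 0, 0], atol=1e-12)

    def test_translation_invariance(self):
        spec = sp.LCODSpec([(0, 1), (1, 2)], [1.0, -2.0])
        frame = np.random.default_rng(3).uniform(-2, 2, (4, 3))
        grad = sp.lcod_gradient(frame, spec)
        # net gradient dotted with any rigid translation vanishes
        np.testing.assert_allclose(grad.sum(axis=0), 0.0, atol=1e-12)

    def test_repeated_atoms_accumulate(self):
        # shared hydrogen (atom 1) appears in both pairs
        spec = sp.LCODSpec([(0, 1), (2, 1)], [1.0, -1.0])
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        grad = sp.lcod_gradient(frame, spec)
        # d(0,1) pulls +x on atom1; -d(2,1) also pulls +x on atom1
        np.testing.assert_allclose(grad[1], [2.0, 0, 0], atol=1e-12)

    def test_zero_separation_raises(self):
        spec = sp.LCODSpec([(0, 1)], [1.0])
        with pytest.raises(sp.DegenerateGeometryError):
            sp.lcod_gradient(np.zeros((2, 3)), spec)
        with pytest.raises(sp.DegenerateGeometryError):
            lcod_value_and_gradient(np.zeros((2, 3)), spec)

    @given(random_frames())
    @settings(max_examples=25, deadline=None)
    def test_matches_finite_differences(self, frame):
        spec = sp.LCODSpec([(0, 1), (2, 1), (3, 4)], [1.0, -1.0, 0.7])
        analytic = sp.lcod_gradient(frame, spec)
        numeric = finite_difference_gradient(frame, spec)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-8)

    @given(random_frames())
    @settings(max_examples=25, deadline=None)
    def test_fused_helper_matches_separate_calls(self, frame):
        spec = sp.LCODSpec([(0, 1), (2, 3)], [1.0, -0.5])
        value, grad = lcod_value_and_gradient(frame, spec)
        assert value == pytest.approx(sp.eval_lcod(frame, spec), abs=1e-12)
        np.testing.assert_allclose(grad, sp.lcod_gradient(frame, spec), atol=1e-12)


class TestHarmonicPathRestraint:
    def test_zero_at_target(self):
        spec = sp.LCODSpec([(0, 1)], [1.0])
        restraint = sp.HarmonicPathRestraint(spec, k=1000.0, lambda0=1.0, lambda1=3.0)
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        energy, forces = sp.restraint_energy_force(frame, restraint, 2.0)
        assert energy == 0.0
        np.testing.assert_allclose(forces, 0.0, atol=1e-12)

    def test_closed_form_energy(self):
        spec = sp.LCODSpec([(0, 1)], [1.0])
        restraint = sp.HarmonicPathRestraint(spec, k=1000.0, lambda0=0.0, lambda1=3.0)
        frame = np.array([[0.0, 0, 0], [2.1, 0, 0]])
        energy, _ = sp.restraint_energy_force(frame, restraint, 2.0)
        assert energy == pytest.approx(0.5 * 1000.0 * 0.1**2)  # 5.0 kcal/mol

    @given(random_frames())
    @settings(max_examples=20, deadline=None)
    def test_force_matches_finite_difference_of_energy(self, frame):
        spec = sp.LCODSpec([(0, 1), (2, 1)], [1.0, -1.0])
        restraint = sp.HarmonicPathRestraint(spec, k=47.0, lambda0=0.0, lambda1=1.0)
        lam = 0.3
        _, forces = sp.restraint_energy_force(frame, restraint, lam)
        h = 1e-6
        for atom in range(frame.shape[0]):
            for axis in range(3):
                plus, minus = frame.copy(), frame.copy()
                plus[atom, axis] += h
                minus[atom, axis] -= h
                e_p, _ = sp.restraint_energy_force(plus, restraint, lam)
                e_m, _ = sp.restraint_energy_force(minus, restraint, lam)
                fd = -(e_p - e_m) / (2 * h)
                assert forces[atom, axis] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_invalid_parameters(self):
        spec = sp.LCODSpec([(0, 1)], [1.0])
        with pytest.raises(ValueError):
            sp.HarmonicPathRestraint(spec, k=-1.0, lambda0=0.0, lambda1=1.0)
        restraint = sp.HarmonicPathRestraint(spec, k=1.0, lambda0=0.0, lambda1=1.0)
        with pytest.raises(ValueError):
            sp.restraint_energy_force(np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]],
                                      restraint, np.inf)


class TestFlatWell:
    def setup_method(self):
        self.restraint = sp.FlatWellRestraint(
            center_atom=0, satellite_atoms=(1, 2), radius=3.0, k_wall=10.0
        )

    def frame(self, d1, d2):
        return np.array([[0.0, 0, 0], [d1, 0, 0], [0, d2, 0]])

    def test_zero_inside(self):
        energy, forces = sp.flat_well_energy_force(self.frame(1.5, 2.9), self.restraint)
        assert energy == 0.0
        np.testing.assert_allclose(forces, 0.0)

    def test_closed_form_outside(self):
        delta = 0.25
        energy, forces = sp.flat_well_energy_force(
            self.frame(3.0 + delta, 1.0), self.restraint
        )
        assert energy == pytest.approx(0.5 * 10.0 * delta**2)
        # wall force pulls the satellite back toward the centre
        assert forces[1, 0] == pytest.approx(-10.0 * delta)
        assert forces[0, 0] == pytest.approx(+10.0 * delta)

    def test_continuity_at_wall(self):
        e_in, _ = sp.flat_well_energy_force(self.frame(3.0 - 1e-9, 1.0), self.restraint)
        e_out, _ = sp.flat_well_energy_force(self.frame(3.0 + 1e-9, 1.0), self.restraint)
        assert abs(e_out - e_in) < 1e-12

    def test_force_matches_finite_difference(self):
        frame = np.array([[0.1, -0.2, 0.3], [3.4, 1.0, -0.5], [-2.0, 2.5, 1.0]])
        _, forces = sp.flat_well_energy_force(frame, self.restraint)
        h = 1e-6
        for atom in range(3):
            for axis in range(3):
                plus, minus = frame.copy(), frame.copy()
                plus[atom, axis] += h
                minus[atom, axis] -= h
                e_p, _ = sp.flat_well_energy_force(plus, self.restraint)
                e_m, _ = sp.flat_well_energy_force(minus, self.restraint)
                assert forces[atom, axis] == pytest.approx(
                    -(e_p - e_m) / (2 * h), rel=1e-5, abs=1e-7
                )


class TestSelections:
    PDB_LINES = (
        "ATOM      1  OE1 GLU A  22       0.000   0.000   0.000  1.00  0.00           O\n"
        "ATOM      2  HE2 GLU A  22       1.000   0.000   0.000  1.00  0.00           H\n"
        "ATOM      3  O   HOH A  99       3.000   0.000   0.000  1.00  0.00           O\n"
        "ATOM      4  H1  HOH A  99       4.000   0.000   0.000  1.00  0.00           H\n"
        "ATOM      5  N   THR A   1       6.000   0.000   0.000  1.00  0.00           N\n"
        "END\n"
    )

    @pytest.fixture()
    def pdb_path(self, tmp_path):
        path = tmp_path / "active_site.pdb"
        path.write_text(self.PDB_LINES)
        return str(path)

    def test_resolve_by_name(self, pdb_path):
        assert sp.resolve_selection(pdb_path, "GLU 22 HE2") == 1
        assert sp.resolve_selection(pdb_path, "HOH 99 O") == 2
        assert sp.resolve_selection(pdb_path, 7) == 7  # integers pass through

    def test_resolve_missing_atom(self, pdb_path):
        with pytest.raises(IndexError):
            sp.resolve_selection(pdb_path, "GLU 22 XX9")

    def test_spec_from_triples_with_structure(self, pdb_path):
        spec = sp.spec_from_triples(
            [["GLU 22 OE1", "GLU 22 HE2", 1.0], ["HOH 99 O", "GLU 22 HE2", -1.0]],
            pdb_path,
        )
        assert spec.pairs == ((0, 1), (2, 1))
        assert spec.coefficients == (1.0, -1.0)

    def test_spec_from_triples_indices_only(self):
        spec = sp.spec_from_triples([[0, 1, 1.0]])
        assert spec.pairs == ((0, 1),)
        with pytest.raises(ValueError):
            sp.spec_from_triples([["GLU 22 OE1", 1, 1.0]])
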