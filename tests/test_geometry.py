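"""Cystine geometry: torsions, bending angles, strain energy, B averages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystmine.fixtures import CystineSpec, build_cystine, random_cystine_specs
from cystmine.geometry import (
    GeometryError,
    b_factor_average,
    bond_angle,
    dihedral,
    dse,
    measure_cystine,
    ss_state,
)
from cystmine.pdbfile import Atom, Residue, SecStructRecord

finite_angle = st.floats(-720, 720, allow_nan=False, allow_infinity=False)


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_out_of_plane_sign_matches_independent_oracles(self):
        # independent oracles sharing the standard phi/psi torsion convention
        from Bio.PDB.vectors import Vector, calc_dihedral

        mda = pytest.importorskip("MDAnalysis.lib.distances")
        val = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1))
        assert val == pytest.approx(90.0)
        assert np.degrees(
            mda.calc_dihedrals(*(np.array(p, dtype=float)[None] for p in
                                 [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)]))[0]
        ) == pytest.approx(val, abs=1e-4)
        rng = np.random.default_rng(42)
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                ours = dihedral(*pts)
            except GeometryError:
                continue
            ref = np.degrees(calc_dihedral(*[Vector(p) for p in pts]))
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_degenerate_points_raise(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(GeometryError):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (-1, 0, 0))

    def test_chi3_palindromic_atom_order_gives_equal_torsion(self, rng):
        for spec in random_cystine_specs(25, rng):
            res1, res2 = build_cystine(spec)
            cb1, sg1 = res1.coords("CB"), res1.coords("SG")
            cb2, sg2 = res2.coords("CB"), res2.coords("SG")
            assert dihedral(cb1, sg1, sg2, cb2) == pytest.approx(
                dihedral(cb2, sg2, sg1, cb1), abs=1e-9
            )


class TestMeasureCystine:
    def test_recovers_generator_targets(self):
        spec = CystineSpec(chi1=-60, chi2=-60, chi3=-90, chi2p=-60, chi1p=-60)
        geom = measure_cystine(*build_cystine(spec))
        assert geom.chi_vector == pytest.approx(spec.chi, abs=1e-6)
        assert geom.alpha1 == pytest.approx(spec.alpha1, abs=1e-6)
        assert geom.alpha2 == pytest.approx(spec.alpha2, abs=1e-6)

    def test_equilibrium_length_is_measured_exactly(self):
        geom = measure_cystine(*build_cystine(CystineSpec(d=2.038)))
        assert geom.d == pytest.approx(2.038, abs=1e-6)

    def test_side_swap_relabels_primed_quantities(self, rng):
        for spec in random_cystine_specs(10, rng):
            res1, res2 = build_cystine(spec)
            fwd = measure_cystine(res1, res2)
            rev = measure_cystine(res2, res1)
            assert rev.chi1 == pytest.approx(fwd.chi1p, abs=1e-9)
            assert rev.chi2 == pytest.approx(fwd.chi2p, abs=1e-9)
            assert rev.chi3 == pytest.approx(fwd.chi3, abs=1e-9)
            assert rev.chi2p == pytest.approx(fwd.chi2, abs=1e-9)
            assert rev.chi1p == pytest.approx(fwd.chi1, abs=1e-9)
            assert rev.alpha1 == pytest.approx(fwd.alpha2, abs=1e-9)
            assert rev.alpha2 == pytest.approx(fwd.alpha1, abs=1e-9)
            assert rev.d == pytest.approx(fwd.d, abs=1e-12)
            assert rev.dse == pytest.approx(fwd.dse, abs=1e-9)

    def test_missing_atom_error_names_the_atom(self):
        res1, res2 = build_cystine(CystineSpec())
        res2.atoms = [a for a in res2.atoms if a.name != "SG"]
        with pytest.raises(GeometryError, match="residue 2 is missing atom SG"):
            measure_cystine(res1, res2)


class TestDse:
    # hand-evaluated: all 3chi cosines are -1 at +-60; cos(2*-90) = -1, cos(3*-90) = 0
    def test_relaxed_conformation_leaves_only_chi3_threefold_term(self):
        assert dse(-60, -60, -90, -60, -60) == pytest.approx(2.51)

    # hand-evaluated: only the twofold chi3 term survives at all-180
    def test_all_trans_gives_twofold_chi3_term(self):
        assert dse(180, 180, 180, 180, 180) == pytest.approx(29.28)

    # hand-evaluated: every cosine equals 1 at the origin
    def test_all_zero_is_the_global_maximum(self):
        assert dse(0, 0, 0, 0, 0) == pytest.approx(84.5)

    @given(chi=st.tuples(*[finite_angle] * 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_side_swap_and_periodicity_invariance(self, chi):
        c1, c2, c3, c4, c5 = chi
        base = dse(c1, c2, c3, c4, c5)
        assert dse(c5, c4, c3, c2, c1) == pytest.approx(base, abs=1e-9)
        assert dse(c1 + 360, c2 - 360, c3 + 360, c4, c5) == pytest.approx(base, abs=1e-8)
        assert 0.0 <= base <= 84.5 + 1e-9

    def test_alternative_constants_are_switchable(self):
        doubled = {"k1": 16.74, "k2": 8.36, "k3_two": 29.28, "k3_three": 5.02}
        assert dse(0, 0, 0, 0, 0, constants=doubled) == pytest.approx(169.0)

    def test_non_finite_input_raises(self):
        with pytest.raises(GeometryError):
            dse(np.nan, 0, 0, 0, 0)


def _residue_with_b(b_values, names=("N", "CA", "C", "O", "CB", "SG")):
    res = Residue("A", 1, " ", "CYS")
    for name, b in zip(names, b_values):
        res.atoms.append(
            Atom(name=name, element=name[0], residue_name="CYS", chain_id="A",
                 residue_number=1, b_factor=b)
        )
    return res


class TestBFactorAverage:
    def test_constant_input(self):
        avg, missing = b_factor_average(_residue_with_b([20.0] * 6), _residue_with_b([20.0] * 6))
        assert avg == pytest.approx(20.0)
        assert missing == 0

    def test_symmetric_halves(self):
        avg, _ = b_factor_average(_residue_with_b([10.0] * 6), _residue_with_b([30.0] * 6))
        assert avg == pytest.approx(20.0)

    def test_one_to_twelve_averages_to_six_point_five(self):
        avg, _ = b_factor_average(
            _residue_with_b([1, 2, 3, 4, 5, 6]), _residue_with_b([7, 8, 9, 10, 11, 12])
        )
        assert avg == pytest.approx(6.5)

    def test_missing_atoms_are_counted_and_excluded(self):
        partial = _residue_with_b([10.0] * 4, names=("N", "CA", "C", "O"))
        avg, missing = b_factor_average(partial, _residue_with_b([10.0] * 6))
        assert missing == 2
        assert avg == pytest.approx(10.0)

    def test_no_atoms_raises(self):
        empty = Residue("A", 1, " ", "CYS")
        with pytest.raises(GeometryError):
            b_factor_average(empty, Residue("A", 2, " ", "CYS"))


class TestSsState:
    helices = [SecStructRecord("helix", "A", (10, " "), (20, " "))]
    sheets = [SecStructRecord("sheet", "A", (18, " "), (30, " "))]

    def test_helix_membership(self):
        assert ss_state("A", 15, " ", self.helices, self.sheets) == "helix"

    def test_strand_membership(self):
        assert ss_state("A", 25, " ", self.helices, self.sheets) == "strand"

    def test_no_range_is_loop(self):
        assert ss_state("A", 50, " ", self.helices, self.sheets) == "loop"
        assert ss_state("B", 15, " ", self.helices, self.sheets) == "loop"

    def test_overlap_prefers_helix(self):
        assert ss_state("A", 19, " ", self.helices, self.sheets) == "helix"


def test_bond_angle_right_angle():
    assert bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)
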