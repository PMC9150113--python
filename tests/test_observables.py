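"""R_G, SASA and hydrogen-bond detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coilglobule.errors import EmptySelectionError, TopologyError
from coilglobule.observables import (HBond, HBondCriterion, fibonacci_sphere,
                                     find_hbonds, per_residue_series,
                                     radius_of_gyration, sasa)
from coilglobule.structure_io import Frame, Topology
from coilglobule.synthetic import make_hbond_fixture

from conftest import brute_force_hbonds


def _point_topology(masses, radii=None, roles=None):
    n = len(masses)
    radii = radii if radii is not None else [0.17] * n
    roles = roles if roles is not None else ["backbone_C"] * n
    return Topology(names=[f"C{i}" for i in range(n)],
                    elements=["C"] * n, roles=roles, masses=masses,
                    radii=radii, resids=[1] * n, bonds=np.empty((0, 2), int))


BOX = np.array([50.0, 50.0, 50.0])


class TestRadiusOfGyration:
    def test_equal_mass_dumbbell_is_half_separation(self):
        top = _point_topology([12.0, 12.0])
        frame = Frame([[0, 0, 0], [0.8, 0, 0]], BOX)
        assert radius_of_gyration(frame, top) == pytest.approx(0.4)

    def test_single_atom_is_zero(self):
        top = _point_topology([12.0])
        assert radius_of_gyration(Frame([[1, 1, 1]], BOX), top) == 0.0

    def test_unit_square_corners(self):
        top = _point_topology([1.0] * 4)
        frame = Frame([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], BOX)
        assert radius_of_gyration(frame, top) == pytest.approx(math.sqrt(2) / 2)

    def test_mass_weighting(self):
        # a heavy atom pins the centre of mass
        top = _point_topology([30.0, 10.0])
        frame = Frame([[0, 0, 0], [1, 0, 0]], BOX)
        # com at 0.25; rg = sqrt((30*0.0625 + 10*0.5625)/40)
        assert radius_of_gyration(frame, top) == pytest.approx(
            math.sqrt((30 * 0.25 ** 2 + 10 * 0.75 ** 2) / 40))

    def test_empty_selection_rejected(self):
        top = _point_topology([12.0])
        with pytest.raises(EmptySelectionError):
            radius_of_gyration(Frame([[0, 0, 0]], BOX), top,
                               selection=np.array([], dtype=int))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6), st.floats(0.5, 3.0))
    def test_rigid_invariance_and_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        n = 12
        top = _point_topology(list(rng.uniform(1, 16, n)))
        xyz = rng.uniform(0, 2, (n, 3))
        rg = radius_of_gyration(Frame(xyz, BOX), top)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = xyz @ Q.T + rng.uniform(-5, 5, 3)
        assert radius_of_gyration(Frame(moved, BOX), top) == pytest.approx(rg)
        assert radius_of_gyration(Frame(xyz * scale, BOX), top) == \
            pytest.approx(rg * scale)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        top = _point_topology([16.0], radii=[0.152])
        frame = Frame([[1, 1, 1]], BOX)
        area = sasa(frame, top, probe=0.14, n_sphere_points=960)
        assert area == pytest.approx(4 * math.pi * 0.292 ** 2, rel=0.01)

    def test_distant_spheres_are_additive(self):
        top = _point_topology([12.0, 12.0], radii=[0.17, 0.17])
        frame = Frame([[0, 0, 0], [2.0, 0, 0]], BOX)
        single = 4 * math.pi * 0.31 ** 2
        assert sasa(frame, top) == pytest.approx(2 * single, rel=0.01)

    @pytest.mark.parametrize("d", [0.2, 0.35, 0.5])
    def test_two_intersecting_spheres_closed_form(self, d):
        # equal extended radii R: total accessible area 4*pi*R*(R + d/2)
        top = _point_topology([12.0, 12.0], radii=[0.17, 0.17])
        frame = Frame([[0, 0, 0], [d, 0, 0]], BOX)
        R = 0.17 + 0.14
        assert sasa(frame, top) == pytest.approx(4 * math.pi * R * (R + d / 2),
                                                 rel=0.01)

    def test_point_doubling_converges(self):
        top = _point_topology([12.0, 12.0], radii=[0.17, 0.17])
        frame = Frame([[0, 0, 0], [0.35, 0, 0]], BOX)
        a = sasa(frame, top, n_sphere_points=960)
        b = sasa(frame, top, n_sphere_points=1920)
        assert abs(b - a) / b < 0.005

    def test_missing_radius_names_atom(self):
        top = _point_topology([12.0, 12.0], radii=[0.17, np.nan])
        with pytest.raises(TopologyError, match="atom 1"):
            sasa(Frame([[0, 0, 0], [1, 0, 0]], BOX), top)

    def test_fibonacci_lattice_is_deterministic_and_unit(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.allclose(pts, fibonacci_sphere(960))

    def test_waters_do_not_occlude(self, solvated_small_chain, small_chain):
        wet_top, wet_frame = solvated_small_chain
        dry_top, dry_frame = small_chain
        dry = sasa(dry_frame, dry_top)
        n = len(dry_top)
        shifted = Frame(wet_frame.coords[:n], wet_frame.box)
        assert sasa(shifted, wet_top) == pytest.approx(dry, rel=1e-9)


class TestHBonds:
    def test_ideal_dimer_inside_cutoffs(self):
        top, frame = make_hbond_fixture("ideal_dimer",
                                        {"distance": 0.30, "angle": 0.0})
        bonds = find_hbonds(frame, top)
        assert len(bonds) == 1
        hb = bonds[0]
        assert hb.category == "water-water"
        assert hb.distance == pytest.approx(0.30, abs=1e-9)
        assert hb.angle == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("params", [
        {"distance": 0.36, "angle": 0.0},   # distance fails
        {"distance": 0.30, "angle": 31.0},  # angle fails
    ])
    def test_dimer_outside_cutoffs(self, params):
        top, frame = make_hbond_fixture("ideal_dimer", params)
        assert find_hbonds(frame, top) == []

    def test_tie_at_cutoff_distance_excluded(self):
        # 0.25 is exactly representable in binary: a clean tie
        top, frame = make_hbond_fixture("ideal_dimer",
                                        {"distance": 0.25, "angle": 0.0})
        crit = HBondCriterion(max_DA_distance=0.25)
        assert find_hbonds(frame, top, crit) == []
        crit2 = HBondCriterion(max_DA_distance=0.2500001)
        assert len(find_hbonds(frame, top, crit2)) == 1

    def test_angle_is_measured_at_donor(self):
        # H placed 25 degrees off the D->A axis: inside a 30 degree cutoff,
        # outside a 20 degree one
        top, frame = make_hbond_fixture("ideal_dimer",
                                        {"distance": 0.30, "angle": 25.0})
        assert len(find_hbonds(frame, top)) == 1
        assert find_hbonds(frame, top, HBondCriterion(0.35, 20.0)) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_periodic_boxes(self, seed):
        top, frame = make_hbond_fixture("random_box", {"n": 50, "box": 1.5},
                                        seed=seed)
        got = {(h.donor, h.hydrogen, h.acceptor)
               for h in find_hbonds(frame, top)}
        assert got == brute_force_hbonds(frame, top)

    def test_detects_bonds_across_periodic_boundary(self):
        top, _ = make_hbond_fixture("ideal_dimer", {"distance": 0.30})
        L = 3.0
        coords = np.array([[L - 0.05, 1.5, 1.5],     # donor O near +x face
                           [L - 0.05 + 0.09572, 1.5, 1.5],
                           [L - 0.11, 1.42, 1.5],
                           [0.25, 1.5, 1.5],          # acceptor across the face
                           [0.33, 1.55, 1.5],
                           [0.33, 1.45, 1.5]])
        frame = Frame(coords, [L, L, L])
        bonds = find_hbonds(frame, top)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(0.30, abs=1e-9)

    def test_polymer_water_categories(self, solvated_small_chain):
        top, frame = solvated_small_chain
        cats = {hb.category for hb in find_hbonds(frame, top)}
        assert cats <= {"polymer-polymer", "polymer-water", "water-water"}

    def test_relabelling_invariance(self):
        """Reversing atom order (with remapped topology) gives the same set."""
        top, frame = make_hbond_fixture("random_box", {"n": 30, "box": 1.4},
                                        seed=3)
        n = len(top)
        perm = np.arange(n)[::-1]
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        top2 = Topology(names=top.names[perm], elements=top.elements[perm],
                        roles=top.roles[perm], masses=top.masses[perm],
                        radii=top.radii[perm], resids=top.resids[perm],
                        bonds=inv[top.bonds])
        frame2 = Frame(frame.coords[perm], frame.box)
        got = {(h.donor, h.hydrogen, h.acceptor)
               for h in find_hbonds(frame, top)}
        got2 = {(perm[h.donor], perm[h.hydrogen], perm[h.acceptor])
                for h in find_hbonds(frame2, top2)}
        assert got == got2

    def test_donor_without_hydrogen_is_topology_error(self):
        top, frame = make_hbond_fixture("ideal_dimer", {"distance": 0.30})
        stripped = Topology(names=top.names, elements=top.elements,
                            roles=top.roles, masses=top.masses,
                            radii=top.radii, resids=top.resids,
                            bonds=np.empty((0, 2), int))
        with pytest.raises(TopologyError, match="no attached hydrogen"):
            find_hbonds(frame, stripped)


def test_per_residue_normalisation():
    assert per_residue_series([60.0], 30)[0] == 2.0
    assert per_residue_series([0.0], 30)[0] == 0.0
    vals = np.array([3.0, 6.0, 9.0])
    assert np.mean(per_residue_series(vals, 30)) == pytest.approx(
        np.mean(vals) / 30)
    with pytest.raises(ValueError):
        per_residue_series([1.0], 0)
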