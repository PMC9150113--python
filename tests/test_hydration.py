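"""Hydration-shell classification, hydrophobic fraction F, connectivity."""

import numpy as np
import pytest

from coilglobule.errors import EmptySelectionError, EmptyShellError
from coilglobule.hydration import (ShellAssignment, apply_window,
                                   classify_shell, connectivity_breakdown,
                                   hydration_series, hydrophobic_fraction,
                                   water_connectivity, water_water_bond_pairs)
from coilglobule.observables import HBondCriterion
from coilglobule.structure_io import Frame, Topology
from coilglobule.synthetic import make_hbond_fixture

from conftest import brute_force_hbonds


def _mini_system(water_positions):
    """One repeating unit's reference atoms plus waters at given O positions.

    Polymer sites: amide N at (1,1,1), amide O at (1.2,1,1), methyl carbons
    at (2,1,1) and (2,1.2,1); box 4 nm.
    """
    names = ["N1", "O1", "C5", "C6"]
    elements = ["N", "O", "C", "C"]
    roles = ["amide_N", "amide_O", "methyl_C", "methyl_C"]
    coords = [[1, 1, 1], [1.2, 1, 1], [2, 1, 1], [2, 1.2, 1]]
    resids = [1, 1, 1, 1]
    bonds = []
    for w, pos in enumerate(water_positions):
        o = len(names)
        names += ["OW", "HW1", "HW2"]
        elements += ["O", "H", "H"]
        roles += ["water_O", "water_H", "water_H"]
        resids += [2 + w] * 3
        coords += [list(pos), [pos[0] + 0.0957, pos[1], pos[2]],
                   [pos[0] - 0.024, pos[1] + 0.0926, pos[2]]]
        bonds += [(o, o + 1), (o, o + 2)]
    top = Topology(names=names, elements=elements, roles=roles,
                   masses=[14 if e == "N" else 16 if e == "O" else
                           12 if e == "C" else 1 for e in elements],
                   radii=[0.155 if e == "N" else 0.152 if e == "O" else
                          0.17 if e == "C" else 0.12 for e in elements],
                   resids=resids, bonds=np.asarray(bonds, int))
    return top, Frame(np.asarray(coords), [4.0, 4.0, 4.0])


class TestClassifyShell:
    def test_hydrophilic_only(self):
        # 0.30 nm from the amide N, far from both methyl carbons
        top, frame = _mini_system([(0.7, 1, 1)])
        a = classify_shell(frame, top)
        assert a.hydrophilic == {2} and a.hydrophobic == frozenset()
        assert a.first_shell == {2} and a.bulk == frozenset()

    def test_hydrophobic_only(self):
        # 0.50 nm from a methyl C, > 0.35 from N and O
        top, frame = _mini_system([(2.5, 1, 1)])
        a = classify_shell(frame, top)
        assert a.hydrophobic == {2} and a.hydrophilic == frozenset()
        assert a.first_shell == {2}

    def test_overlap_counts_once_in_shell(self):
        # 0.30 nm from N and 0.70 from methyl (philic only), plus one at
        # 1.7,1,1: 0.30 nm from methyl C and 0.50 from O -> phobic only,
        # plus one near both
        top, frame = _mini_system([(1.55, 1, 1)])
        a = classify_shell(frame, top)
        # 0.35 from O1 is not < 0.35 ... use distances: to O1 = 0.35 exactly?
        # 1.55-1.2=0.35 -> excluded by the strict rule; to C5 = 0.45 -> phobic
        assert a.hydrophobic == {2}
        top, frame = _mini_system([(1.52, 1, 1)])
        a = classify_shell(frame, top)
        assert a.hydrophilic == {2} and a.hydrophobic == {2}
        assert a.first_shell == {2} and len(a.first_shell) == 1

    def test_bulk_is_complement(self):
        top, frame = _mini_system([(0.7, 1, 1), (3.4, 3.4, 3.4)])
        a = classify_shell(frame, top)
        assert a.first_shell == {2} and a.bulk == {3}

    def test_minimum_image_distances_used(self):
        # water across the periodic boundary from the amide N at (1,1,1):
        # x = 1 - 0.3 + 4 -> wrapped to 0.7 + box
        top, frame = _mini_system([(4.7 % 4.0, 1, 1)])
        a = classify_shell(frame, top)
        assert a.hydrophilic == {2}

    def test_no_polymer_atoms_is_an_error(self):
        top, frame = make_hbond_fixture("random_box", {"n": 5, "box": 1.5})
        with pytest.raises(EmptySelectionError):
            classify_shell(frame, top)


class TestHydrophobicFraction:
    def test_simple_ratio(self):
        a = ShellAssignment(0.0, frozenset({1, 2}),
                            frozenset(range(3, 11)),
                            frozenset(range(1, 11)), frozenset(), 30)
        assert hydrophobic_fraction(a) == pytest.approx(8 / 10)

    def test_all_hydrophobic_gives_one(self):
        a = ShellAssignment(0.0, frozenset(), frozenset({1, 2}),
                            frozenset({1, 2}), frozenset(), 30)
        assert hydrophobic_fraction(a) == 1.0

    def test_empty_shell_undefined(self):
        a = ShellAssignment(0.0, frozenset(), frozenset(), frozenset(),
                            frozenset({1}), 30)
        with pytest.raises(EmptyShellError):
            hydrophobic_fraction(a)

    @pytest.mark.parametrize("seed", range(4))
    def test_bounds_and_radius_monotonicity(self, seed, template):
        top, frame = make_hbond_fixture("shell_bulk",
                                        {"box": 2.2, "n_residues": 8},
                                        seed=seed)
        a_wide = classify_shell(frame, top, r_phobic=0.55)
        a_narrow = classify_shell(frame, top, r_phobic=0.45)
        assert 0.0 <= hydrophobic_fraction(a_wide) <= 1.0
        assert len(a_narrow.hydrophobic) <= len(a_wide.hydrophobic)
        assert hydrophobic_fraction(a_narrow) <= hydrophobic_fraction(a_wide)
        # first-shell count monotone in both radii
        a_big = classify_shell(frame, top, r_philic=0.45, r_phobic=0.65)
        assert a_wide.n_shell <= a_big.n_shell


class TestConnectivity:
    def test_shared_bond_convention(self):
        # two waters, one bond, both in the domain -> 0.5 bonds/molecule
        top, frame = make_hbond_fixture("ideal_dimer", {"distance": 0.30})
        a = ShellAssignment(0.0, frozenset(), frozenset(), frozenset(),
                            frozenset({1, 2}), 30)
        assert water_connectivity(frame, top, domain="bulk",
                                  assignment=a) == pytest.approx(0.5)

    def test_isolated_waters_have_zero(self):
        top, frame = make_hbond_fixture("ideal_dimer", {"distance": 0.50})
        a = ShellAssignment(0.0, frozenset(), frozenset(), frozenset(),
                            frozenset({1, 2}), 30)
        assert water_connectivity(frame, top, domain="bulk", assignment=a) == 0.0

    def test_empty_domain_is_an_error(self):
        top, frame = make_hbond_fixture("ideal_dimer", {"distance": 0.30})
        a = ShellAssignment(0.0, frozenset(), frozenset(), frozenset(),
                            frozenset(), 30)
        with pytest.raises(EmptyShellError):
            water_connectivity(frame, top, domain="bulk", assignment=a)

    def test_matches_brute_force_unique_pairs(self):
        top, frame = make_hbond_fixture("random_box", {"n": 60, "box": 1.5},
                                        seed=7)
        triples = brute_force_hbonds(frame, top)
        pairs = {frozenset((int(top.resids[D]), int(top.resids[A])))
                 for D, H, A in triples}
        all_mols = frozenset(int(m) for m in top.resids[top.water_oxygens])
        a = ShellAssignment(0.0, frozenset(), frozenset(), frozenset(),
                            all_mols, 30)
        conn = water_connectivity(frame, top, domain="bulk", assignment=a)
        assert conn == pytest.approx(len(pairs) / len(all_mols))

    def test_cross_domain_bonds_counted_separately(self):
        top, frame = make_hbond_fixture("shell_bulk",
                                        {"box": 2.2, "n_residues": 8}, seed=1)
        a = classify_shell(frame, top)
        d = connectivity_breakdown(frame, top, assignment=a)
        pairs = water_water_bond_pairs(frame, top)
        n_in = (d["conn_shell"] * len(a.first_shell)
                + d["conn_bulk"] * len(a.bulk))
        assert n_in + d["n_cross_bonds"] == pytest.approx(len(pairs))


class TestHydrationSeries:
    def test_constant_occupancy_has_zero_sd(self):
        top, frame = _mini_system([(0.7, 1, 1)])
        df = hydration_series([frame, frame, frame], top)
        assert df["n_per_residue"].std(ddof=1) == 0.0
        assert df["n_per_residue"].iloc[0] == pytest.approx(1.0)

    def test_window_keeps_trailing_fraction(self):
        top, f = _mini_system([(0.7, 1, 1)])
        frames = []
        for k in range(6):
            g = f.copy()
            g.time = float(k)
            frames.append(g)
        df = hydration_series(frames, top, window=0.5)
        assert list(df["time"]) == [3.0, 4.0, 5.0]
        df2 = apply_window(hydration_series(frames, top), (1, 3))
        assert list(df2["time"]) == [1.0, 2.0]

    def test_mean_commutes_with_per_residue_normalisation(self):
        top, f1 = _mini_system([(0.7, 1, 1), (3.4, 3.4, 3.4)])  # 1 in shell
        _, f2 = _mini_system([(0.7, 1, 1), (2.5, 1, 1)])        # 2 in shell
        df = hydration_series([f1, f2], top)
        assert df["n_per_residue"].mean() == pytest.approx(
            df["n_shell"].mean() / 1)  # one repeating unit in the mini system
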