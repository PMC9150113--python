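import math

import numpy as np
import pytest

from coilglobule.observables import HBondCriterion
from coilglobule.structure_io import minimum_image_vector
from coilglobule.synthetic import build_chain, default_template, solvate


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def small_chain(template):
    """A 5-mer conformer (topology, frame) used by IO and observable tests."""
    return build_chain(template, n_residues=5, compactness=0.3, seed=42)


@pytest.fixture(scope="session")
def solvated_small_chain(template, small_chain):
    top, frame = small_chain
    return solvate(top, frame, box_length=2.5, density=0.997, seed=42)


def brute_force_hbonds(frame, topology, criterion=HBondCriterion()):
    """All-triples reference for the geometric H-bond criterion.

    Deliberately plain loops over every (donor, H, acceptor) triple with
    minimum-image vectors; the implementation under test must match exactly.
    """
    adj = topology.adjacency()
    donors = []
    for d in topology.indices_by_role("amide_N", "water_O"):
        for h in topology.attached_hydrogens(int(d), adj):
            donors.append((int(d), h))
    acceptors = [int(a) for a in topology.indices_by_role("amide_O", "water_O")]
    cos_cut = math.cos(math.radians(criterion.max_HDA_angle))
    out = set()
    for D, H in donors:
        for A in acceptors:
            if A == D or topology.resids[A] == topology.resids[D]:
                continue
            vDA = minimum_image_vector(frame.coords[D], frame.coords[A],
                                       frame.box)
            dist = float(np.linalg.norm(vDA))
            if not dist < criterion.max_DA_distance:
                continue
            vDH = minimum_image_vector(frame.coords[D], frame.coords[H],
                                       frame.box)
            c = float(np.dot(vDH, vDA) / (np.linalg.norm(vDH) * dist))
            if c > cos_cut:
                out.add((D, H, A))
    return out
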