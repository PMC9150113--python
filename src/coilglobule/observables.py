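"""Per-frame structural observables: R_G, SASA and geometric hydrogen bonds.

Three quantities track the coil-to-globule transition of the chain:

* the mass-weighted radius of gyration,
  ``R_G = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i )``;
* the solvent-accessible surface area (SASA), the area of the van der Waals
  envelope of the solute inflated by the probe radius (0.14 nm), estimated
  with the Shrake-Rupley point-counting construction on a deterministic
  Fibonacci sphere lattice;
* hydrogen bonds under the geometric criterion: donor-acceptor distance
  below 0.35 nm and hydrogen-donor-acceptor angle below 30 degrees, both
  strict, with minimum-image distances.

The H-D-A angle is measured at the donor, between the D->H and D->A
vectors (the convention of the standard trajectory-analysis tools); the
criterion object makes both thresholds explicit and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptySelectionError, TopologyError
from .structure_io import (Frame, Topology, minimum_image_vector, wrap_coords)

DEFAULT_PROBE_RADIUS = 0.14  # nm
DEFAULT_SPHERE_POINTS = 960


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond thresholds (both comparisons strict)."""

    max_DA_distance: float = 0.35  # nm
    max_HDA_angle: float = 30.0    # degrees

    def __post_init__(self):
        if not self.max_DA_distance > 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_HDA_angle < 90:
            raise ValueError("angle cutoff must be in (0, 90) degrees")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float
    category: str  # polymer-polymer | polymer-water | water-water


def radius_of_gyration(frame: Frame, topology: Topology,
                       selection: np.ndarray | None = None) -> float:
    """Mass-weighted R_G (nm) of the selection (default: whole polymer).

    The polymer must be whole (unwrapped) beforehand.
    """
    sel = topology.polymer_indices if selection is None else np.asarray(selection)
    if len(sel) == 0:
        raise EmptySelectionError("radius_of_gyration: empty selection")
    m = topology.masses[sel]
    r = frame.coords[sel]
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    sq = ((r - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * sq).sum() / m.sum()))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform deterministic unit-sphere point set (golden-angle lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sasa(frame: Frame, topology: Topology, probe: float = DEFAULT_PROBE_RADIUS,
         n_sphere_points: int = DEFAULT_SPHERE_POINTS,
         selection: np.ndarray | None = None) -> float:
    """Shrake-Rupley solvent-accessible surface area (nm^2) of the solute.

    For every solute atom, the fraction of lattice points on its extended
    sphere (r_vdW + probe) lying outside every other solute atom's extended
    sphere is multiplied by the full sphere area and summed.  Waters are
    excluded both as surface atoms and as occluders; the solute must be
    whole, so no periodic images are considered.
    """
    sel = topology.polymer_indices if selection is None else np.asarray(selection)
    if len(sel) == 0:
        raise EmptySelectionError("sasa: empty selection")
    radii = topology.radii[sel]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = sel[np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[0]]
        raise TopologyError(f"atom {int(bad)} has no usable vdW radius")
    centers = frame.coords[sel]
    ext = radii + probe
    unit = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(centers)
    max_ext = float(ext.max())
    neighbor_lists = tree.query_ball_point(centers, ext + max_ext)
    total = 0.0
    for k in range(len(sel)):
        pts = centers[k] + ext[k] * unit
        nbrs = [j for j in neighbor_lists[k] if j != k]
        # nearest occluders first, dropping buried points incrementally
        if nbrs:
            nbrs = sorted(nbrs, key=lambda j: np.dot(centers[j] - centers[k],
                                                     centers[j] - centers[k]))
        alive = np.ones(n_sphere_points, dtype=bool)
        for j in nbrs:
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            d2 = ((pts[idx] - centers[j]) ** 2).sum(axis=1)
            alive[idx[d2 < ext[j] * ext[j]]] = False
        total += alive.mean() * 4.0 * math.pi * ext[k] ** 2
    return float(total)


def _donor_table(topology: Topology) -> list[tuple[int, int]]:
    """(donor, attached hydrogen) pairs: amide N via its H, water O via both H."""
    adj = topology.adjacency()
    pairs: list[tuple[int, int]] = []
    for d in topology.indices_by_role("amide_N", "water_O"):
        hs = topology.attached_hydrogens(int(d), adj)
        if not hs:
            raise TopologyError(f"donor atom {int(d)} has no attached hydrogen")
        pairs.extend((int(d), h) for h in hs)
    return pairs


def _category(role_d: str, role_a: str) -> str:
    dw = role_d == "water_O"
    aw = role_a == "water_O"
    if dw and aw:
        return "water-water"
    if dw or aw:
        return "polymer-water"
    return "polymer-polymer"


def find_hbonds(frame: Frame, topology: Topology,
                criterion: HBondCriterion = HBondCriterion()) -> list[HBond]:
    """All (donor, H, acceptor) triples passing the geometric criterion.

    Donors are amide nitrogens (through their amide H) and water oxygens
    (through both hydrogens); acceptors are carbonyl oxygens and water
    oxygens.  Pairs within the same residue/molecule are excluded.  All
    distances are minimum-image.
    """
    donors = _donor_table(topology)
    acceptors = topology.indices_by_role("amide_O", "water_O")
    if not donors or len(acceptors) == 0:
        return []
    box = frame.box
    pos = wrap_coords(frame.coords, box)
    d_idx = np.array([d for d, _ in donors])
    h_idx = np.array([h for _, h in donors])
    atree = cKDTree(pos[acceptors], boxsize=box)
    dtree = cKDTree(pos[d_idx], boxsize=box)
    cand = dtree.query_ball_tree(atree, criterion.max_DA_distance)
    cos_cut = math.cos(math.radians(criterion.max_HDA_angle))
    out: list[HBond] = []
    for k, alist in enumerate(cand):
        if not alist:
            continue
        D, H = int(d_idx[k]), int(h_idx[k])
        for a in alist:
            A = int(acceptors[a])
            if A == D or topology.resids[A] == topology.resids[D]:
                continue
            vDA = minimum_image_vector(frame.coords[D], frame.coords[A], box)
            dist = float(np.linalg.norm(vDA))
            if not dist < criterion.max_DA_distance:
                continue  # tie at the cutoff is excluded
            vDH = minimum_image_vector(frame.coords[D], frame.coords[H], box)
            nH = np.linalg.norm(vDH)
            if nH < 1e-12 or dist < 1e-12:
                continue
            c = float(np.dot(vDH, vDA) / (nH * dist))
            if c > cos_cut:  # angle strictly below the cutoff
                angle = math.degrees(math.acos(max(-1.0, min(1.0, c))))
                out.append(HBond(D, H, A, dist, angle,
                                 _category(topology.roles[D], topology.roles[A])))
    return out


def count_hbonds_by_category(hbonds: list[HBond]) -> dict[str, int]:
    counts = {"polymer-polymer": 0, "polymer-water": 0, "water-water": 0}
    for hb in hbonds:
        counts[hb.category] += 1
    return counts


def per_residue_series(values, n_residues: int = 30) -> np.ndarray:
    """Normalise a per-frame series to the number of repeating units."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return np.asarray(values, dtype=float) / n_residues
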