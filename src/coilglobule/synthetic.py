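"""Synthetic polymer-in-water configurations with known ground truth.

Every pipeline input can be generated here without running molecular
dynamics: an atactic 30-unit chain of an acrylamide-type repeating unit
(backbone CH2-CH plus an isopropyl-amide side group: one amide N, one amide
O, two methyl carbons per unit), water placed on a jittered lattice at a
target density, and temperature-series ensembles whose chain compactness
follows a logistic schedule with a prescribed midpoint.

The generator is geometric, not energetic: conformers come from a
self-avoiding persistent walk whose step-direction persistence decreases
(and centroid attraction increases) with a ``compactness`` control in
[0, 1]; water is rigid three-site geometry with the M site implied by the
water model.  All randomness flows from explicit seeds and every ensemble
writes a manifest sufficient to regenerate it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ChainBuildError, SolvationError
from .structure_io import (BONDI_RADII, MASSES, Frame, Topology, append_gro,
                           wrap_coords, write_topology)
from .water_models import WaterModel, builtin_model

AVOGADRO = 6.02214076e23
WATER_MOLAR_MASS = 18.015  # g/mol

MIN_HEAVY_SEPARATION = 0.25  # nm, non-bonded heavy-atom clash threshold
EXCLUSION_BOND_DEPTH = 4     # pairs within this many bonds are not checked
SOLUTE_CLEARANCE = 0.24      # nm, minimum water-O to solute distance

_BACKBONE_STEP = 0.153  # nm, C-C bond


# ---------------------------------------------------------------------------
# residue template


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    role: str


@dataclass
class ResidueTemplate:
    """Atom list, internal bonds and side-group local geometry of one unit.

    Local frame: backbone tangent +x, side-chain attachment +z, binormal +y;
    ``side_coords`` are offsets from the second backbone carbon (C2) for
    atoms 4..18, ``c1_h_offsets`` are the two H offsets from C1.
    """

    atoms: list[TemplateAtom]
    bonds: list[tuple[int, int]]
    side_coords: np.ndarray        # (15, 3) offsets for local atoms 4..18
    c1_h_offsets: np.ndarray       # (2, 3)
    i_c1: int = 0
    i_c2: int = 3

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_local(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def default_template() -> ResidueTemplate:
    """The built-in acrylamide-type repeating unit (19 atoms).

    Local atom order: C1 H11 H12 C2 H21 C3 O1 N1 HN C4 H41 C5 H51 H52 H53
    C6 H61 H62 H63.  Bond lengths: C-C 0.153, C=O 0.123, C-N 0.134,
    N-C 0.147, N-H 0.101, C-H 0.109 nm.
    """
    A = TemplateAtom
    atoms = [
        A("C1", "C", "backbone_C"), A("H11", "H", "backbone_H"),
        A("H12", "H", "backbone_H"), A("C2", "C", "backbone_C"),
        A("H21", "H", "backbone_H"), A("C3", "C", "carbonyl_C"),
        A("O1", "O", "amide_O"), A("N1", "N", "amide_N"),
        A("HN", "H", "amide_H"), A("C4", "C", "isopropyl_CH"),
        A("H41", "H", "backbone_H"), A("C5", "C", "methyl_C"),
        A("H51", "H", "methyl_H"), A("H52", "H", "methyl_H"),
        A("H53", "H", "methyl_H"), A("C6", "C", "methyl_C"),
        A("H61", "H", "methyl_H"), A("H62", "H", "methyl_H"),
        A("H63", "H", "methyl_H"),
    ]
    bonds = [(0, 1), (0, 2), (0, 3), (3, 4), (3, 5), (5, 6), (5, 7), (7, 8),
             (7, 9), (9, 10), (9, 11), (9, 15), (11, 12), (11, 13), (11, 14),
             (15, 16), (15, 17), (15, 18)]
    coords = np.zeros((19, 3))
    coords[4] = 0.109 * _unit([-0.3, 0.0, -0.95])          # H21
    coords[5] = [0.0, 0.0, 0.153]                          # C3
    coords[6] = coords[5] + 0.123 * np.array([-0.866, 0.0, 0.5])   # O1
    coords[7] = coords[5] + 0.134 * np.array([0.866, 0.0, 0.5])    # N1
    coords[8] = coords[7] + 0.101 * np.array([0.866, 0.0, -0.5])   # HN
    coords[9] = coords[7] + 0.147 * np.array([0.0, 0.0, 1.0])      # C4
    coords[10] = coords[9] + 0.109 * _unit([-0.70, 0.0, 0.71])     # H41
    coords[11] = coords[9] + _BACKBONE_STEP * _unit([0.40, 0.82, 0.40])   # C5
    coords[15] = coords[9] + _BACKBONE_STEP * _unit([0.40, -0.82, 0.40])  # C6
    for c_methyl, h_slots in ((11, (12, 13, 14)), (15, (16, 17, 18))):
        u = _unit(coords[c_methyl] - coords[9])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        p1 = _unit(ref - np.dot(ref, u) * u)
        p2 = np.cross(u, p1)
        for k, h in enumerate(h_slots):
            ang = 2.0 * math.pi * k / 3.0
            d = _unit(u / 3.0 + (p1 * math.cos(ang) + p2 * math.sin(ang))
                      * math.sqrt(8.0) / 3.0)
            coords[h] = coords[c_methyl] + 0.109 * d
    c1_h = np.array([0.109 * _unit([0.0, 0.8, -0.6]),
                     0.109 * _unit([0.0, -0.8, -0.6])])
    return ResidueTemplate(atoms=atoms, bonds=bonds,
                           side_coords=coords[4:19].copy(), c1_h_offsets=c1_h)


# ---------------------------------------------------------------------------
# chain topology and clash exclusions


def chain_topology(template: ResidueTemplate, n_residues: int) -> Topology:
    """Topology (names, roles, masses, radii, resids, bonds) of an n-mer."""
    names, elements, roles, resids = [], [], [], []
    bonds: list[tuple[int, int]] = []
    na = template.n_atoms
    for r in range(n_residues):
        off = r * na
        for a in template.atoms:
            names.append(a.name)
            elements.append(a.element)
            roles.append(a.role)
            resids.append(r + 1)
        bonds.extend((off + i, off + j) for i, j in template.bonds)
        if r > 0:  # backbone link C2(prev) - C1(this)
            bonds.append(((r - 1) * na + template.i_c2, off + template.i_c1))
    masses = [MASSES[e] for e in elements]
    radii = [BONDI_RADII[e] for e in elements]
    return Topology(names=names, elements=elements, roles=roles, masses=masses,
                    radii=radii, resids=resids,
                    bonds=np.asarray(bonds, dtype=int))


def _exclusion_sets(topology: Topology, depth: int = EXCLUSION_BOND_DEPTH
                    ) -> dict[int, set[int]]:
    """Heavy atoms within ``depth`` bonds of each heavy atom (clash-exempt)."""
    adj = topology.adjacency()
    heavy = np.flatnonzero(topology.elements != "H")
    heavy_set = set(int(h) for h in heavy)
    out: dict[int, set[int]] = {}
    for a in heavy:
        a = int(a)
        frontier = {a}
        seen = {a}
        for _ in range(depth):
            frontier = {m for f in frontier for m in adj[f]} - seen
            seen |= frontier
        out[a] = (seen & heavy_set) - {a}
    return out


# ---------------------------------------------------------------------------
# chain builder


def _walk_parameters(compactness: float) -> tuple[float, float]:
    """(step randomness amplitude, centroid attraction) for the walk."""
    amp = 0.20 + 1.0 * compactness
    attraction = 0.45 * compactness
    return amp, attraction


def build_chain(template: ResidueTemplate | None = None, n_residues: int = 30,
                compactness: float = 0.5,
                seed: int | np.random.Generator = 0,
                max_restarts: int = 120) -> tuple[Topology, Frame]:
    """Self-avoiding chain conformer with tunable compactness in [0, 1].

    The backbone is a persistent random walk (persistence falls, and a
    centroid-attraction bias grows, with ``compactness``); side groups are
    attached with a random dihedral and a random mirror reflection per unit
    (approximate atacticity).  No pair of heavy atoms more than
    ``EXCLUSION_BOND_DEPTH`` bonds apart sits closer than 0.25 nm.
    ``compactness`` 0 yields extended conformers, 1 collapsed ones.
    """
    if not 0.0 <= compactness <= 1.0:
        raise ValueError("compactness must lie in [0, 1]")
    template = template or default_template()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    topology = chain_topology(template, n_residues)
    excl = _exclusion_sets(topology)
    na = template.n_atoms
    heavy_local = template.heavy_local

    for attempt in range(max_restarts):
        # hard seeds: progressively relax the centroid attraction so dense
        # globules remain buildable rather than failing outright
        relax = 1.0 if attempt < max_restarts // 2 else 0.8
        coords = _try_build(template, n_residues, compactness, rng,
                            topology, excl, na, heavy_local, relax)
        if coords is not None:
            coords -= coords.mean(axis=0)
            extent = coords.max(axis=0) - coords.min(axis=0)
            L = float(extent.max() + 1.0)
            coords += L / 2.0
            return topology, Frame(coords, np.array([L, L, L]))
    raise ChainBuildError(
        f"chain placement failed after {max_restarts} restarts "
        f"(n={n_residues}, compactness={compactness}, seed={seed!r})")


def _try_build(template, n_residues, compactness, rng, topology, excl,
               na, heavy_local, relax: float = 1.0):
    """One growth attempt: residue by residue, backbone step + side group.

    If a residue's side group cannot be placed, its backbone steps are
    resampled (local backtracking) before the whole attempt is abandoned.
    """
    amp, attraction = _walk_parameters(compactness)
    attraction *= relax
    placed = np.full((len(topology), 3), np.nan)
    placed_mask = np.zeros(len(topology), dtype=bool)
    is_heavy = topology.elements != "H"
    side_locals = list(range(4, 19))

    def heavy_clash(idx: int, x: np.ndarray) -> bool:
        others = np.flatnonzero(placed_mask & is_heavy)
        if len(others) == 0:
            return False
        ex = excl[idx]
        keep = [o for o in others if o not in ex]
        if not keep:
            return False
        dist = np.linalg.norm(placed[keep] - x, axis=1)
        return bool((dist < MIN_HEAVY_SEPARATION).any())

    def gi(res: int, local: int) -> int:
        return res * na + local

    def sample_step(prev: np.ndarray, d: np.ndarray, k: int,
                    bb_so_far: list[np.ndarray]) -> np.ndarray:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        step = d + amp * u
        if attraction > 0 and k > 4:
            centroid = np.mean(bb_so_far, axis=0)
            to_c = centroid - prev
            nc = np.linalg.norm(to_c)
            if nc > 1e-9:
                step = step + attraction * min(1.0, nc) * to_c / nc
        return step / np.linalg.norm(step)

    def place_side(res: int, c1, c2, c2_next_dir):
        t = c2_next_dir
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, t)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        n0 = _unit(ref - np.dot(ref, t) * t)
        mirror = 1.0 if rng.random() < 0.5 else -1.0
        for trial in range(40):
            m = mirror if trial < 20 else -mirror
            psi = rng.uniform(0.0, 2.0 * math.pi)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            nrot = math.cos(psi) * n0 + math.sin(psi) * np.cross(t, n0)
            b = np.cross(t, nrot)
            local = template.side_coords.copy()
            local[:, 1] *= m
            cphi, sphi = math.cos(phi), math.sin(phi)
            xy = local[:, :2].copy()
            local[:, 0] = cphi * xy[:, 0] - sphi * xy[:, 1]
            local[:, 1] = sphi * xy[:, 0] + cphi * xy[:, 1]
            world = (c2 + local[:, 0:1] * t + local[:, 1:2] * b
                     + local[:, 2:3] * nrot)
            if any(heavy_clash(gi(res, li), w)
                   for li, w in zip(side_locals, world)
                   if template.atoms[li].element != "H"):
                continue
            return world, t, b, nrot
        return None

    bb: list[np.ndarray] = []
    d = np.array([1.0, 0.0, 0.0])
    for res in range(n_residues):
        ok = False
        for _ in range(30):
            # backbone pair C1, C2
            if res == 0:
                c1 = np.zeros(3)
                d1 = d
            else:
                d1 = sample_step(bb[-1], d, 2 * res, bb)
                c1 = bb[-1] + _BACKBONE_STEP * d1
                if heavy_clash(gi(res, template.i_c1), c1):
                    continue
            d2 = sample_step(c1, d1, 2 * res + 1, bb + [c1])
            c2 = c1 + _BACKBONE_STEP * d2
            if heavy_clash(gi(res, template.i_c2), c2):
                continue
            side = place_side(res, c1, c2, _unit(c2 - c1))
            if side is None:
                continue
            world, t, b, nrot = side
            bb.extend([c1, c2])
            placed[gi(res, template.i_c1)] = c1
            placed[gi(res, template.i_c2)] = c2
            placed_mask[gi(res, template.i_c1)] = True
            placed_mask[gi(res, template.i_c2)] = True
            for li, w in zip(side_locals, world):
                placed[gi(res, li)] = w
                placed_mask[gi(res, li)] = True
            for off, li in zip(template.c1_h_offsets, (1, 2)):
                placed[gi(res, li)] = c1 + off[0] * t + off[1] * b + off[2] * nrot
                placed_mask[gi(res, li)] = True
            d = d2
            ok = True
            break
        if not ok:
            return None
    assert placed_mask.all()
    return placed


# ---------------------------------------------------------------------------
# solvation


def water_count_for(density: float, box_length: float) -> int:
    """Ideal molecule count for a cubic box at the target density."""
    return int(round(density * box_length ** 3 * AVOGADRO
                     / WATER_MOLAR_MASS * 1e-21))


def orient_along_diagonal(coords: np.ndarray) -> np.ndarray:
    """Rotate so the principal axis of the point cloud lies on (1,1,1)."""
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    target = _unit([1.0, 1.0, 1.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return c
    cth = float(np.dot(axis, target))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - cth) / s ** 2)
    return c @ R.T


def solvate(topology: Topology, frame: Frame, box_length: float,
            density: float = 0.997, model: WaterModel | None = None,
            seed: int | np.random.Generator = 0,
            clearance: float = SOLUTE_CLEARANCE,
            orient: str | None = None) -> tuple[Topology, Frame]:
    """Add lattice-jitter water around the solute at a target density.

    Water oxygens go on a jittered cubic lattice; any site whose oxygen
    would sit within ``clearance`` (minimum image) of a solute atom is
    dropped, so the final count is the ideal count minus the excluded
    sites.  Hydrogens use the model's rigid geometry (default TIP4P-family)
    with random orientations.  ``orient="diagonal"`` first rotates the
    solute's principal axis onto the box diagonal.  An empty topology
    solvates a neat-water box.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    model = model or builtin_model("TIP4P/2005")
    if box_length <= 0:
        raise SolvationError("box length must be positive")
    n_target = water_count_for(density, box_length)
    if n_target < 1:
        raise SolvationError(
            f"density {density} g/cm^3 unattainable in a {box_length} nm box")
    box = np.array([box_length] * 3)

    solute_xyz = np.asarray(frame.coords, dtype=float)
    if len(solute_xyz):
        if orient == "diagonal":
            solute_xyz = orient_along_diagonal(solute_xyz)
        solute_xyz = solute_xyz - solute_xyz.mean(axis=0) + box / 2.0

    m = max(1, math.ceil(n_target ** (1.0 / 3.0)))
    a = box_length / m
    grid = (np.stack(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"), axis=-1)
            .reshape(-1, 3) + 0.5) * a
    pick = rng.choice(len(grid), size=n_target, replace=False)
    sites = grid[pick] + rng.uniform(-0.3 * a, 0.3 * a, size=(n_target, 3))
    sites = wrap_coords(sites, box)
    if len(solute_xyz):
        tree = cKDTree(wrap_coords(solute_xyz, box), boxsize=box)
        near = tree.query_ball_point(sites, clearance)
        keep = np.array([len(h) == 0 for h in near])
        sites = sites[keep]
    n_w = len(sites)
    if n_w == 0:
        raise SolvationError("no water sites survive the solute clearance")

    # rigid three-site water with random orientation
    r_oh = model.r_OH * 0.1  # angstrom -> nm
    half = math.radians(model.theta_HOH) / 2.0
    u = rng.normal(size=(n_w, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    ref = np.where(np.abs(u[:, 2:3]) < 0.9,
                   np.tile([0.0, 0.0, 1.0], (n_w, 1)),
                   np.tile([1.0, 0.0, 0.0], (n_w, 1)))
    p = ref - (u * ref).sum(axis=1, keepdims=True) * u
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    h1 = sites + r_oh * (math.cos(half) * u + math.sin(half) * p)
    h2 = sites + r_oh * (math.cos(half) * u - math.sin(half) * p)

    n_solute = len(solute_xyz)
    waters = np.stack([sites, h1, h2], axis=1).reshape(-1, 3)
    coords = np.vstack([solute_xyz, waters]) if n_solute else waters

    pol_max = int(topology.resids.max()) if len(topology) else 0
    names = list(topology.names)
    elements = list(topology.elements)
    roles = list(topology.roles)
    masses = list(topology.masses)
    radii = list(topology.radii)
    resids = list(int(r) for r in topology.resids)
    bonds = [tuple(int(v) for v in bnd) for bnd in topology.bonds]
    for w in range(n_w):
        o_idx = n_solute + 3 * w
        names += ["OW", "HW1", "HW2"]
        elements += ["O", "H", "H"]
        roles += ["water_O", "water_H", "water_H"]
        masses += [MASSES["O"], MASSES["H"], MASSES["H"]]
        radii += [BONDI_RADII["O"], BONDI_RADII["H"], BONDI_RADII["H"]]
        resids += [pol_max + 1 + w] * 3
        bonds += [(o_idx, o_idx + 1), (o_idx, o_idx + 2)]
    top = Topology(names=names, elements=elements, roles=roles, masses=masses,
                   radii=radii, resids=resids, bonds=np.asarray(bonds, dtype=int))
    return top, Frame(coords, box, time=frame.time,
                      temperature=frame.temperature, pressure=frame.pressure)


# ---------------------------------------------------------------------------
# temperature-series ensembles


@dataclass
class EnsembleSpec:
    """Study conditions of a synthetic temperature/pressure ensemble.

    Defaults mirror the analysed study at desk scale: a 30-unit chain on a
    278-308 K grid every 5 K with bulk-density water in a 4 nm box.  Each
    frame is drawn from a two-state mixture: globule with logistic occupation
    probability ``1/(1 + exp(-(T - T_C*)/w))`` (midpoint at the prescribed
    transition temperature of its pressure), coil otherwise, plus Gaussian
    frame noise on the compactness.  Because state populations mix linearly,
    the ensemble mean of *every* conformational observable (R_G, SASA, shell
    occupancy) follows a sigmoid in T with the same midpoint — the
    statistical structure the transition fits assume.
    """

    n_residues: int = 30
    box_length: float = 4.0
    density: float = 0.997
    temperatures: tuple = (278.0, 283.0, 288.0, 293.0, 298.0, 303.0, 308.0)
    pressures: tuple = (0.1,)
    true_tc: dict = field(default_factory=lambda: {0.1: 295.0})
    width_K: float = 2.5
    noise_sd: float = 0.05
    frames_per_point: int = 50
    seed: int = 2024
    model_name: str = "TIP4P/2005"
    include_water: bool = True
    compactness_coil: float = 0.0
    compactness_globule: float = 1.0
    shell_water_boost: float = 0.0  # placement bias; 0 = plain bulk solvation

    def validate(self) -> None:
        if self.compactness_coil >= self.compactness_globule:
            raise ValueError("coil compactness must be below globule compactness")
        if sorted(self.pressures) != sorted(self.true_tc):
            raise ValueError("true_tc must list every pressure")
        if self.frames_per_point < 1 or self.n_residues < 1:
            raise ValueError("frames_per_point and n_residues must be >= 1")

    def globule_probability(self, T: float, P: float) -> float:
        """Logistic occupation of the globule state at (T, P)."""
        tc = self.true_tc[P]
        return 1.0 / (1.0 + math.exp(-(T - tc) / self.width_K))


def generate_ensemble(spec: EnsembleSpec, out_dir) -> dict:
    """Write per-state-point GRO trajectories, sidecars and a manifest.

    Frame ``j`` at (T, P) uses compactness ``schedule(T, P) + noise`` and an
    independent sub-seed derived from ``(spec.seed, P index, T index, j)``;
    the same spec and seed reproduce the files byte for byte.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = default_template()
    polymer_top = chain_topology(template, spec.n_residues)
    polymer_top_path = out_dir / "polymer.top.tsv"
    write_topology(polymer_top_path, polymer_top)
    model = builtin_model(spec.model_name)
    state_points = []
    for pi, P in enumerate(spec.pressures):
        for ti, T in enumerate(spec.temperatures):
            path = out_dir / f"traj_P{P:g}_T{T:g}.gro"
            path.write_text("")  # truncate
            frames_meta = []
            p_glob = spec.globule_probability(T, P)
            for j in range(spec.frames_per_point):
                rng = np.random.default_rng([spec.seed, pi, ti, j])
                state = "globule" if rng.random() < p_glob else "coil"
                base = (spec.compactness_globule if state == "globule"
                        else spec.compactness_coil)
                c = float(np.clip(base + rng.normal(0.0, spec.noise_sd),
                                  0.0, 1.0))
                top, frame = build_chain(template, spec.n_residues, c, rng)
                if spec.include_water:
                    top, frame = solvate(top, frame, spec.box_length,
                                         spec.density, model, rng)
                else:
                    box = np.array([spec.box_length] * 3)
                    xyz = frame.coords - frame.coords.mean(axis=0) + box / 2
                    frame = Frame(xyz, box)
                frame = Frame(wrap_coords(frame.coords, frame.box), frame.box,
                              time=5.0 * j, temperature=T, pressure=P)
                append_gro(path, top, frame)
                frames_meta.append({"state": state, "compactness": c,
                                    "n_waters":
                                    int(np.sum(top.roles == "water_O"))})
            state_points.append({
                "pressure": P, "temperature": T, "trajectory": path.name,
                "frames": frames_meta,
            })
    manifest = {
        "spec": {k: (dict(v) if isinstance(v, dict) else
                     list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "polymer_topology": polymer_top_path.name,
        "state_points": state_points,
        "truth": {
            "transition_midpoints_K": {str(k): v for k, v in spec.true_tc.items()},
            "logistic_width_K": spec.width_K,
            "compactness_plateaus": [spec.compactness_coil,
                                     spec.compactness_globule],
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# hydrogen-bond fixtures


def make_hbond_fixture(kind: str, params: dict | None = None,
                       seed: int = 0) -> tuple[Topology, Frame]:
    """Configurations with known or brute-force-checkable H-bond sets.

    ``ideal_dimer``: two waters, donor H aimed at the acceptor with the
    requested D-A distance and H-D-A angle; the acceptor's hydrogens point
    away so no reverse bond can form.  ``random_box``: n randomly oriented
    waters in a periodic cube.  ``shell_bulk``: a collapsed solvated chain
    for shell-vs-bulk connectivity comparisons.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "ideal_dimer":
        d = params.get("distance", 0.30)
        ang = math.radians(params.get("angle", 0.0))
        L = params.get("box", 3.0)
        r_oh = 0.09572
        dO = np.array([L / 2 - d / 2, L / 2, L / 2])
        aO = dO + np.array([d, 0.0, 0.0])
        h1 = dO + r_oh * np.array([math.cos(ang), math.sin(ang), 0.0])
        h2 = dO + r_oh * _unit([-0.3, -0.8, 0.52])
        ah1 = aO + r_oh * _unit([1.0, 0.4, 0.0])
        ah2 = aO + r_oh * _unit([1.0, -0.4, 0.0])
        coords = np.stack([dO, h1, h2, aO, ah1, ah2])
        top = _water_only_topology(2)
        return top, Frame(coords, np.array([L, L, L]))
    if kind == "random_box":
        n = int(params.get("n", 50))
        L = params.get("box", 1.5)
        empty = Topology(names=[], elements=[], roles=[], masses=[], radii=[],
                         resids=[], bonds=np.empty((0, 2), int))
        dens = n * WATER_MOLAR_MASS / AVOGADRO / (L ** 3) * 1e21
        top, frame = solvate(empty, Frame(np.empty((0, 3)), [L] * 3), L,
                             density=dens, seed=rng)
        return top, frame
    if kind == "shell_bulk":
        L = params.get("box", 3.0)
        density = params.get("density", 0.997)
        compactness = params.get("compactness", 0.9)
        top, frame = build_chain(None, params.get("n_residues", 15),
                                 compactness, rng)
        return solvate(top, frame, L, density=density, seed=rng)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _water_only_topology(n_waters: int) -> Topology:
    names, elements, roles, resids, bonds = [], [], [], [], []
    for w in range(n_waters):
        o = 3 * w
        names += ["OW", "HW1", "HW2"]
        elements += ["O", "H", "H"]
        roles += ["water_O", "water_H", "water_H"]
        resids += [w + 1] * 3
        bonds += [(o, o + 1), (o, o + 2)]
    masses = [MASSES[e] for e in elements]
    radii = [BONDI_RADII[e] for e in elements]
    return Topology(names=names, elements=elements, roles=roles, masses=masses,
                    radii=radii, resids=resids, bonds=np.asarray(bonds, int))
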