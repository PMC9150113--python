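"""Configurations, trajectories, topology annotation and periodic geometry.

The package works on text formats only: GRO (fixed column, nm) and
multi-model PDB (angstrom) for coordinates, plus a TSV "topology sidecar"
that carries the per-atom annotation (role, mass, van der Waals radius,
residue index, bonds) that neither coordinate format stores.

Internal units are nm throughout.  Boxes are orthorhombic; triclinic input
is rejected.  Coordinates are treated as wrapped: analyses that need a whole
polymer call :func:`unwrap_polymer` first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ParseError, TopologyError

# ---------------------------------------------------------------------------
# roles and per-element defaults

POLYMER_ROLES = (
    "backbone_C", "carbonyl_C", "amide_N", "amide_O", "amide_H",
    "isopropyl_CH", "methyl_C", "methyl_H", "backbone_H",
)
WATER_ROLES = ("water_O", "water_H")
ROLES = POLYMER_ROLES + WATER_ROLES

#: Atomic masses, u.
MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

#: Bondi van der Waals radii, nm (H, C, N, O).
BONDI_RADII = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152}

#: Default atom-name -> role map covering the synthetic naming scheme.
DEFAULT_ROLE_MAP = {
    "C1": "backbone_C", "C2": "backbone_C", "C3": "carbonyl_C",
    "O1": "amide_O", "N1": "amide_N", "HN": "amide_H",
    "C4": "isopropyl_CH", "C5": "methyl_C", "C6": "methyl_C",
    "H11": "backbone_H", "H12": "backbone_H", "H21": "backbone_H",
    "H41": "backbone_H",
    "H51": "methyl_H", "H52": "methyl_H", "H53": "methyl_H",
    "H61": "methyl_H", "H62": "methyl_H", "H63": "methyl_H",
    "OW": "water_O", "HW1": "water_H", "HW2": "water_H",
}


def role_is_water(role: str) -> bool:
    return role in WATER_ROLES


# ---------------------------------------------------------------------------
# containers


@dataclass
class Topology:
    """Per-atom annotation plus polymer/water connectivity.

    ``resids`` index polymer repeating units 1..n and then each water
    molecule with its own index.  ``bonds`` covers polymer connectivity and
    the O-H bonds of every water.
    """

    names: np.ndarray
    elements: np.ndarray
    roles: np.ndarray
    masses: np.ndarray
    radii: np.ndarray
    resids: np.ndarray
    bonds: np.ndarray  # (n_bonds, 2) int

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.roles = np.asarray(self.roles, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.bonds = (np.asarray(self.bonds, dtype=int).reshape(-1, 2)
                      if len(self.bonds) else np.empty((0, 2), dtype=int))

    def __len__(self) -> int:
        return len(self.names)

    # --- selections -------------------------------------------------------
    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.roles, WATER_ROLES)

    @property
    def polymer_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_water)

    def indices_by_role(self, *roles: str) -> np.ndarray:
        return np.flatnonzero(np.isin(self.roles, list(roles)))

    @property
    def water_oxygens(self) -> np.ndarray:
        return self.indices_by_role("water_O")

    @property
    def n_polymer_residues(self) -> int:
        pol = self.polymer_indices
        return int(self.resids[pol].max()) if len(pol) else 0

    def water_molecule_of(self) -> np.ndarray:
        """Residue (molecule) id per atom; -1 for polymer atoms."""
        out = np.where(self.is_water, self.resids, -1)
        return out

    # --- bonds ------------------------------------------------------------
    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(len(self))]
        for i, j in self.bonds:
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
        return adj

    def attached_hydrogens(self, index: int, adj=None) -> list[int]:
        adj = adj if adj is not None else self.adjacency()
        return [j for j in adj[index] if self.elements[j] == "H"]

    def polymer_bonds(self) -> np.ndarray:
        if len(self.bonds) == 0:
            return self.bonds
        w = self.is_water
        keep = ~(w[self.bonds[:, 0]] | w[self.bonds[:, 1]])
        return self.bonds[keep]

    # --- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants of the annotation."""
        if np.any(self.masses <= 0):
            raise TopologyError("non-positive atom mass")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise TopologyError(f"unknown roles: {sorted(unknown)}")
        pol = self.polymer_indices
        if len(pol):
            for res in np.unique(self.resids[pol]):
                sel = self.roles[pol[self.resids[pol] == res]]
                counts = {r: int(np.sum(sel == r)) for r in
                          ("methyl_C", "amide_N", "amide_O")}
                if counts != {"methyl_C": 2, "amide_N": 1, "amide_O": 1}:
                    raise TopologyError(
                        f"repeating unit {res}: expected 2 methyl_C, 1 amide_N,"
                        f" 1 amide_O, got {counts}")
            if not self._polymer_connected():
                raise TopologyError("polymer bond list is not a single component")
        wat = np.flatnonzero(self.is_water)
        if len(wat):
            for res in np.unique(self.resids[wat]):
                sel = self.roles[wat[self.resids[wat] == res]]
                if not (np.sum(sel == "water_O") == 1 and np.sum(sel == "water_H") == 2):
                    raise TopologyError(f"water {res}: expected 1 O + 2 H")

    def _polymer_connected(self) -> bool:
        pol = self.polymer_indices
        if len(pol) <= 1:
            return True
        pos = {int(a): k for k, a in enumerate(pol)}
        adj: list[list[int]] = [[] for _ in pol]
        for i, j in self.polymer_bonds():
            adj[pos[int(i)]].append(pos[int(j)])
            adj[pos[int(j)]].append(pos[int(i)])
        seen = np.zeros(len(pol), dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            k = stack.pop()
            for m in adj[k]:
                if not seen[m]:
                    seen[m] = True
                    stack.append(m)
        return bool(seen.all())


@dataclass
class Frame:
    """One configuration: coordinates (nm), orthorhombic box, state labels."""

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0
    temperature: float | None = None
    pressure: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")

    def copy(self) -> "Frame":
        return Frame(self.coords.copy(), self.box.copy(), self.time,
                     self.temperature, self.pressure)


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image_vector(a, b, box) -> np.ndarray:
    """Displacement b - a wrapped componentwise into [-L/2, L/2).

    ``a`` and ``b`` broadcast; the norm of the result is the minimum-image
    distance.
    """
    box = np.asarray(box, dtype=float)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.floor(d / box + 0.5)


def minimum_image_distance(a, b, box) -> np.ndarray:
    return np.linalg.norm(minimum_image_vector(a, b, box), axis=-1)


def wrap_coords(coords, box) -> np.ndarray:
    """Wrap coordinates into [0, L) per component."""
    box = np.asarray(box, dtype=float)
    return np.asarray(coords, dtype=float) % box


def unwrap_polymer(frame: Frame, topology: Topology) -> Frame:
    """Make the polymer whole across periodic boundaries.

    Walks the polymer bond graph and shifts each atom by lattice vectors so
    every bonded pair sits at its minimum-image separation; waters are left
    untouched.  Idempotent on an already-whole chain.
    """
    pol = topology.polymer_indices
    if len(pol) == 0:
        return frame.copy()
    bonds = topology.polymer_bonds()
    pos = {int(a): k for k, a in enumerate(pol)}
    adj: list[list[int]] = [[] for _ in pol]
    for i, j in bonds:
        adj[pos[int(i)]].append(pos[int(j)])
        adj[pos[int(j)]].append(pos[int(i)])
    out = frame.copy()
    coords = out.coords
    sub = coords[pol].copy()
    seen = np.zeros(len(pol), dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        k = stack.pop()
        for m in adj[k]:
            if not seen[m]:
                sub[m] = sub[k] + minimum_image_vector(sub[k], sub[m], frame.box)
                seen[m] = True
                stack.append(m)
    if not seen.all():
        raise TopologyError("polymer is disconnected; cannot unwrap")
    coords[pol] = sub
    return out


# ---------------------------------------------------------------------------
# role assignment and partial topology construction


def assign_roles(names: Sequence[str], role_map: dict | None = None) -> np.ndarray:
    role_map = DEFAULT_ROLE_MAP if role_map is None else role_map
    roles = []
    for n in names:
        if n not in role_map:
            raise TopologyError(f"atom name {n!r} missing from the role map")
        roles.append(role_map[n])
    return np.asarray(roles, dtype=object)


def load_role_map(path) -> dict:
    """Read an editable name->role map (lines of ``name<TAB>role``)."""
    out = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[1] not in ROLES:
            raise ParseError("bad role-map line", path=path, line=ln)
        out[parts[0]] = parts[1]
    return out


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise TopologyError(f"cannot infer element from atom name {name!r}")


def _partial_topology(names: list[str], file_resids: list[int],
                      role_map: dict | None) -> Topology:
    """Annotation from atom names alone: roles, masses, radii, water bonds.

    Polymer bonds are unknown at this stage (the sidecar carries them).
    Water residue indices are re-assigned by grouping O,H,H in file order,
    so narrow residue-number fields in PDB/GRO do not corrupt them.
    """
    roles = assign_roles(names, role_map)
    elements = np.array([_element_of(n) for n in names], dtype=object)
    masses = np.array([MASSES[e] for e in elements])
    radii = np.array([BONDI_RADII[e] for e in elements])
    resids = np.asarray(file_resids, dtype=int).copy()
    is_w = np.isin(roles, WATER_ROLES)
    bonds = []
    if is_w.any():
        pol_max = int(resids[~is_w].max()) if (~is_w).any() else 0
        wat_idx = np.flatnonzero(is_w)
        mol = pol_max
        current_O = None
        for i in wat_idx:
            if roles[i] == "water_O":
                mol += 1
                current_O = i
            else:
                if current_O is None:
                    raise TopologyError("water hydrogen precedes its oxygen")
                bonds.append((int(current_O), int(i)))
            resids[i] = mol
    return Topology(names=np.asarray(names, dtype=object), elements=elements,
                    roles=roles, masses=masses, radii=radii, resids=resids,
                    bonds=np.asarray(bonds, dtype=int).reshape(-1, 2))


# ---------------------------------------------------------------------------
# topology sidecar (TSV)

_SIDECAR_HEADER = "index\tname\telement\trole\tmass\tradius\tresid\tbonded"


def write_topology(path, topology: Topology) -> None:
    adj: list[list[int]] = [[] for _ in range(len(topology))]
    for i, j in topology.bonds:
        i, j = int(i), int(j)
        adj[min(i, j)].append(max(i, j))
    lines = [_SIDECAR_HEADER]
    for i in range(len(topology)):
        bonded = ",".join(str(j) for j in sorted(adj[i])) or "-"
        lines.append("\t".join([
            str(i), str(topology.names[i]), str(topology.elements[i]),
            str(topology.roles[i]), f"{topology.masses[i]:.4f}",
            f"{topology.radii[i]:.4f}", str(int(topology.resids[i])), bonded,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path) -> Topology:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].rstrip() != _SIDECAR_HEADER:
        raise ParseError("missing sidecar header", path=path, line=1)
    names, elements, roles, masses, radii, resids = [], [], [], [], [], []
    bonds = []
    for ln, raw in enumerate(lines[1:], 2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 8:
            raise ParseError("bad sidecar row", path=path, line=ln)
        idx = int(parts[0])
        if idx != len(names):
            raise ParseError("non-contiguous atom index", path=path, line=ln)
        names.append(parts[1]); elements.append(parts[2]); roles.append(parts[3])
        masses.append(float(parts[4])); radii.append(float(parts[5]))
        resids.append(int(parts[6]))
        if parts[7] != "-":
            bonds.extend((idx, int(j)) for j in parts[7].split(","))
    return Topology(names=names, elements=elements, roles=roles, masses=masses,
                    radii=radii, resids=resids,
                    bonds=np.asarray(bonds, dtype=int).reshape(-1, 2))


# ---------------------------------------------------------------------------
# GRO

def _parse_box_line(line: str, path, ln: int) -> np.ndarray:
    try:
        vals = [float(x) for x in line.split()]
    except ValueError:
        raise ParseError("unreadable box line", path=path, line=ln)
    if len(vals) == 3:
        box = np.array(vals)
    elif len(vals) == 9:
        if any(abs(v) > 1e-9 for v in vals[3:]):
            raise ParseError("triclinic boxes are not supported", path=path, line=ln)
        box = np.array(vals[:3])
    else:
        raise ParseError("box line must carry 3 (or 9) floats", path=path, line=ln)
    if np.any(box <= 0):
        raise ParseError("box lengths must be positive", path=path, line=ln)
    return box


def _time_from_title(title: str) -> float:
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0])
        except (IndexError, ValueError):
            pass
    return 0.0


def iter_gro_frames(path, role_map: dict | None = None
                    ) -> Iterator[tuple[Topology, Frame]]:
    """Stream (partial topology, frame) pairs from a (multi-frame) GRO file."""
    path = Path(path)
    with path.open() as fh:
        ln = 0
        frame_idx = 0
        while True:
            title = fh.readline()
            ln += 1
            if title == "":
                if frame_idx == 0:
                    raise ParseError("empty GRO file", path=path, line=1)
                return
            if title.strip() == "" and fh.readline() == "":
                return
            nline = fh.readline()
            ln += 1
            try:
                natoms = int(nline.strip())
            except ValueError:
                raise ParseError(
                    f"frame {frame_idx}: bad atom-count line", path=path, line=ln)
            names, resids, coords = [], [], []
            for _ in range(natoms):
                line = fh.readline()
                ln += 1
                if line == "":
                    raise ParseError(
                        f"truncated frame {frame_idx}", path=path, line=ln)
                try:
                    resids.append(int(line[0:5]))
                    names.append(line[10:15].strip())
                    floats = line[20:].split()
                    coords.append([float(x) for x in floats[:3]])
                except (ValueError, IndexError):
                    raise ParseError(
                        f"malformed GRO atom record in frame {frame_idx}",
                        path=path, line=ln)
            boxline = fh.readline()
            ln += 1
            if boxline == "":
                raise ParseError(
                    f"frame {frame_idx}: missing box line", path=path, line=ln)
            box = _parse_box_line(boxline, path, ln)
            top = _partial_topology(names, resids, role_map)
            yield top, Frame(np.asarray(coords), box, time=_time_from_title(title))
            frame_idx += 1


def _write_gro_frame(fh, topology: Topology, frame: Frame, title: str) -> None:
    if len(frame.coords) != len(topology):
        raise ValueError("coordinate count does not match topology")
    fh.write(f"{title} t= {frame.time:.3f}\n{len(topology)}\n")
    for i in range(len(topology)):
        resid = int(topology.resids[i]) % 100000
        resname = "SOL" if role_is_water(topology.roles[i]) else "PNI"
        x, y, z = frame.coords[i]
        fh.write(f"{resid:5d}{resname:<5s}{str(topology.names[i]):>5s}"
                 f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
    fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def write_gro(path, topology: Topology, frames: Frame | Iterable[Frame],
              title: str = "coilglobule") -> None:
    if isinstance(frames, Frame):
        frames = [frames]
    with Path(path).open("w") as fh:
        for frame in frames:
            _write_gro_frame(fh, topology, frame, title)


def append_gro(path, topology: Topology, frame: Frame,
               title: str = "coilglobule") -> None:
    """Append one frame (with its own topology/atom count) to a GRO file."""
    with Path(path).open("a") as fh:
        _write_gro_frame(fh, topology, frame, title)


# ---------------------------------------------------------------------------
# PDB (multi-model, angstrom)


def iter_pdb_frames(path, role_map: dict | None = None
                    ) -> Iterator[tuple[Topology, Frame]]:
    path = Path(path)
    box = None
    names: list[str] = []
    resids: list[int] = []
    coords: list[list[float]] = []
    frame_idx = 0
    in_model = False
    any_yield = False
    time = 0.0

    def build():
        nonlocal any_yield
        top = _partial_topology(names, resids, role_map)
        any_yield = True
        return top, Frame(np.asarray(coords) * 0.1, box, time=time)

    with path.open() as fh:
        for ln, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    a, b, c = (float(line[6:15]), float(line[15:24]),
                               float(line[24:33]))
                    al, be, ga = (float(line[33:40]), float(line[40:47]),
                                  float(line[47:54]))
                except ValueError:
                    raise ParseError("bad CRYST1 record", path=path, line=ln)
                if any(abs(x - 90.0) > 1e-3 for x in (al, be, ga)):
                    raise ParseError("non-orthorhombic cell", path=path, line=ln)
                box = np.array([a, b, c]) * 0.1
            elif rec == "MODEL ":
                in_model = True
                names, resids, coords = [], [], []
                try:
                    time = float(line.split()[1])
                except (IndexError, ValueError):
                    time = float(frame_idx)
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    names.append(line[12:16].strip())
                    resids.append(int(line[22:26]))
                    coords.append([float(line[30:38]), float(line[38:46]),
                                   float(line[46:54])])
                except (ValueError, IndexError):
                    raise ParseError("malformed ATOM record", path=path, line=ln)
            elif rec == "ENDMDL":
                if box is None:
                    raise ParseError("ENDMDL before CRYST1", path=path, line=ln)
                yield build()
                frame_idx += 1
                in_model = False
    if in_model:
        raise ParseError(f"truncated frame {frame_idx}: missing ENDMDL", path=path)
    if not any_yield:
        if coords:
            if box is None:
                raise ParseError("missing CRYST1 box", path=path)
            yield build()
        else:
            raise ParseError("no atoms found", path=path)


def write_pdb(path, topology: Topology, frames: Frame | Iterable[Frame]) -> None:
    if isinstance(frames, Frame):
        frames = [frames]
    with Path(path).open("w") as fh:
        first = True
        for m, frame in enumerate(frames, 1):
            if len(frame.coords) != len(topology):
                raise ValueError("coordinate count does not match topology")
            if first:
                a, b, c = frame.box * 10.0
                fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                         f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
                first = False
            fh.write(f"MODEL     {frame.time:8.3f}\n")
            for i in range(len(topology)):
                resname = "SOL" if role_is_water(topology.roles[i]) else "PNI"
                x, y, z = frame.coords[i] * 10.0
                name = str(topology.names[i])
                fh.write(f"ATOM  {(i + 1) % 100000:5d} {name:<4.4s}"
                         f"{resname:>4.3s} A{int(topology.resids[i]) % 10000:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                         f"          {str(topology.elements[i]):>2.2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# format dispatch


def _format_of(path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.upper()
    else:
        f = Path(path).suffix.lstrip(".").upper()
    if f not in ("GRO", "PDB"):
        raise ParseError(f"unsupported format {f!r} (GRO or PDB)", path=path)
    return f


def read_configuration(path, fmt: str | None = None,
                       role_map: dict | None = None) -> tuple[Topology, Frame]:
    """Read the first configuration of a file; returns a partial topology
    (roles/masses/radii/water bonds; polymer bonds come from the sidecar)."""
    it = (iter_gro_frames(path, role_map) if _format_of(path, fmt) == "GRO"
          else iter_pdb_frames(path, role_map))
    return next(it)


def read_trajectory(path, fmt: str | None = None, role_map: dict | None = None
                    ) -> Iterator[Frame]:
    """Stream frames in file order; time labels must be non-decreasing.

    The generator holds a single frame at a time (bounded working set).
    """
    it = (iter_gro_frames(path, role_map) if _format_of(path, fmt) == "GRO"
          else iter_pdb_frames(path, role_map))
    last_t = -np.inf
    for k, (_, frame) in enumerate(it):
        if frame.time < last_t:
            raise ParseError(f"time labels decrease at frame {k}", path=path)
        last_t = frame.time
        yield frame
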