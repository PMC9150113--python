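"""Hydration-shell classification and water-water connectivity.

A water belongs to the first hydration shell of the chain when its oxygen
lies (minimum image) within 0.35 nm of any amide nitrogen/oxygen
(*hydrophilic* water) or within 0.55 nm of any methyl carbon (*hydrophobic*
water).  The two categories may overlap; the shell is their union and every
water counts once.  ``F`` is the hydrophobic fraction |hydrophobic|/|shell|.
"Bulk" is everything outside the shell.

Water-water hydrogen-bond connectivity is reported per molecule inside a
domain (shell or bulk): unique donor-acceptor molecule pairs with *both*
partners in the domain, divided by the domain size.  Bonds straddling the
two domains are excluded from both and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyShellError, EmptySelectionError, TopologyError
from .observables import HBondCriterion, find_hbonds
from .structure_io import Frame, Topology, wrap_coords

R_HYDROPHILIC = 0.35  # nm, water O to amide N/O
R_HYDROPHOBIC = 0.55  # nm, water O to methyl C


@dataclass
class ShellAssignment:
    """Per-frame partition of waters into shell categories.

    Sets hold water *molecule* ids (topology resids of the waters).
    """

    frame_label: float
    hydrophilic: frozenset[int]
    hydrophobic: frozenset[int]
    first_shell: frozenset[int]
    bulk: frozenset[int]
    n_residues: int

    @property
    def n_shell(self) -> int:
        return len(self.first_shell)

    @property
    def n_per_residue(self) -> float:
        return self.n_shell / self.n_residues

    @property
    def F(self) -> float:
        return hydrophobic_fraction(self)


def classify_shell(frame: Frame, topology: Topology,
                   r_philic: float = R_HYDROPHILIC,
                   r_phobic: float = R_HYDROPHOBIC) -> ShellAssignment:
    """Assign every water to hydrophilic/hydrophobic/shell/bulk categories.

    A water may sit in both categories (counted once in the shell); all
    distances are minimum-image between its oxygen and the polymer sites.
    """
    philic_sites = topology.indices_by_role("amide_N", "amide_O")
    phobic_sites = topology.indices_by_role("methyl_C")
    if len(philic_sites) == 0 and len(phobic_sites) == 0:
        raise EmptySelectionError("classify_shell: no polymer reference atoms")
    ow = topology.water_oxygens
    mol = topology.resids[ow]
    pos = wrap_coords(frame.coords, frame.box)
    wtree = cKDTree(pos[ow], boxsize=frame.box)

    def near(sites, r):
        if len(sites) == 0:
            return np.zeros(len(ow), dtype=bool)
        hits = wtree.query_ball_point(pos[sites], r)
        mask = np.zeros(len(ow), dtype=bool)
        for h in hits:
            mask[h] = True
        # enforce the strict "<" reading of the cutoffs
        cand = np.flatnonzero(mask)
        if len(cand):
            d = np.min(np.linalg.norm(
                (pos[ow[cand], None, :] - pos[sites][None, :, :] +
                 frame.box / 2) % frame.box - frame.box / 2, axis=2), axis=1)
            mask[cand] = d < r
        return mask

    philic = near(philic_sites, r_philic)
    phobic = near(phobic_sites, r_phobic)
    shell = philic | phobic
    return ShellAssignment(
        frame_label=frame.time,
        hydrophilic=frozenset(int(m) for m in mol[philic]),
        hydrophobic=frozenset(int(m) for m in mol[phobic]),
        first_shell=frozenset(int(m) for m in mol[shell]),
        bulk=frozenset(int(m) for m in mol[~shell]),
        n_residues=max(topology.n_polymer_residues, 1),
    )


def hydrophobic_fraction(assignment: ShellAssignment) -> float:
    """F = |hydrophobic| / |first shell|; undefined on an empty shell."""
    if not assignment.first_shell:
        raise EmptyShellError(
            f"frame {assignment.frame_label}: empty first shell, F undefined")
    return len(assignment.hydrophobic) / len(assignment.first_shell)


def water_water_bond_pairs(frame: Frame, topology: Topology,
                           criterion: HBondCriterion = HBondCriterion()
                           ) -> set[frozenset[int]]:
    """Unique water-water hydrogen-bonded molecule pairs (each bond once)."""
    pairs: set[frozenset[int]] = set()
    for hb in find_hbonds(frame, topology, criterion):
        if hb.category == "water-water":
            pairs.add(frozenset((int(topology.resids[hb.donor]),
                                 int(topology.resids[hb.acceptor]))))
    return pairs


def water_connectivity(frame: Frame, topology: Topology,
                       criterion: HBondCriterion = HBondCriterion(),
                       domain: str = "bulk",
                       assignment: ShellAssignment | None = None) -> float:
    """Water-water H-bonds per molecule within a domain (shell or bulk)."""
    if domain not in ("first_shell", "bulk"):
        raise ValueError("domain must be 'first_shell' or 'bulk'")
    if assignment is None:
        assignment = classify_shell(frame, topology)
    members = getattr(assignment, domain)
    if not members:
        raise EmptyShellError(f"domain {domain!r} is empty")
    pairs = water_water_bond_pairs(frame, topology, criterion)
    inside = sum(1 for p in pairs if p <= members)
    return inside / len(members)


def connectivity_breakdown(frame: Frame, topology: Topology,
                           criterion: HBondCriterion = HBondCriterion(),
                           assignment: ShellAssignment | None = None
                           ) -> dict[str, float | int]:
    """Shell and bulk per-molecule connectivity plus the cross-domain count."""
    if assignment is None:
        assignment = classify_shell(frame, topology)
    pairs = water_water_bond_pairs(frame, topology, criterion)
    shell, bulk = assignment.first_shell, assignment.bulk
    n_shell_bonds = sum(1 for p in pairs if p <= shell)
    n_bulk_bonds = sum(1 for p in pairs if p <= bulk)
    n_cross = len(pairs) - n_shell_bonds - n_bulk_bonds
    return {
        "conn_shell": n_shell_bonds / len(shell) if shell else np.nan,
        "conn_bulk": n_bulk_bonds / len(bulk) if bulk else np.nan,
        "n_cross_bonds": n_cross,
    }


def hydration_series(frames: Iterable[Frame], topology: Topology,
                     criterion: HBondCriterion = HBondCriterion(),
                     connectivity: bool = False,
                     window: float | tuple[int, int] = 1.0) -> pd.DataFrame:
    """Per-frame hydration table; see :func:`window_stats` for the summary.

    ``window`` keeps either the trailing fraction of frames (float in (0, 1])
    or an explicit ``(start, stop)`` frame range.
    """
    rows = []
    for frame in frames:
        a = classify_shell(frame, topology)
        row = {
            "time": frame.time,
            "n_shell": a.n_shell,
            "n_per_residue": a.n_per_residue,
            "n_philic": len(a.hydrophilic),
            "n_phobic": len(a.hydrophobic),
            "F": hydrophobic_fraction(a) if a.first_shell else np.nan,
        }
        if connectivity:
            row.update(connectivity_breakdown(frame, topology, criterion, a))
        rows.append(row)
    df = pd.DataFrame(rows)
    return apply_window(df, window)


def apply_window(df: pd.DataFrame, window: float | tuple[int, int]) -> pd.DataFrame:
    """Restrict a per-frame table to the analysis window."""
    if isinstance(window, tuple):
        lo, hi = window
        out = df.iloc[lo:hi]
    else:
        if not 0 < window <= 1:
            raise ValueError("fractional window must be in (0, 1]")
        n = len(df)
        out = df.iloc[n - max(1, int(round(window * n))):] if n else df
    if len(out) == 0:
        raise ValueError("analysis window is empty")
    return out.reset_index(drop=True)


def window_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each numeric column over the (already windowed) table."""
    num = df.select_dtypes("number")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1).fillna(0.0)})
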