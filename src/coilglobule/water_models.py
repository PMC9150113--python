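"""Four-site rigid water models of the TIP4P family.

A TIP4P-family molecule carries a Lennard-Jones site on oxygen, a positive
partial charge ``q_H`` on each hydrogen and the balancing negative charge
``-2 q_H`` on a massless *M* site displaced by ``d_OM`` from the oxygen along
the H-O-H bisector, towards the hydrogens.  Only the charge geometry is used
here: the module places the M site and evaluates the molecular dipole as an
analytic self-check of the parameter sets; no energetics are computed.

Units follow the conventions of the original model papers: lengths in
angstrom, charges in elementary charge, epsilon in kelvin, dipole in debye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import GeometryError, UnsupportedModelError

#: 1 e*angstrom expressed in debye (10^-18 esu cm).
E_ANGSTROM_TO_DEBYE = 4.803

#: Rigid TIP4P-family internal geometry (gas-phase water geometry).
RIGID_R_OH = 0.9572  # angstrom
RIGID_THETA_HOH = 104.52  # degrees


@dataclass(frozen=True)
class WaterModel:
    """Parameter set of a rigid four-site water model.

    Attributes
    ----------
    name : str
        Model label, e.g. ``"TIP4P/2005"``.
    epsilon : float
        Lennard-Jones well depth on oxygen, in K.
    sigma : float
        Lennard-Jones size, in angstrom.
    q_H : float
        Hydrogen partial charge, in e.  The M site carries ``-2 q_H``.
    d_OM : float
        Oxygen-to-M-site distance along the bisector, in angstrom.
    mu_ref : float
        Published molecular dipole, in debye (metadata, cross-checked by
        :func:`dipole_moment`).
    rho_ref : float
        Published liquid density at 298 K and 0.1 MPa, in g/cm^3
        (carried as metadata only; reproducing it requires simulation).
    r_OH : float
        Rigid O-H bond length, angstrom.
    theta_HOH : float
        Rigid H-O-H angle, degrees.
    """

    name: str
    epsilon: float
    sigma: float
    q_H: float
    d_OM: float
    mu_ref: float
    rho_ref: float
    r_OH: float = RIGID_R_OH
    theta_HOH: float = RIGID_THETA_HOH

    def __post_init__(self):
        if not (self.q_H > 0):
            raise ValueError("q_H must be positive")
        if not (0 < self.d_OM < self.r_OH):
            raise ValueError("d_OM must lie strictly between 0 and r_OH")
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")

    @property
    def q_M(self) -> float:
        """M-site charge; the molecule is exactly neutral by construction."""
        return -2.0 * self.q_H

    def reference_geometry(self):
        """Rigid-geometry site coordinates (O, H1, H2, M) in angstrom.

        Oxygen at the origin, bisector along +z, hydrogens in the xz plane.
        """
        half = math.radians(self.theta_HOH) / 2.0
        O = np.zeros(3)
        H1 = np.array([self.r_OH * math.sin(half), 0.0, self.r_OH * math.cos(half)])
        H2 = np.array([-self.r_OH * math.sin(half), 0.0, self.r_OH * math.cos(half)])
        M = msite_position(O, H1, H2, self.d_OM)
        return O, H1, H2, M

    def to_text(self) -> str:
        """Serialise as ``key: value`` lines (stable field order)."""
        lines = [f"{k}: {v}" for k, v in asdict(self).items()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "WaterModel":
        kv = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            kv[key.strip()] = val.strip()
        name = kv.pop("name")
        return cls(name=name, **{k: float(v) for k, v in kv.items()})

    def write(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def read(cls, path) -> "WaterModel":
        return cls.from_text(Path(path).read_text())


_BUILTIN = {
    "TIP4P/2005": dict(epsilon=93.2, sigma=3.1589, q_H=0.5564, d_OM=0.1546,
                       mu_ref=2.305, rho_ref=0.9979),
    "TIP4P/Ice": dict(epsilon=106.1, sigma=3.1668, q_H=0.5897, d_OM=0.1577,
                      mu_ref=2.426, rho_ref=0.993),
}


def builtin_model(name: str) -> WaterModel:
    """Return one of the built-in four-site parameter sets.

    Supported names: ``"TIP4P/2005"`` and ``"TIP4P/Ice"`` (case-insensitive).
    """
    for label, params in _BUILTIN.items():
        if name.lower() == label.lower():
            return WaterModel(name=label, **params)
    raise UnsupportedModelError(
        f"unknown water model {name!r}; supported: {sorted(_BUILTIN)}"
    )


def msite_position(O, H1, H2, d_OM: float) -> np.ndarray:
    """Place the M site on the H-O-H bisector at distance ``d_OM`` from O.

    The bisector direction is the normalised sum of the two unit O->H
    vectors; the M site sits on the hydrogen side of the oxygen.  All
    coordinates in angstrom (any consistent unit works).

    Raises
    ------
    GeometryError
        If either O-H vector vanishes or the two are (anti)collinear so
        that the bisector is undefined.
    """
    O = np.asarray(O, dtype=float)
    u1 = np.asarray(H1, dtype=float) - O
    u2 = np.asarray(H2, dtype=float) - O
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise GeometryError("hydrogen coincides with oxygen")
    u1, u2 = u1 / n1, u2 / n2
    if np.linalg.norm(np.cross(u1, u2)) < 1e-10:
        raise GeometryError("O, H1, H2 are collinear; bisector undefined")
    bis = u1 + u2
    nb = np.linalg.norm(bis)
    if nb < 1e-12:  # pragma: no cover - caught by the cross-product test
        raise GeometryError("degenerate bisector")
    return O + d_OM * bis / nb


def dipole_moment(model: WaterModel) -> float:
    """Molecular dipole magnitude in debye from the four-site charges.

    Evaluates ``|sum_i q_i r_i|`` over {+q_H at each H, -2 q_H at M} using
    the model's rigid geometry and converts e*angstrom to debye.  For the
    symmetric molecule this equals the closed form
    ``2 q_H (r_OH cos(theta/2) - d_OM) * 4.803``.
    """
    if model.r_OH is None or model.theta_HOH is None:  # defensive; dataclass defaults
        raise GeometryError("model lacks rigid geometry")
    return dipole_from_parameters(model.q_H, model.d_OM, model.r_OH, model.theta_HOH)


def dipole_from_parameters(q_H: float, d_OM: float, r_OH: float = RIGID_R_OH,
                           theta_HOH: float = RIGID_THETA_HOH) -> float:
    """Dipole (debye) of an arbitrary four-site charge set; allows q_H = 0."""
    if q_H == 0:
        return 0.0
    half = math.radians(theta_HOH) / 2.0
    O = np.zeros(3)
    H1 = np.array([r_OH * math.sin(half), 0.0, r_OH * math.cos(half)])
    H2 = np.array([-r_OH * math.sin(half), 0.0, r_OH * math.cos(half)])
    M = msite_position(O, H1, H2, d_OM)
    charges = np.array([q_H, q_H, -2.0 * q_H])
    sites = np.stack([H1, H2, M])
    mu_vec = (charges[:, None] * sites).sum(axis=0)
    return float(np.linalg.norm(mu_vec)) * E_ANGSTROM_TO_DEBYE
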