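"""Sigmoid transition fits, T_C estimation and P-T phase classification.

Observable-vs-temperature series are fitted with the symmetric
four-parameter logistic (Boltzmann sigmoid)

    y(T) = A_glob + (A_coil - A_glob) / (1 + exp((T - T_C) / w)),

whose inflection sits at the plateau midpoint; the transition temperature is
the average of the midpoints fitted to R_G(T) and SASA(T).  Classification
cutoffs are the fitted observable value at the inflection point: the chain
radius-of-gyration cutoff (1.2 nm at atmospheric pressure) and the
hydration-per-residue cutoff (12.5).  A state point is *coil* when its mean
R_G is at or above the R_G cutoff, otherwise *globule*; a globule keeping at
least the hydration cutoff of shell waters per repeating unit is a
*hydrated globule*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import NoTransitionError

RG_CUTOFF = 1.2          # nm, coil/globule threshold
RG_CUTOFF_ALT = 1.1      # nm, sensitivity check
HYDRATION_CUTOFF = 12.5  # shell waters per repeating unit

LABELS = ("coil", "globule", "hydrated_globule")


@dataclass
class TemperatureSeries:
    """Mean/SD of one observable on a temperature grid at one pressure."""

    observable: str
    pressure: float
    temperatures: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_frames: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.temperatures) == len(self.means) == len(self.sds)):
            raise ValueError("temperature/mean/sd lengths differ")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.sds < 0):
            raise ValueError("negative SD")


@dataclass
class SigmoidFit:
    """Fitted Boltzmann-sigmoid parameters with standard errors."""

    observable: str
    a_coil: float
    a_glob: float
    t_c: float
    width: float
    se: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int

    def value_at(self, T) -> np.ndarray:
        return _boltzmann(np.asarray(T, dtype=float),
                          self.a_coil, self.a_glob, self.t_c, self.width)

    def to_text(self) -> str:
        rows = [f"observable: {self.observable}",
                f"a_coil: {self.a_coil:.6g} +/- {self.se['a_coil']:.3g}",
                f"a_glob: {self.a_glob:.6g} +/- {self.se['a_glob']:.3g}",
                f"t_c: {self.t_c:.6g} +/- {self.se['t_c']:.3g}",
                f"width: {self.width:.6g} +/- {self.se['width']:.3g}",
                f"residual_norm: {self.residual_norm:.6g}",
                f"converged: {self.converged}",
                f"n_points: {self.n_points}"]
        return "\n".join(rows) + "\n"


def _boltzmann(T, a_coil, a_glob, t_c, w):
    z = np.clip((T - t_c) / w, -700.0, 700.0)  # avoid exp overflow
    return a_glob + (a_coil - a_glob) / (1.0 + np.exp(z))


def fit_sigmoid(series: TemperatureSeries, weighted: bool = True) -> SigmoidFit:
    """Bounded least-squares Boltzmann fit with deterministic initialisation.

    Plateaus start from the endpoint means, the midpoint from the steepest
    finite difference, and points are weighted by 1/SD when every SD is
    positive.  Flat series and non-convergent fits raise
    :class:`NoTransitionError`.
    """
    T, y, sd = series.temperatures, series.means, series.sds
    if len(T) < 4:
        raise NoTransitionError("need at least 4 temperature points")
    span = T[-1] - T[0]
    scale = max(abs(y).max(), 1e-30)
    if y.max() - y.min() < 1e-10 * scale:
        raise NoTransitionError("flat series: no transition to fit")
    a_coil0 = y[:2].mean()
    a_glob0 = y[-2:].mean()
    slopes = np.abs(np.diff(y) / np.diff(T))
    k = int(np.argmax(slopes))
    t_c0 = 0.5 * (T[k] + T[k + 1])
    w0 = max(span / 10.0, 1e-3)
    sigma = sd if (weighted and np.all(sd > 0)) else None
    lo = [-np.inf, -np.inf, T[0] - 10.0, 1e-6]
    hi = [np.inf, np.inf, T[-1] + 10.0, 10.0 * span]
    p0 = [a_coil0, a_glob0, min(max(t_c0, lo[2]), hi[2]), w0]
    try:
        with warnings.catch_warnings():
            # exactly-determined fits (4 points) have no covariance estimate
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(_boltzmann, T, y, p0=p0, sigma=sigma,
                                   bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise NoTransitionError(f"sigmoid fit did not converge: {exc}") from exc
    a_coil, a_glob, t_c, w = (float(v) for v in popt)
    if abs(a_coil - a_glob) < 1e-10 * scale or w > 2.0 * span:
        raise NoTransitionError("degenerate fit: plateaus indistinguishable "
                                "or width exceeds the data range")
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = y - _boltzmann(T, *popt)
    return SigmoidFit(
        observable=series.observable,
        a_coil=a_coil, a_glob=a_glob, t_c=t_c, width=w,
        se=dict(zip(("a_coil", "a_glob", "t_c", "width"),
                    (float(e) for e in perr))),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True, n_points=len(T))


def estimate_tc(fit_rg: SigmoidFit, fit_sasa: SigmoidFit) -> tuple[float, float]:
    """Transition temperature: mean of the two fitted midpoints.

    The uncertainty is the larger of half the midpoint difference and the
    standard error of their mean propagated from the fit errors.
    """
    for f in (fit_rg, fit_sasa):
        if not f.converged:
            raise NoTransitionError(f"fit of {f.observable} did not converge")
    tc = 0.5 * (fit_rg.t_c + fit_sasa.t_c)
    half_diff = 0.5 * abs(fit_rg.t_c - fit_sasa.t_c)
    propagated = 0.5 * float(np.hypot(fit_rg.se["t_c"], fit_sasa.se["t_c"]))
    return tc, max(half_diff, propagated)


def derive_cutoff(fit: SigmoidFit) -> float:
    """Observable value at the inflection point: (A_coil + A_glob) / 2."""
    if not fit.converged:
        raise NoTransitionError("cannot derive a cutoff from an unconverged fit")
    return 0.5 * (fit.a_coil + fit.a_glob)


@dataclass
class StatePoint:
    """One (pressure, temperature) condition with its window-mean observables."""

    pressure: float
    temperature: float
    mean_rg: float
    mean_hydration: float
    label: str = ""


def classify_state(mean_rg: float, mean_hydration_per_residue: float,
                   rg_cutoff: float = RG_CUTOFF,
                   hyd_cutoff: float = HYDRATION_CUTOFF) -> str:
    """coil if R_G >= rg_cutoff; globule otherwise; hydrated_globule when a
    globule keeps >= hyd_cutoff shell waters per repeating unit."""
    if mean_rg >= rg_cutoff:
        return "coil"
    if mean_hydration_per_residue >= hyd_cutoff:
        return "hydrated_globule"
    return "globule"


@dataclass
class PhaseMap:
    """Labelled (T, P) grid plus per-pressure boundary temperatures."""

    table: pd.DataFrame
    boundaries: dict[float, float | None]
    rg_cutoff: float
    hyd_cutoff: float


def _boundary(sub: pd.DataFrame) -> float | None:
    """Midpoint between the warmest coil and the coolest (hydrated) globule."""
    coil_T = sub.loc[sub["label"] == "coil", "temperature"]
    glob_T = sub.loc[sub["label"] != "coil", "temperature"]
    if len(coil_T) == 0 or len(glob_T) == 0:
        return None
    return 0.5 * (coil_T.max() + glob_T.min())


def build_phase_map(points: Sequence[StatePoint],
                    rg_cutoff: float = RG_CUTOFF,
                    hyd_cutoff: float = HYDRATION_CUTOFF) -> PhaseMap:
    """Classify every state point and locate the per-pressure boundary.

    Boundaries are reported as the midpoint between the warmest coil and the
    coolest globule at each pressure; a pressure whose points all share one
    label is marked unresolved (``None``).
    """
    pressures = sorted({p.pressure for p in points})
    temps = sorted({p.temperature for p in points})
    if len(pressures) < 2 or len(temps) < 2:
        raise ValueError("need at least 2 pressures and 2 temperatures")
    return _phase_map(points, rg_cutoff, hyd_cutoff)


def _phase_map(points: Sequence[StatePoint], rg_cutoff: float,
               hyd_cutoff: float) -> "PhaseMap":
    rows = [{
        "pressure": p.pressure, "temperature": p.temperature,
        "mean_rg": p.mean_rg, "mean_hydration": p.mean_hydration,
        "label": classify_state(p.mean_rg, p.mean_hydration,
                                rg_cutoff, hyd_cutoff),
    } for p in points]
    table = (pd.DataFrame(rows)
             .sort_values(["pressure", "temperature"]).reset_index(drop=True))
    boundaries = {float(P): _boundary(sub)
                  for P, sub in table.groupby("pressure", sort=True)}
    return PhaseMap(table=table, boundaries=boundaries,
                    rg_cutoff=rg_cutoff, hyd_cutoff=hyd_cutoff)


def cutoff_sensitivity(points: Sequence[StatePoint],
                       rg_cutoff: float = RG_CUTOFF,
                       alt_rg_cutoff: float = RG_CUTOFF_ALT,
                       hyd_cutoff: float = HYDRATION_CUTOFF
                       ) -> tuple[PhaseMap, PhaseMap, pd.DataFrame]:
    """Rerun the map with an alternative R_G cutoff and list relabelled points.

    Only points whose mean R_G lies between the two cutoffs can change label.
    """
    base = _phase_map(points, rg_cutoff, hyd_cutoff)
    alt = _phase_map(points, alt_rg_cutoff, hyd_cutoff)
    merged = base.table.merge(
        alt.table, on=["pressure", "temperature", "mean_rg", "mean_hydration"],
        suffixes=("", "_alt"))
    changed = merged[merged["label"] != merged["label_alt"]].reset_index(drop=True)
    return base, alt, changed
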