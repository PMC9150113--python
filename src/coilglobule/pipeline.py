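"""End-to-end orchestration: trajectories -> observables -> fits -> phase map.

A :class:`RunConfig` names one trajectory per (temperature, pressure) state
point plus the polymer topology sidecar.  The pipeline streams each
trajectory, computes per-frame observables (R_G, optionally SASA, hydrogen
bonds, hydration-shell statistics), averages them over the analysis window
(default: the last third of frames), fits sigmoids at the reference
pressure to estimate the transition temperature and the classification
cutoffs, labels every state point and assembles the P-T phase map.

Outputs are plain TSV/JSON and are a pure function of (inputs, config): a
rerun reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import NoTransitionError, PipelineError
from .hydration import apply_window, classify_shell, hydrophobic_fraction
from .observables import (HBondCriterion, count_hbonds_by_category,
                          find_hbonds, radius_of_gyration, sasa)
from .structure_io import (Topology, iter_gro_frames, iter_pdb_frames,
                           read_topology, unwrap_polymer)
from .transition import (RG_CUTOFF, HYDRATION_CUTOFF, SigmoidFit, StatePoint,
                         TemperatureSeries, build_phase_map, cutoff_sensitivity,
                         derive_cutoff, estimate_tc, fit_sigmoid)

log = logging.getLogger("coilglobule")


@dataclass
class StatePointInput:
    pressure: float
    temperature: float
    trajectory: str


@dataclass
class RunConfig:
    """Pipeline configuration (see the YAML keys of the same names)."""

    state_points: list[StatePointInput]
    polymer_topology: str
    out_dir: str = "pipeline_out"
    window: float = 1.0 / 3.0           # trailing fraction of frames
    hbond_distance: float = 0.35        # nm
    hbond_angle: float = 30.0           # degrees
    r_philic: float = 0.35              # nm
    r_phobic: float = 0.55              # nm
    sasa_probe: float = 0.14            # nm
    sasa_points: int = 960
    compute_sasa: bool = True
    rg_cutoff: float | str = "derive"   # nm or "derive" (inflection value)
    hyd_cutoff: float | str = "derive"  # per residue or "derive"
    rg_cutoff_alt_offset: float = -0.1  # sensitivity rerun offset, nm
    reference_pressure: float | None = None  # default: lowest pressure
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.state_points:
            raise ValueError("no state points configured")
        if isinstance(self.window, (int, float)) and not 0 < self.window <= 1:
            raise ValueError("window fraction must be in (0, 1]")
        for cut in (self.hbond_distance, self.r_philic, self.r_phobic,
                    self.sasa_probe):
            if cut <= 0:
                raise ValueError("cutoffs must be positive")
        missing = [sp.trajectory for sp in self.state_points
                   if not Path(sp.trajectory).exists()]
        if missing:
            raise FileNotFoundError(f"missing trajectories: {missing}")
        if not Path(self.polymer_topology).exists():
            raise FileNotFoundError(
                f"missing polymer topology: {self.polymer_topology}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        sps = [StatePointInput(float(d["pressure"]), float(d["temperature"]),
                               str(base / d["trajectory"]))
               for d in raw.pop("state_points")]
        top = str(base / raw.pop("polymer_topology"))
        return cls(state_points=sps, polymer_topology=top, **raw)

    @classmethod
    def from_manifest(cls, manifest_path, **overrides) -> "RunConfig":
        """Build a config straight from a synthetic-ensemble manifest."""
        manifest_path = Path(manifest_path)
        man = json.loads(manifest_path.read_text())
        base = manifest_path.parent
        sps = [StatePointInput(float(d["pressure"]), float(d["temperature"]),
                               str(base / d["trajectory"]))
               for d in man["state_points"]]
        return cls(state_points=sps,
                   polymer_topology=str(base / man["polymer_topology"]),
                   **overrides)


def merge_polymer_bonds(partial: Topology, polymer: Topology) -> Topology:
    """Graft the sidecar's polymer bonds onto a file-derived partial topology."""
    n = len(polymer)
    if len(partial) < n or list(partial.names[:n]) != list(polymer.names):
        raise PipelineError("topology", cause=ValueError(
            "trajectory atoms do not start with the sidecar's polymer atoms"))
    water_bonds = partial.bonds[(partial.bonds >= n).any(axis=1)] \
        if len(partial.bonds) else partial.bonds
    bonds = np.vstack([polymer.bonds, water_bonds]) if len(water_bonds) \
        else polymer.bonds
    out = Topology(names=partial.names, elements=partial.elements,
                   roles=partial.roles, masses=partial.masses,
                   radii=partial.radii, resids=partial.resids, bonds=bonds)
    return out


def analyse_state_point(traj_path, polymer_top: Topology, config: RunConfig
                        ) -> pd.DataFrame:
    """Per-frame observable/hydration table for one trajectory (windowed)."""
    crit = HBondCriterion(config.hbond_distance, config.hbond_angle)
    fmt = Path(traj_path).suffix.lstrip(".").upper()
    it = (iter_gro_frames(traj_path) if fmt == "GRO"
          else iter_pdb_frames(traj_path))
    rows = []
    for partial, frame in it:
        top = merge_polymer_bonds(partial, polymer_top)
        whole = unwrap_polymer(frame, top)
        row = {"time": frame.time,
               "rg": radius_of_gyration(whole, top)}
        if config.compute_sasa:
            row["sasa"] = sasa(whole, top, probe=config.sasa_probe,
                               n_sphere_points=config.sasa_points)
        hb = count_hbonds_by_category(find_hbonds(frame, top, crit))
        n_res = top.n_polymer_residues
        row["hb_pp_per_res"] = hb["polymer-polymer"] / n_res
        row["hb_pw_per_res"] = hb["polymer-water"] / n_res
        if top.is_water.any():
            a = classify_shell(frame, top, config.r_philic, config.r_phobic)
            row["n_per_residue"] = a.n_per_residue
            row["F"] = hydrophobic_fraction(a) if a.first_shell else np.nan
        rows.append(row)
    if not rows:
        raise PipelineError("read", state_point=str(traj_path),
                            cause=ValueError("no frames"))
    return apply_window(pd.DataFrame(rows), config.window)


def _series(summary: pd.DataFrame, pressure: float, col: str,
            name: str) -> TemperatureSeries:
    sub = summary[(summary["pressure"] == pressure)
                  & summary[f"{col}_mean"].notna()].sort_values("temperature")
    return TemperatureSeries(
        observable=name, pressure=pressure,
        temperatures=sub["temperature"].to_numpy(),
        means=sub[f"{col}_mean"].to_numpy(),
        sds=sub[f"{col}_sd"].to_numpy(),
        n_frames=sub["n_frames"].to_numpy())


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    fits: dict[str, SigmoidFit]
    t_c: float | None
    t_c_uncertainty: float | None
    rg_cutoff: float
    hyd_cutoff: float
    phase_map: "pd.DataFrame"
    boundaries: dict[float, float | None]
    boundaries_alt: dict[float, float | None]
    changed_by_alt_cutoff: pd.DataFrame
    out_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage; see the module docstring for the data flow."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    polymer_top = read_topology(config.polymer_topology)
    polymer_top.validate()

    rows = []
    for sp in config.state_points:
        label = (sp.temperature, sp.pressure)
        log.info("analysing state point T=%s K, P=%s MPa", *label)
        try:
            df = analyse_state_point(sp.trajectory, polymer_top, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("observables", state_point=label, cause=exc)
        df.to_csv(out / f"obs_P{sp.pressure:g}_T{sp.temperature:g}.tsv",
                  sep="\t", index=False, float_format="%.6g")
        row = {"pressure": sp.pressure, "temperature": sp.temperature,
               "n_frames": len(df)}
        for col in df.columns:
            if col == "time":
                continue
            row[f"{col}_mean"] = float(df[col].mean())
            row[f"{col}_sd"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
        rows.append(row)
    summary = (pd.DataFrame(rows)
               .sort_values(["pressure", "temperature"]).reset_index(drop=True))
    summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                   float_format="%.6g")

    ref_p = (config.reference_pressure if config.reference_pressure is not None
             else float(summary["pressure"].min()))
    fits: dict[str, SigmoidFit] = {}
    try:
        fits["rg"] = fit_sigmoid(_series(summary, ref_p, "rg", "R_G"))
    except NoTransitionError as exc:
        raise PipelineError("fit", state_point=("*", ref_p), cause=exc)
    # SASA/hydration fits are desirable but not essential: without them the
    # pipeline still classifies (T_C and/or the hydration cutoff fall back)
    if config.compute_sasa and "sasa_mean" in summary:
        try:
            fits["sasa"] = fit_sigmoid(_series(summary, ref_p, "sasa", "SASA"))
        except NoTransitionError as exc:
            log.warning("SASA fit failed (%s); T_C left undefined", exc)
    if "n_per_residue_mean" in summary:
        try:
            fits["hydration"] = fit_sigmoid(
                _series(summary, ref_p, "n_per_residue", "hydration"))
        except NoTransitionError as exc:
            log.warning("hydration fit failed (%s); default cutoff used", exc)

    t_c = t_c_unc = None
    if "rg" in fits and "sasa" in fits:
        t_c, t_c_unc = estimate_tc(fits["rg"], fits["sasa"])
    rg_cut = (derive_cutoff(fits["rg"]) if config.rg_cutoff == "derive"
              else float(config.rg_cutoff))
    if config.hyd_cutoff == "derive" and "hydration" in fits:
        hyd_cut = derive_cutoff(fits["hydration"])
    elif config.hyd_cutoff == "derive":
        hyd_cut = HYDRATION_CUTOFF
    else:
        hyd_cut = float(config.hyd_cutoff)

    points = [StatePoint(r["pressure"], r["temperature"], r["rg_mean"],
                         r.get("n_per_residue_mean", 0.0))
              for r in summary.to_dict("records")]
    base, alt, changed = cutoff_sensitivity(
        points, rg_cutoff=rg_cut,
        alt_rg_cutoff=rg_cut + config.rg_cutoff_alt_offset,
        hyd_cutoff=hyd_cut)
    base.table.to_csv(out / "phasemap.tsv", sep="\t", index=False,
                      float_format="%.6g")
    with (out / "fits.txt").open("w") as fh:
        for f in fits.values():
            fh.write(f.to_text() + "\n")
    bounds = pd.DataFrame(
        [{"pressure": P, "boundary_T": b, "boundary_T_alt": alt.boundaries[P]}
         for P, b in base.boundaries.items()])
    bounds.to_csv(out / "boundaries.tsv", sep="\t", index=False,
                  float_format="%.6g")
    provenance = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "t_c": t_c, "t_c_uncertainty": t_c_unc,
        "rg_cutoff": rg_cut, "hyd_cutoff": hyd_cut,
        "reference_pressure": ref_p,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return PipelineResult(summary=summary, fits=fits, t_c=t_c,
                          t_c_uncertainty=t_c_unc, rg_cutoff=rg_cut,
                          hyd_cutoff=hyd_cut, phase_map=base.table,
                          boundaries=base.boundaries,
                          boundaries_alt=alt.boundaries,
                          changed_by_alt_cutoff=changed, out_dir=out)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
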