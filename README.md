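# coilglobule

Analysis toolkit for the temperature/pressure-induced **coil-to-globule
transition** of a thermoresponsive polymer — the single-chain counterpart of
LCST phase separation in PNIPAM-type solutions — simulated in rigid four-site
(TIP4P-family) water.

Given polymer-in-water configurations (GRO or multi-model PDB, orthorhombic
periodic boxes) and a per-atom topology annotation, the package computes the
structural observables and hydration statistics used to characterise the
transition, fits the transition temperature, and assembles a pressure–
temperature phase diagram:

* **Radius of gyration** `R_G = sqrt( Σ m_i |r_i − r_com|² / Σ m_i )` of the
  unwrapped chain.
* **Solvent-accessible surface area** via the Shrake–Rupley construction:
  the van der Waals envelope (Bondi radii) inflated by a 0.14 nm probe,
  sampled on a deterministic Fibonacci sphere lattice.
* **Hydrogen bonds** under the geometric criterion — donor–acceptor distance
  `< 0.35 nm` and hydrogen–donor–acceptor angle `< 30°` — categorised as
  polymer–polymer, polymer–water or water–water.
* **Hydration shell**: a water belongs to the first shell when its oxygen is
  within 0.35 nm of an amide N/O (*hydrophilic*) or within 0.55 nm of a
  methyl carbon (*hydrophobic*); `F` is the hydrophobic fraction of the
  shell.  Water–water H-bond connectivity is reported per molecule in the
  shell and in the bulk (each bond counted once).
* **Transition fits**: observable-vs-temperature series are fitted with the
  Boltzmann sigmoid `y(T) = A_glob + (A_coil − A_glob)/(1 + exp((T − T_C)/w))`;
  the transition temperature is the mean of the midpoints fitted to
  `R_G(T)` and `SASA(T)`, and classification cutoffs are the fitted values
  at the inflection point.
* **Phase-diagram classification**: a state point with mean `R_G ≥ 1.2 nm`
  is *coil*, otherwise *globule*; a globule retaining ≥ 12.5 shell waters
  per repeating unit is a *hydrated globule*.  A sensitivity rerun with a
  1.1 nm cutoff flags the labels that depend on the choice.

A first-class **synthetic-data generator** builds every input the pipeline
needs without molecular dynamics: an atactic 30-unit chain grown as a
self-avoiding persistent walk with a tunable compactness, jittered-lattice
water at bulk density, and temperature/pressure ensembles drawn from a
two-state (coil/globule) mixture with a prescribed transition midpoint — so
the whole pipeline can be validated against known ground truth.

## Worked example

```python
from coilglobule import builtin_model, dipole_moment
m = builtin_model("TIP4P/Ice")
print(f"{m.name}: mu = {dipole_moment(m):.3f} D (published {m.mu_ref})")

from coilglobule import EnsembleSpec, generate_ensemble, RunConfig, run_pipeline
spec = EnsembleSpec(true_tc={0.1: 295.0}, frames_per_point=10, seed=1,
                    box_length=3.0)
generate_ensemble(spec, "ens")
cfg = RunConfig.from_manifest("ens/manifest.json", out_dir="out",
                              window=1.0, log_level="WARNING")
res = run_pipeline(cfg)
print(f"T_C = {res.t_c:.1f} +/- {res.t_c_uncertainty:.1f} K")
print(res.phase_map[["temperature", "mean_rg", "label"]].to_string(index=False))
```

prints

```
TIP4P/Ice: mu = 2.426 D (published 2.426)
T_C = 295.6 +/- 1.3 K   (generated with midpoint 295.0 K)
 temperature  mean_rg   label
       278.0 2.428286    coil
       283.0 2.415440    coil
       288.0 2.197703    coil
       293.0 2.074693    coil
       298.0 1.308800 globule
       303.0 1.400462 globule
       308.0 0.987249 globule
```

i.e. the pipeline read back the generated trajectories, fitted sigmoids to
`R_G(T)` and `SASA(T)`, recovered the transition midpoint the ensemble was
generated with (295.6 vs 295.0 K), and labelled each state point with the
cutoff derived from the fit's inflection.

The same stages are available from the shell:

```bash
coilglobule watermodel --name TIP4P/2005 --check-dipole
coilglobule generate --spec spec.yaml --out ens/
coilglobule observables --traj ens/traj_P0.1_T278.gro --top ens/polymer.top.tsv --out obs.tsv
coilglobule run --config run.yaml
```

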