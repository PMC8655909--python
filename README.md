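# rnadsorb

Coarse-grained Monte Carlo simulations of short RNA fragments adsorbing
onto a flat attractive substrate, with free-energy profiles from umbrella
sampling + WHAM and an ideal-chain (Edwards) reference theory.

## The problem

Whether RNA binds a surface — a viral capsid interior, a nanoparticle, a
delivery vesicle — depends not only on the attraction strength but on the
RNA's secondary structure: base-paired stems behave as rigid objects,
while unpaired strands can deform and spread. This package models that
competition at minimal resolution. Each nucleotide is five beads (a
phosphate, a sugar virtual site and a rigid base triangle); stems are held
in A-form geometry by a harmonic restraint on the εRMSD metric; the
substrate is a featureless plane acting on phosphates through a screened
electrostatic wall potential

    U(z) = ε_r (λ_r/z)¹² − ε_surf e^{−z/λ_D},   λ_r = 0.1 nm, λ_D = 1 nm,

whose strength ε_surf is scanned. For every fragment — in its structured
("wiss") and unstructured ("noss") version — the package computes:

* the potential of mean force F(d_CM) of the centre-of-mass height, via
  umbrella-sampling Monte Carlo and WHAM, with blocking-analysis +
  block-bootstrap error bars; the adsorption free energy F_m is its
  minimum relative to the large-distance plateau;
* the per-monomer contact fraction
  φ = (1/ε_min) ∫ ρ(z) min{0, U(z)} dz (exact for a square well) and the
  contact number N·φ;
* the gyration anisotropy ⟨R_g⊥²⟩/⟨R_g∥²⟩ of the adsorbed ensemble;
* the ground-state (Edwards) free energy per monomer of an infinite ideal
  chain in the same wall potential, the theoretical baseline for the
  per-nucleotide scaling of F_m with the well depth ε_min.

Three built-in fragment fixtures mirror archetypal motifs: a 22-nt hairpin
with a small bulge (S1, 7 bp), a 50-nt bulged hairpin (S2, 15 bp) and a
36-nt two-hairpin multibranch with a single-nucleotide hinge (S3, 11 bp).

## Worked example

```python
import numpy as np
from rnadsorb import fragments, sampler, surface, wham_pmf

frag = fragments.make_fragment("S1", structured=True, seed=1)
wall = surface.DebyeHuckelWall(eps_surf=0.89)
windows = sampler.default_windows(n_equil=500, n_prod=2500,
                                  seeds=range(15))
samples = sampler.run_window_scan(frag.topology, None, wall, windows,
                                  frag.conformation, frag.template)
pmf = wham_pmf.pmf_from_samples(samples)
print(f"F_m = {wham_pmf.adsorption_free_energy(pmf):.2f} kBT at "
      f"{pmf.bin_centers[np.nanargmin(pmf.free_energy)]:.2f} nm")
```

```
F_m = -3.65 kBT at 1.33 nm
```

The structured 22-nt hairpin at ε_surf = 0.89 kBT binds with about 4 kBT
and sits with its centre of mass ≈ 1.3 nm above the plane — roughly the
A-form helix radius plus the wall-contact height, because the restrained
stem cannot flatten onto the surface. Running the same scan for the
unstructured variant gives a shallower minimum at this attraction: rigid
base-paired fragments attach more easily when the surface is weakly
attractive, while a strongly attractive surface favours the deformable
unstructured chain.

The same pipeline is scriptable from the shell:

```bash
rnadsorb run config.yaml     # build -> sample -> wham -> observables
                             #       -> edwards -> report (summary.json)
```

with a YAML config selecting the fragment, wall family, ε_surf list,
window layout and master seed; every stage is cached and reproducible
(identical config + seed ⇒ identical trajectories).

## Layout

| module | contents |
|---|---|
| `rnadsorb.cg_model` | nucleotide geometry, topology parsing, εRMSD, energies |
| `rnadsorb.surface` | Debye–Hückel, Mie 9-3 and square-well walls |
| `rnadsorb.fragments` | S1/S2/S3 stand-ins, builders, self-avoiding walks |
| `rnadsorb.sampler` | umbrella-window Metropolis Monte Carlo (numba) |
| `rnadsorb.wham_pmf` | WHAM, blocking analysis, bootstrap, PMF summaries |
| `rnadsorb.observables` | densities, contact numbers, gyration components |
| `rnadsorb.edwards` | ideal-chain ground-state solver |
| `rnadsorb.config` / `rnadsorb.pipeline` / `rnadsorb.cli` | config schema, staged pipeline, `rnadsorb` CLI |
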