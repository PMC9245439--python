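# micellometrics

Structural analysis of self-assembled micelles of sequence-defined,
charged amphiphilic peptoid block copolymers — and of molecular
configurations more generally. The package computes, from PDB/GRO
coordinate files or from its own synthetic configurations:

- **Gyration-tensor descriptors.** The weighted second-moment tensor
  `G_ab = (1/W) Σ_i w_i (r_ia − ⟨r_a⟩)(r_ib − ⟨r_b⟩)` with mass or
  coherent-neutron-scattering-length weights; its eigenvalues
  λ₁ ≥ λ₂ ≥ λ₃ give `R_g² = λ₁ + λ₂ + λ₃`, the asphericity
  `b = 1 − 3(λ₁λ₂ + λ₂λ₃ + λ₃λ₁)/(λ₁+λ₂+λ₃)²` (0 for a sphere, 1 for a
  rod) and the shape parameter
  `S = 27(λ₁−λ̄)(λ₂−λ̄)(λ₃−λ̄)/(λ₁+λ₂+λ₃)³` (−0.25 for a perfect oblate,
  0 for a sphere, 2 for a perfect prolate). The hydration-shell variant
  augments the selection with every water molecule whose oxygen lies
  within 0.35 nm of the solute.
- **Solvent-accessible surface area.** Shrake–Rupley point counting with
  a 1.4 Å probe rolling over Bondi van der Waals spheres; total,
  per-chain and per-atom areas, plus the SASA : R_g² ratio table used as
  a sphericity diagnostic across systems.
- **Neutron scattering observables.** Partial radial distribution
  functions, the Faber–Ziman neutron-weighted total g(r), the static
  structure factor `S(Q) = 1 + 4πρ ∫ r²(g−1) sinc(Qr) dr`, and Guinier
  extraction of R_g from the low-Q region (ln S linear in Q² with slope
  −R_g²/3).
- **Ionic structure.** Na⁺ and water coordination of carboxylate groups
  (0.35 nm cutoff), nearest interchain carboxylate-carbon distances,
  COO–Na–COO salt-bridge fractions (0.5 nm cutoff) and the condensed
  counterion fraction.
- **A synthetic micelle generator** that plants known ground truth
  (condensation fraction, salt bridges, core/corona geometry, hydration
  shell) so every analysis stage can be validated end to end without
  running molecular dynamics.

It is aimed at simulators characterizing micelle morphology from MD
trajectories and comparing against small-angle neutron scattering.

## Worked example

```python
import numpy as np
from micellometrics import (SyntheticMicelleSpec, generate_micelle,
                            analyze_frames, compute_sasa, select,
                            salt_bridges)

spec = SyntheticMicelleSpec(n_chains=28, na_condensation_fraction=0.1,
                            planted_salt_bridges=2, n_frames=5, seed=1)
system = generate_micelle(spec)

results = analyze_frames(system, "micelle", include_rgb=True)
print(f"Rg = {np.mean([r.rg for r in results]):.3f} nm")
shell = analyze_frames(system, "micelle", include_shell=True,
                       shell_cutoff=0.35)
print(f"Rg with 0.35 nm hydration shell = {shell[0].rg:.3f} nm")
area = compute_sasa(select(system.frames[0], "micelle"))
print(f"SASA total = {area.total:.1f} nm^2, per chain = "
      f"{area.per_chain:.2f} nm^2")
report = salt_bridges(system)
print(f"condensed Na+ = {report.condensed_fraction:.1f}%, bridge "
      f"fraction (<0.5 nm pairs) = {report.fraction_05:.1f}%")
```

prints

```
Rg = 2.055 nm
Rg with 0.35 nm hydration shell = 2.132 nm
SASA total = 361.6 nm^2, per chain = 12.92 nm^2
condensed Na+ = 10.7%, bridge fraction (<0.5 nm pairs) = 100.0%
```

The generated micelle is a 28-chain aggregate of 25-mer chains (five
N-decyl residues forming the core, a methoxyethyl/carboxyethyl corona);
the shell-augmented R_g exceeds the bare value because peripheral water
mass is added, the condensed fraction recovers the planted 10%
(3 of 28 ions), and both planted bridges are found — bridged pairs are
100% of the carboxylate pairs closer than 0.5 nm.

The same analyses run from the shell:

```
micellometrics gen --n-chains 28 --condensation 0.1 --seed 1 --out micelle
micellometrics shape micelle.gro --out analysis
micellometrics ions micelle.gro --out analysis
micellometrics run config.yaml --out results_dir
```

## Layout

| module | contents |
| --- | --- |
| `micellometrics.model` | `AtomSet`/`MicelleSystem` containers, selections, periodic geometry, solvation shell |
| `micellometrics.io` | PDB/GRO readers and writers (MDAnalysis-backed), role inference |
| `micellometrics.synthetic` | micelle generator with planted ground truth, ideal-body fixtures, study-series presets |
| `micellometrics.shape` | gyration tensor, asphericity, shape parameter, per-frame analysis |
| `micellometrics.sasa` | Shrake–Rupley SASA, SASA : R_g² ratio table |
| `micellometrics.scattering` | partial/weighted RDFs, S(Q), Guinier R_g |
| `micellometrics.ions` | coordination, nearest-interchain distances, salt bridges, condensation |
| `micellometrics.reporting` | block-averaged summaries, 2D joint densities, Pearson correlations |
| `micellometrics.pipeline` / `cli` | YAML-configured end-to-end runs, `micellometrics` command |

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.
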