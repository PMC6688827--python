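# membind

Analysis of peripheral protein–membrane binding in molecular-dynamics
trajectories, built around the membrane recognition of the lipid kinase
PIP5K1A: how the protein approaches a PIP-containing bilayer, which
residues grip the lipid headgroups, what orientation it binds in, and how
the two subunits of the dimer share (or fail to share) the membrane.

It is for simulation groups post-processing coarse-grained or atomistic
membrane-binding ensembles who want the standard analyses as tested,
scriptable library calls rather than one-off shell pipelines — and who want
every stage validated against synthetic trajectories with planted ground
truth.

## What it computes

- **Binding kinetics** — protein/bilayer centre-of-mass distance per frame
  (3D or |Δz|), ensemble averages, and single-exponential fits
  d(t) = d∞ + (d₀ − d∞)·e^(−t/τ).
- **Residue–lipid contacts** — per-residue contact counts against
  substrate-lipid headgroups (min-particle < 0.7 nm, coarse-grained; or
  COM-to-headgroup-COM < 0.35 nm, atomistic), normalised to the
  most-contacting residue, as profiles and residue × time occupancy.
- **Orientation landscapes** — the Rzz scalar (the (3,3) element of the
  Kabsch rotation matrix to a productively-bound reference pose, after
  in-plane fitting), pooled (distance, Rzz) probability maps over replicate
  ensembles, and detection of binding modes as smoothed local maxima.
- **Dimer geometry** — the three-point hinge angle θ between subunits
  (anchored at the catalytic lysines, simulation residues 182 and 505),
  per-subunit membrane distances, geometric hydrogen-bond counts
  (≤ 0.35 nm, ≤ 30°) with moving averages, and per-residue Cα RMSF.
- **Bookkeeping the analyses depend on** — simulation↔crystal-structure
  residue renumbering (simulation 1–253 ↔ PDB 57–309, 254–324 ↔ 356–426),
  a small selection language, and GRO/PDB/XTC/TRR/DCD IO via MDAnalysis.
- **Synthetic systems** — lattice bilayers of configurable composition
  (default 75/20/5 PC/PS/PI4P), sphere-model proteins with planted hotspot
  residues, and seeded rigid-body encounter trajectories with exponential
  approach kinetics and one or two orientational binding modes, plus the
  recorded ground truth for recovery testing.

## Worked example

Run the shipped synthetic demo (three seeded replicates of a monomer
encountering a 75/20/5 bilayer, 400 frames each):

```python
from membind.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict({
    "synthetic": {"preset": "demo"}, "seed": 3,
    "stages": ["bind", "contacts", "landscape"],
    "output_dir": "demo_out",
})
bundle = run_pipeline(cfg)
print(bundle.binding_fit)
print(bundle.modes)
print(bundle.contact_profile.sort_values("raw", ascending=False).head(5))
bundle.write()
```

Output (exactly reproducible from the seed):

```
{'d0_nm': 7.9916, 'd_inf_nm': 4.8124, 'tau_ns': 19.506,
 'residual_rms_nm': 0.1162, 'converged': True}
[{'label': 'mode1', 'peak_distance_nm': 4.520, 'peak_rzz': 0.926, 'mass': 0.537},
 {'label': 'mode2', 'peak_distance_nm': 5.431, 'peak_rzz': 0.138, 'mass': 0.463}]
 residue  pdb_residue  raw  normalized
     188          244  612    1.000000
     183          239  611    0.998366
     190          246  610    0.996732
     185          241  610    0.996732
     182          238  607    0.991830
```

Reading this: the ensemble-mean approach curve fits τ ≈ 19.5 ns against the
planted 20 ns (d₀ ≈ 8 nm start, plateau near the bound distance). The
landscape shows two modes — a productive pose close to the membrane
(d ≈ 4.5 nm, Rzz ≈ 0.93 relative to the automatically picked
catalytic-site-down reference) and a looser encounter pose further out
(d ≈ 5.4 nm, Rzz ≈ 0.14). The top contact residues map to crystal-structure
numbering via the built-in renumbering: residues 238 and 244 — the
catalytic lysine and arginine of the PIP-binding DLKGS…R motif — are among
the strongest PIP contacts, as planted.

The same analyses are available from the shell:

```sh
membind synth --preset demo --seed 0 --out demo          # system + truth
membind bind --structure demo/system.gro --trajectory demo/trajectory.pdb --json
membind contacts --structure demo/system.gro --trajectory demo/trajectory.pdb \
    --cutoff 0.7 --mode min_particle --out contacts.csv
membind run --config my_run.yaml                          # full pipeline
```

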