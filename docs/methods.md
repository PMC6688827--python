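# Methods

`membind` post-processes molecular-dynamics trajectories of a peripheral
protein — concretely, a PIP kinase — encountering and binding a
PIP-containing lipid bilayer. Everything it computes is validated end-to-end
against a synthetic trajectory generator with planted ground truth. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic validation does and does not establish.

## Analyses

### Membrane-binding kinetics

Binding progress is the distance between the protein and bilayer centres of
mass per frame. Two metrics are provided: the full 3D separation and the
`z_component` metric, |Δz| along the membrane normal (reported as an
absolute value so approaches to either leaflet read identically). The
separation vector is always wrapped componentwise to the minimum periodic
image (orthorhombic boxes only); each molecule's coordinates are first made
whole by nearest-image chaining from its first particle, which is valid for
molecules smaller than half the box. Replicate series are averaged
pointwise (`ensemble_mean`), and kinetics are summarised by a least-squares
fit of

    d(t) = d_inf + (d0 − d_inf) · exp(−t/τ)

with initial guesses d0 = first value, d_inf = last value, τ = half the
time span, and τ constrained positive. A single exponential with a plateau
is the minimal form consistent with the approach curves; the model function
is pluggable. Non-convergence is reported in the result object (with the
optimizer message) rather than raised.

### Residue–lipid contacts

Two contact definitions are shipped because both occur in practice at the
two simulation resolutions:

- `min_particle` (coarse-grained convention, default cutoff **0.7 nm**): a
  residue contacts in a frame iff the minimum over all residue-particle ×
  target-particle minimum-image distances is below the cutoff;
- `com` (atomistic convention, default cutoff **0.35 nm**): the residue COM
  must be within the cutoff of some target lipid's headgroup COM.

The inequality at the cutoff is **strict** (`< cutoff`): boundary pairs are
excluded. This is worth documenting because some common tools use `≤`.
Per-frame occupancy is 0/1 against *any* target lipid by default; a
per-lipid-count variant is a flag. Profiles are normalised to the residue
with the largest count; an all-zero profile normalises to zeros and is
flagged rather than raising. Proximal-substrate counting (lipids whose
headgroup COM lies within a radius — default **3.5 nm** — of a site COM)
also uses a strict inequality.

### Orientation (Rzz) and the distance–orientation landscape

The orientation scalar Rzz is the (3,3) element of the least-squares
rotation matrix between a frame and a reference pose **after** the frame is
fitted in the xy plane: the in-plane fit removes xy translation (COM match)
and the closed-form 2D least-squares rotation about z, leaving tilt
untouched. Rzz = 1 means the same tilt as the reference, −1 an inverted
protein; rotations about the membrane normal and in-plane translations do
not change it. Superposition uses the Kabsch algorithm (SVD, reflection
corrected via the determinant sign, mass weights by default with a flag for
uniform weights; collinear inputs raise a degeneracy error).

The reference "productively bound" pose is picked automatically as the
frame, across the ensemble, maximising contacts between the catalytic-site
motif residues (DLKGS, simulation residues 180–184 by default) and the
substrate-lipid headgroups; a user-supplied reference overrides this, and
an ensemble with no catalytic contact raises an error directing the user to
supply one.

The landscape is a pooled 2D probability histogram (default 50×50 bins
spanning the observed ranges) over (|Δz| COM separation, Rzz) across all
replicate frames. Pooling rather than per-replicate averaging is chosen for
simplicity; for equal-length replicates the two are identical, and a
per-replicate path can be built from the same series objects. Modes are
local maxima of the Gaussian-smoothed map (σ = 1 bin), ranked by smoothed
density, accepted greedily with a minimum Chebyshev separation of 2 bins;
ties break toward the lowest distance bin, then the lowest Rzz bin. Each
mode's mass is the probability assigned by nearest-peak partitioning of the
bins. Requesting more modes than exist returns the available ones with a
warning.

### Dimer geometry, hydrogen bonds, RMSF

The hinge angle θ between the two kinase subunits is the planar angle at a
vertex COM between two arm COMs. Default anchors are the backbone (Cα/BB)
particles of the catalytic lysine of subunit A (simulation residue 182),
the interface valine of subunit A (residue 29), and the catalytic lysine of
subunit B (residue 505). Anchors are selections by residue and particle
name, not raw atom serial numbers, because serials are build-specific; the
Cα choice for the anchors is an assumption. The subunit-B offset is
505 − 182 = **323** and is configurable (`DIMER_SUBUNIT_OFFSET` is derived
from the catalytic-lysine numbering, the only direct evidence available).

Hydrogen bonds use the common geometric criterion — donor–acceptor
minimum-image distance ≤ **0.35 nm** and hydrogen–donor–acceptor angle ≤
**30°** (both inclusive, both configurable) — counted over explicit
(donor, hydrogen, acceptor) triples; donors without mapped hydrogens are a
topology error. The moving average is centred in time with shrinking
windows at the edges, so output length equals input length.

RMSF is computed per backbone particle after pre-aligning all frames to
frame 1 and then iteratively superposing onto the time-average structure
(the common convention; a frame-1 reference is a flag). Global rigid-body
motion is removed by construction; note that the rigid fit absorbs ~1/n of
a single particle's independent motion.

## The synthetic-data generator

The generator emulates the statistical structure of coarse-grained
encounter simulations; it is the ground truth against which every analysis
stage is validated.

- **Bilayer** (`build_bilayer`): two leaflet lattices at z = ±thickness/2
  (default thickness 4.0 nm, spacing 0.8 nm ≈ a POPC area per lipid), each
  lipid one headgroup bead and two tail beads. Species counts come from
  largest-remainder rounding of the composition — default **75% PC / 20%
  PS / 5% PI4P** — and are shuffled over sites with the seed. The default
  20×20 grid gives an 800-lipid, 16×16 nm patch with exact 600/160/40
  counts; the `monomer-cg` preset uses a 10×10 grid at 0.75 nm spacing
  (the 7.5×7.5 nm patch used for monomer encounter runs, 150/40/10).
- **Protein** (`build_protein_model`): a rigid one-bead-per-residue sphere
  (default 324 residues, radius 2.5 nm — the approximate monomer radius).
  Internal dynamics are deliberately absent: the coarse-grained elastic
  network preserves tertiary structure, so a rigid stand-in suffices for
  analysis testing. The designated hotspot residues — by default the
  catalytic DLKGS-to-R/K-rich region (180–197) plus the activation loop
  (276–313), the two regions that dominate the kinase's PIP contact
  profile — occupy a quasi-uniform polar cap around the −z pole, separated
  from the other beads by a polar margin (default 0.2 in cos θ). The margin
  mimics a protruding membrane-binding patch and makes the planted contact
  ordering geometrically strict, so hotspot-recovery tests are not decided
  by ties at the cap boundary. The point set is re-balanced on the sphere
  so its centroid coincides with the sphere centre (the map is monotone in
  z and preserves the cap ordering exactly).
- **Encounter** (`simulate_encounter`): the COM separation follows
  d(t) = d_b + (d0 − d_b)exp(−t/τ) plus iid Gaussian noise (σ, default
  0.2 nm); defaults d0 = 8 nm (protein COM ~4 nm above the surface),
  d_b = 4.5 nm, τ = 150 ns, frames every 0.5 ns for 2 μs. The orientation
  performs a random axis-angle walk while unbound (step 0.15 rad/frame) and,
  once the noiseless distance is within max(2σ, 0.02 nm) of the bound
  distance, relaxes geodesically toward the drawn mode's orientation (time
  constant τ/5) with a small bound jitter (0.02 rad/frame). Binding modes
  are drawn per trajectory from configurable weights; each mode has an Rzz
  relative to the productive reference pose (1 = hotspot cap on the
  headgroups) and optionally its own bound distance. Defaults plant a
  looser encounter mode (Rzz 0.45, d 5.4 nm, weight 0.4) and a productive
  mode (Rzz 1.0, weight 0.6). Binding is irreversible by default (matching
  productive binding); a detachment rate option produces release/retreat/
  re-approach episodes for alternation tests. Because the lattice bilayer
  has no lipid diffusion, the substrate lipids are relocated (by exchanging
  lattice-site species assignments, composition preserved) to cluster
  beneath the landing point — emulating the substrate enrichment observed
  under a bound kinase; this can be disabled. All randomness flows from one
  seeded NumPy generator and the full realisation (mode per frame, binding
  frame, noiseless distance) is recorded in `SyntheticTruth`.
- **Dimer stand-ins**: `build_synthetic_dimer` places two sphere subunits
  so the three-point hinge angle at the default anchors equals a requested
  value exactly (180° = the flat crystallographic arrangement); it is a
  geometric stand-in, clearly labelled synthetic, for exercising the hinge
  metric. `simulate_dimer_encounter` descends a rigid dimer with subunit A
  following the encounter kinetics and subunit B riding a fixed offset
  above, emulating one-site-bound configurations.

**What passing tests show — and don't.** The generator has no forces, no
lipid diffusion, no solvent or ions, no internal protein dynamics and no
protein lateral diffusion. Recovery of planted τ, hotspots and modes
demonstrates that the analysis chain is correct and unbiased on data whose
statistical structure matches its assumptions; it does not demonstrate
anything about force fields or sampling in real simulations.

## Numerical choices and problem sizes

- Kabsch degeneracy threshold: second singular value ≤ 1e-12 of the
  largest. Rzz is clipped to [−1, 1] against rounding.
- Largest-remainder ties break by species name, making composition
  assignment deterministic.
- `fit_binding_curve` treats τ as bounded positive via optimizer bounds;
  a constant series is a precondition violation (error), non-convergence a
  reported state.
- Validation problem sizes are scaled for a single CPU: noiseless-τ
  recovery uses 1000 frames; noisy-τ (σ = 0.3 nm) uses 2000 frames;
  ensemble-mean fits use 25 replicates × 800 frames; hotspot recovery uses
  1000 frames at σ = 0.2; landscape recovery uses 20 ensembles of 8
  replicates × 600 frames. Eight replicates per landscape ensemble are
  chosen so that both planted modes are realised with high probability
  (with equal weights, the chance that all replicates draw one mode is
  2⁻⁷ ≈ 0.8%); with fewer replicates, apparent failures are mode-sampling
  starvation, not detector error.
- Pipeline outputs are written with fixed float formatting, so identical
  config + seed reproduces byte-identical CSV/JSON.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- Molecule unwrapping by nearest-image chaining assumes compact molecules;
  the bilayer's xy COM is not meaningful after chaining (its z COM, the
  quantity used, is).
- The crystallographic hinge-angle check runs against a synthetic dimer
  built with crystal geometry unless a real crystal-structure file is
  supplied (see `tests/test_acceptance.py`); the packaged data contain no
  PDB depositions.
- The hydrogen-bond counter requires an explicit donor→hydrogen map; it
  does not infer bonding from distances.
- No free-energy estimates, residence-time/k_off modelling, kinetic
  networks between modes, or curvature analysis.
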