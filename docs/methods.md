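# Methods

`memanchor` is a desk-scale, coarse-grained re-implementation of a
chemical-shift-restrained ensemble-refinement and membrane-topology
workflow for the membrane-anchor region of α-synuclein (αS residues
1–30, ssNMR-assigned region 6–25).  This note documents the models, the
parameters that matter, the synthetic-data generators, and the
numerical choices, in the package's own terms.

## Coarse peptide model

Each residue carries five sites: backbone N, CA, C, O and one sidechain
centroid (SC; coincident with CA for glycine).  Geometry is built from
internal coordinates with fixed bond lengths and angles (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; N–CA–C 111.2°, CA–C–N 116.2°,
C–N–CA 121.7°; ω fixed trans) by sequential NeRF placement.  The only
degrees of freedom are the per-residue (φ, ψ) torsions.  φ of residue 1
positions no heavy atom (there is no preceding carbonyl carbon); the
builder ignores it, extraction reports it as NaN, and the helicity
assignment judges residue 1 on ψ alone.  Consecutive CA–CA distances
come out at 3.804 Å and the canonical helix (all residues at
φ, ψ = −57°, −47°) has a rise of 1.558 Å/residue and a CA radius of
2.27 Å, matching real α-helix geometry.

The SC centroid sits at a residue-specific distance from CA (tabulated
in `chain.py`, e.g. Ala 1.53 Å, Phe 3.41 Å, Lys 3.50 Å) along a fixed
direction in the N–CA–C frame.  Charge classes are formal: Lys/Arg +1,
Asp/Glu −1, plus +1 on the N-terminal amine (the N atom of residue 1).
Hydrophobic residues are {A, V, L, I, M, F}.  All tables can be
overridden from YAML.

## Descriptors

- **CA-RMSD to the ideal helix** over residues 6–25 (the assigned
  region; the flexible termini are excluded), after least-squares
  superposition on the same atoms.
- **Dipole moment** of residues 6–25 in e·nm: |Σ qᵢ(rᵢ − o)| with formal
  charges and origin o at the centroid of the selected sites.  The
  selection carries net charge +3 e, so the origin convention matters;
  it is configurable, and backbone partial dipoles are off by default.
- **Radius of gyration** (unit masses over all coarse sites) and
  **SASA** by Shrake–Rupley sphere sampling (960 Fibonacci points per
  atom, probe 1.4 Å, coarse radii: N 1.55, CA/C 1.70, O 1.52 Å, SC per
  residue; zero-radius glycine centroids are skipped).
- **Convergence metrics** per cumulative block: running-mean-structure
  CA RMSD, dihedral drift (RMS change of the per-torsion mean resultant
  vectors, which equals the circular RMSD of mean dihedrals for ordered
  ensembles and decays to zero for stationary disordered ones), block
  Rg, and block SASA (sub-sampled; SASA is the costliest metric).
  Default thresholds: 0.5 Å, 15°, 0.5 Å drift, 5% relative drift.

## Toy shift predictor

δ(res, atom) = δ_coil(aa, atom) + w(φ, ψ) · Δδ_helix(atom), with
w = exp(−[(φ+57)² + (ψ+47)²]/(2·25²)) using circular differences, a
packaged random-coil table, and Δδ_helix = (+2.6, −0.4, +1.9) ppm for
(CA, CB, C).  This is a deliberate stand-in for a structure-based
predictor: deterministic, smooth, and qualitatively correct (helix
raises CA/C and lowers CB).  Glycine is assigned a nominal CB coil
value so every residue carries the same three reporters; real glycine
has no CB, which is one of the places the coarse model departs from
chemistry.  A perturbed variant (rescaled secondary shifts, displaced
basin, wider width) is packaged for cross-validation so that validation
never reuses the restraining predictor.  Claimed error estimates are
0.4/0.5/0.4 ppm for CA/CB/C.

## Replica-averaged restraint

E = k · Σ_j max(0, |δ̄_j − δ_exp,j| − ε_j)², where δ̄_j is the mean
predicted shift over the M = 4 simultaneously evolving replicas.  The
flat-bottom half-width ε defaults to the per-row σ of the shift table;
only CA/CB/C are restrained by default, and residues without data
(1–5, 26–30) contribute nothing.  Averaging over replicas enforces the
measurement as an ensemble property: compensating deviations between
replicas are free, which the tests exercise directly (M = 2 with ±d
deviations gives E = 0).

The force constant is k = 200 kJ mol⁻¹ ppm⁻².  This is a calibration of
the coarse model, fixed before the acceptance tests were written:
confining one (φ, ψ) pair to the helical basin costs ≈10 kJ/mol of
torsional entropy at 278 K, and the restraint gradient per unit basin
weight is ≈2k·v (v = violation in ppm), so k must be large enough that
the equilibrium violation v ≈ 5/k ppm lies inside the flat bottom.  At
k = 200 the residual restraint energy is dominated by irreducible
conflicts between the noisy targets of the three nuclei of a residue,
not by a helicity deficit.

## Physical energy and sampler

The coarse physical energy has three torsion-space terms plus excluded
volume:

1. **Torsion propensity**: two attractive Gaussian wells, helical
   (−57, −47; depth 5.5 kJ/mol, width 30°) and extended
   (−120, +130; depth 2.5 kJ/mol, width 40°).
2. **Helix cooperativity**: −J Σᵢ hᵢhᵢ₊₁ with hᵢ the helical basin
   weight (width 30°) and J = 6.5 kJ/mol.  This nearest-neighbour term
   is the coarse analogue of the cooperative hydrogen-bond network of a
   real helix.  It is essential: shift data constrain only per-residue
   basin populations, so without cooperativity the sampler satisfies
   the ensemble-averaged restraints with isolated in-basin residues
   that never form the ≥4-residue runs that define measurable helix.
3. **Excluded volume**: soft-sphere repulsion between sidechain
   centroids with |i−j| ≥ 2, E = k_rep Σ max(0, d₀ − r)², d₀ = 4.0 Å,
   k_rep = 2 kJ mol⁻¹ Å⁻² (the ideal helix, whose minimum non-local
   centroid separation is 4.6 Å, is strain-free).
4. Optionally, a **membrane slab term** for placed conformations
   (hydrophobic attraction into / polar penalty for the acyl region);
   it is not used during sampling — refinement is performed in torsion
   space without a bilayer, and topology analyses use constructed
   placements.

With these defaults the unrestrained chain at 278 K is largely
disordered (mean 6–25 helicity ≈ 0.35, i.e. transient intrinsic
propensity), and shift restraints tip the balance toward the helical
state.  The balance was calibrated once against the recovery setup
described below and then frozen.

The sampler runs M = 4 replicas in lockstep through annealing cycles of
600 ps: 100 ps at 278 K (the collection segment), a 100 ps linear ramp
to 350 K, 100 ps at 350 K, and a 300 ps linear cool.  "ps" is a nominal
bookkeeping unit: each ps maps to `steps_per_ps` (default 10) MC
sweeps, and one sweep proposes one single-angle Gaussian move (width
15°) per residue per replica, accepted by Metropolis on
E_phys + E_restraint at the segment temperature.  Move widths adapt
toward 30–50% acceptance during the discard horizon only, so collected
frames come from a fixed kernel.  Replicas never exchange; they couple
only through the restraint average.  Frames are saved every 10 ps of
the 278 K holds after discarding whole cycles (discard rounded up), and
the reference protocol's arithmetic falls out exactly: 417 cycles =
250.2 ns/replica, and a 50 ns discard (84 cycles) with 10 ps saving
over 4 replicas leaves 13 320 conformations.  Everything is
reproducible from the per-replica seeds.

Sequential-scan single-angle Metropolis preserves the Boltzmann
distribution; the tests verify this on a two-residue toy system against
quadrature enumeration of the torsion potential (total variation
< 0.05) and check uniform marginals on a flat potential.

## Ensemble analyses

- **FES**: 2-D histogram of (CA-RMSD to ideal helix, dipole), 40×40
  bins spanning the observed ranges padded 5%, F = −kT ln(n/n_max) at
  278 K, so the most populated bin sits at F = 0 and unoccupied bins
  are flagged rather than zero.  (Colour conventions that run from 0 to
  −30 kJ/mol are the same surface with the sign flipped.)  Basins are
  local minima over the 8-neighbourhood; each occupied bin is assigned
  to a basin by steepest descent (lexicographic tie-break) and basin
  populations are drainage-area count shares.
- **Helix assignment**: φ ∈ [−100, −30], ψ ∈ [−77, −17] and membership
  in a run of ≥4 consecutive in-window residues.  This replaces a
  hydrogen-bond-based assignment, which a 5-site model cannot support.
- **RMSF**: CA fluctuations about the iteratively superposed mean
  structure (fit on residues 6–25 by default).
- **Salt bridges**: occupancy of (positive, negative) sidechain
  centroid pairs within 5.0 Å; the N-terminal amine uses the N atom.
  **Hydrophobic contacts**: hydrophobic centroid pairs, |i−j| ≥ 2,
  5.0 Å.  With single-centroid sidechains the (i, i+3)/(i, i+4)
  helix-face distances are ≈6.5 Å, so face-geometry tests use a 7 Å
  cutoff while the reported maps keep the conventional 5 Å.

## Coarse bilayer and topology measures

Lipids (DOPE:DOPS:DOPC 5:3:2 by largest-remainder rounding) sit on a
jittered 8 Å lattice, split evenly between leaflets, each with a
phosphorus site at |z| ≈ 19 Å, a glycerol site at 16.5 Å, and 18 chain
carbons whose mean |z| decreases piecewise-linearly through anchor
points C5 ≈ 12.5 Å, C10 ≈ 7.5 Å, C16 ≈ 2.5 Å.  DOPS carries −1 e at
the P site.  A doxyl label can be placed on a fraction of lipids at
carbon 5/10/16 or the headgroup (2% matches the experimental doping;
attenuation *predictions* use fully labelled patches so that the
lateral label spacing is small against the PRE radius, emulating the
ensemble averaging over many labelled vesicles).

- **Surface fit**: least-squares plane through proximal-leaflet P atoms
  within 10 Å of any protein atom (error if fewer than 3); midplane
  from the two leaflets' mean P positions; normal oriented outward.
- **Tilt**: first principal component of smoothed CA positions
  (window-4 running mean over residues 6–25), oriented N→C; tilt is the
  angle between the axis and its in-plane projection, signed positive
  when the N-terminal end is deeper.  Constructed 0°/12° placements are
  recovered within 0.5° through the fitted surface and to numerical
  precision against the exact frame.
- **Depths**: SC centroid projection onto the normal, measured from the
  midplane, positive toward the proximal leaflet.
- **Contacts/energies**: lipid sites within 5.0 Å of the SC centroid;
  Lennard-Jones (σ, ε per site type, Lorentz–Berthelot) and Coulomb
  (f = 138.935 kJ nm mol⁻¹ e⁻², formal charges) truncated at 0.9 nm.
  Because the rigid lattice cannot relax around an inserted peptide,
  `pack_lipids_around` displaces clashing lipids laterally to a 4.5 Å
  closest approach before computing contacts or energies.
- **PRE**: r_eff = ⟨min-over-labels r⁻⁶⟩^(−1/6) per residue and
  A = 1/(1 + (r_eff/R_c)⁻⁶) with R_c = 13 Å; "broadened" means
  A < 0.5.  This is an effective-distance sigmoid, not
  Solomon–Bloembergen relaxation (correlation times are not modelled).

## Synthetic data and what passing tests mean

`generate_helical_ensemble` draws per-frame helix/coil residue states
from a two-state Markov chain with stationary probability h and mean
helical run length 8 (so the ≥4-run criterion is exercised
realistically); helical residues sample torsions N((−57, −47), 10°),
coil residues N((−120, +135), 35°).  `synthesize_shifts` back-calculates
ensemble-mean shifts for residues 6–25 (CA/CB/C, 60 rows) and adds
i.i.d. Gaussian noise (default 0.3 ppm), recorded in the σ column.
`place_peptide` constructs placements at an exact tilt and anchor
depth, parameterised by the reference topology values (12°, F4 at 8.9 Å).

The end-to-end recovery check synthesizes shifts from a 70%-helical
ensemble (0.3 ppm noise) and refines for 30 annealing cycles (18 ns
nominal per replica, 6 ns discard — a deliberate desk-scale reduction
of the full-scale 250 ns; block analysis shows the restrained helicity
is flat well before the discard horizon).  The refined ensemble
recovers the ensemble-mean helical basin weight almost exactly
(0.56 vs the generator's 0.60); the remaining gap to the 0.70 state
fraction is the run-length criterion plus the flat-bottom slack, and
sits inside the ±0.15 recovery tolerance.  What these tests show is
that the machinery — predictor, replica averaging, annealed MC,
analyses — is self-consistent with known ground truth.  What they do
not show is fidelity to real lipid-bound αS: the generator has no
membrane, no tertiary interactions beyond soft spheres, Gaussian noise
instead of spectrometer artefacts, and a predictor that shares its
functional family with the restraint.

## Numerical choices and limitations

- Coordinates are Å internally; dipoles reported in e·nm (÷10).
- kT at 278 K is 2.3114 kJ/mol (R = 0.0083144626 kJ mol⁻¹ K⁻¹).
- MC kernels are numba-compiled; fixed seeds give bit-reproducible
  trajectories within an environment.
- Degenerate inputs: single-frame ensembles are rejected where block
  statistics are required; an all-identical ensemble yields a
  single-bin FES with a warning; surface fits fail loudly when too few
  P atoms qualify; placement requests with tilt > 85° are refused (a
  steeper 30-residue helix would span the whole leaflet).
- The flat-patch bilayer ignores SUV curvature; PRE is an
  effective-distance model; membrane-coupled *sampling* is not
  performed (topology is analysed on constructed placements); and the
  all-atom force-field, explicit solvent, and real shift predictors are
  out of scope by design.
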