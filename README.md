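# memanchor

Coarse-grained refinement and membrane-topology analysis of the
α-synuclein membrane anchor (residues 1–30).

α-Synuclein binds synaptic-vesicle-like membranes through its
N-terminal ~30 residues, which fold into an amphipathic helix whose
tilt and insertion depth control how tightly the protein anchors to the
bilayer.  Experimentally this state is characterised by solid-state NMR
chemical shifts of the rigid, assigned region (residues 6–25) and by
paramagnetic relaxation enhancement (PRE) from doxyl spin labels placed
at chosen depths in the lipid tails.  `memanchor` provides a complete,
desk-scale computational counterpart of that workflow for structural
biologists who want to prototype or teach it end to end:

- a coarse torsion-space peptide model (5 sites/residue) with exact
  torsion ↔ Cartesian round-tripping;
- replica-averaged chemical-shift-restrained refinement: M = 4 replicas
  evolve by Metropolis Monte Carlo through 278–350 K annealing cycles
  while a flat-bottom harmonic penalises the deviation of their *mean*
  back-calculated shifts from the data,

  E = k · Σⱼ max(0, |δ̄ⱼ − δ_exp,j| − εⱼ)²,

  which enforces the NMR measurement as an ensemble average;
- free-energy surfaces F = −kT ln(n/n_max) on (CA-RMSD to the ideal
  helix, dipole moment) over residues 6–25, with basin detection;
- per-residue helix populations, RMSF, salt-bridge and hydrophobic
  contact occupancies (5.0 Å centroid cutoffs);
- a coarse DOPE:DOPS:DOPC (5:3:2) bilayer with depth-calibrated chain
  carbons, membrane-surface fitting, helix tilt and insertion depth,
  sidechain–lipid contacts and Lennard-Jones/Coulomb energies (0.9 nm
  cutoff), and PRE-attenuation prediction for doxyl labels at lipid
  carbons 5/10/16 or the headgroup;
- synthetic-data generators (ensembles of known helicity, noisy shift
  tables, placements at exact tilt/depth) so the whole pipeline is
  testable with known ground truth and no downloads.

The science and the numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Refine against synthetic shifts from a 70%-helical ensemble and compare
with an unrestrained control:

```python
from memanchor import alpha_synuclein_anchor, build_ideal_helix
from memanchor.analysis import helix_population, project_fes
from memanchor.sampler import (AnnealingSchedule, SamplerConfig,
                               run_replica_annealing, schedule_accounting)
from memanchor.synthetic import generate_helical_ensemble, synthesize_shifts

chain = alpha_synuclein_anchor()
truth, _ = generate_helical_ensemble(chain, 0.7, 400, seed=101)
table = synthesize_shifts(truth, noise_sd=0.3, seed=102)   # 60 rows, 6-25

print(schedule_accounting(AnnealingSchedule(n_cycles=417), n_replicas=4))
# {'cycle_ps': 600, 'total_ns_per_replica': 250.2, 'discarded_cycles': 84,
#  'frames_per_cycle_per_replica': 10, 'collected_frames_total': 13320}

sched = AnnealingSchedule(n_cycles=30, discard_ns=6.0)     # desk scale
res = run_replica_annealing(chain, sched, table,
                            SamplerConfig(seeds=(21, 22, 23, 24)))
print(len(res.ensemble))                                   # 800
print(round(helix_population(res.ensemble)[5:25].mean(), 3))
# 0.561  -- mean helicity of the assigned region, vs 0.70 planted

fes = project_fes(res.ensemble, build_ideal_helix(chain))
print(round(fes.bin_centers()[0][fes.basins[0]["bin"][0]], 2))
# 3.0    -- main-basin CA-RMSD (Angstrom); an unrestrained control run
#           puts its main basin near 4.8
```

The first line is the reference protocol's frame accounting, computed
from the schedule arithmetic alone (20 collected cycles x 10 frames x 4
replicas = 800 frames at desk scale).  The refinement then recovers the
planted helicity within the stochastic tolerance of the recovery test,
and the main free-energy basin moves to markedly lower helix RMSD than
the unrestrained control's.

A command-line interface mirrors the library:

```bash
memanchor synth ensemble --seed 3 --helicity 0.7 --frames 400 --out ens.pdb
memanchor synth shifts --ensemble ens.pdb --seed 4 --out shifts.tsv
memanchor refine --config cfg.yaml --shifts shifts.tsv --out refined.pdb
memanchor analyze --ensemble refined.pdb --out-dir results/
memanchor synth bilayer --seed 5 --n-lipids 128 --label C5 --out bl.pdb
memanchor topology --ensemble refined.pdb --bilayer bl.pdb --out topo.json
memanchor pre --ensemble refined.pdb --bilayer bl.pdb --label C5
```

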