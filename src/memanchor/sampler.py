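"""Four-replica annealed Metropolis sampling in torsion space.

The annealing schedule mirrors the reference replica-averaged refinement protocol: each
600 ps cycle holds 100 ps at 278 K, heats over 100 ps to 350 K, holds
100 ps at 350 K and cools back over 300 ps.  Conformations are collected
only from the low-temperature holds, after an initial discard horizon
(rounded up to whole cycles).  "ps" is a nominal bookkeeping unit mapped
to MC sweeps (``steps_per_ps``); one sweep proposes one single-angle
Gaussian move per residue per replica.

The four replicas never exchange; they couple only through the
replica-averaged chemical-shift restraint, which penalises deviations of
the across-replica mean of the predicted shifts from the target values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .chain import PeptideChain
from .descriptors import convergence_metrics
from .ensemble import Ensemble
from .geometry import Conformation
from .shifts import (ATOMS, ChemicalShiftTable, ReplicaRestraint,
                     ToyShiftPredictor)

R_GAS = _kernels.R_GAS


@dataclass
class TorsionPotential:
    """Torsion propensity: two attractive Gaussian wells (helical and
    extended) plus a nearest-neighbour helix-cooperativity term.

    Depths in kJ/mol, widths/centres in degrees.  The cooperativity term
    -coop_j * sum_i h_i h_{i+1}, with h the helical basin weight of width
    ``coop_sigma``, is the coarse analogue of the cooperative
    hydrogen-bond network that makes helix formation a run-forming
    transition; without it the sampler would satisfy ensemble-averaged
    restraints with isolated in-basin residues that never form helical
    runs.  The defaults leave an unrestrained chain at 278 K largely
    disordered (helix nucleation is penalised by the torsional entropy
    loss) while letting shift restraints tip the balance.
    """

    helix_center: tuple = (-57.0, -47.0)
    helix_depth: float = 5.5
    helix_sigma: float = 30.0
    extended_center: tuple = (-120.0, 130.0)
    extended_depth: float = 2.5
    extended_sigma: float = 40.0
    coop_j: float = 6.5
    coop_sigma: float = 30.0


@dataclass
class ExcludedVolume:
    """Soft-sphere centroid repulsion: E = k * sum max(0, d0 - r)^2.

    d0 = 4.0 Angstrom keeps the ideal helix (minimum non-local centroid
    separation 4.6 Angstrom) strain-free while penalising collapse.
    """

    d0: float = 4.0
    k: float = 2.0


@dataclass
class AnnealingSchedule:
    """Cycle structure of the annealed sampling (temperatures in K, nominal
    durations in ps)."""

    n_cycles: int
    t_low: float = 278.0
    t_high: float = 350.0
    segment_ps: tuple = (100, 100, 100, 300)   # hold-low, heat, hold-high, cool
    steps_per_ps: int = 10
    frame_interval_ps: int = 10
    discard_ns: float = 50.0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.t_low <= 0 or self.t_high <= 0:
            raise ValueError("temperatures must be positive")
        if any(s <= 0 for s in self.segment_ps):
            raise ValueError("segment durations must be positive")
        if self.segment_ps[0] % self.frame_interval_ps != 0:
            raise ValueError("frame interval must divide the hold-low "
                             "segment")

    @property
    def cycle_ps(self) -> int:
        return int(sum(self.segment_ps))

    @property
    def discarded_cycles(self) -> int:
        """Discard horizon rounded UP to whole cycles."""
        return math.ceil(self.discard_ns * 1000.0 / self.cycle_ps)

    def sweep_arrays(self):
        """Per-sweep (temperature, collect flag, cycle index) arrays."""
        spp = self.steps_per_ps
        seg = [int(s) * spp for s in self.segment_ps]
        cyc_sweeps = sum(seg)
        hold, heat, hhigh, cool = seg
        t_cycle = np.empty(cyc_sweeps)
        t_cycle[:hold] = self.t_low
        t_cycle[hold:hold + heat] = np.linspace(
            self.t_low, self.t_high, heat, endpoint=False)
        t_cycle[hold + heat:hold + heat + hhigh] = self.t_high
        t_cycle[hold + heat + hhigh:] = np.linspace(
            self.t_high, self.t_low, cool, endpoint=False)
        temps = np.tile(t_cycle, self.n_cycles)
        collect = np.zeros(cyc_sweeps * self.n_cycles, dtype=np.uint8)
        stride = self.frame_interval_ps * spp
        disc = self.discarded_cycles
        if disc >= self.n_cycles:
            raise ValueError("discard horizon exceeds the schedule")
        for c in range(disc, self.n_cycles):
            base = c * cyc_sweeps
            # collect at the end of each frame interval within hold-low
            for k in range(stride - 1, hold, stride):
                collect[base + k] = 1
        cycle_idx = np.repeat(np.arange(self.n_cycles), cyc_sweeps)
        return temps, collect, cycle_idx


def schedule_accounting(schedule: AnnealingSchedule,
                        n_replicas: int = 4) -> dict:
    """Pure schedule arithmetic (no sampling).

    collected_frames_total counts frames from all replicas: (n_cycles -
    discarded_cycles) * (hold_low_ps / frame_interval_ps) * n_replicas.
    """
    disc = schedule.discarded_cycles
    if disc >= schedule.n_cycles:
        raise ValueError("discard horizon exceeds the schedule")
    per_cycle = schedule.segment_ps[0] // schedule.frame_interval_ps
    return {
        "cycle_ps": schedule.cycle_ps,
        "total_ns_per_replica": schedule.n_cycles * schedule.cycle_ps / 1000,
        "discarded_cycles": disc,
        "frames_per_cycle_per_replica": per_cycle,
        "collected_frames_total":
            (schedule.n_cycles - disc) * per_cycle * n_replicas,
    }


@dataclass
class SamplerConfig:
    """Sampler parameters: per-replica seeds, move width, energy weights."""

    seeds: tuple = (11, 12, 13, 14)
    move_width_deg: float = 15.0
    adapt_moves: bool = True           # width adaptation during discard only
    w_torsion: float = 1.0
    w_excluded: float = 1.0
    torsion_potential: TorsionPotential = field(
        default_factory=TorsionPotential)
    excluded_volume: ExcludedVolume = field(default_factory=ExcludedVolume)
    restraint: ReplicaRestraint = field(default_factory=ReplicaRestraint)
    predictor: ToyShiftPredictor = field(default_factory=ToyShiftPredictor)

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replica seeds must be distinct")
        if self.move_width_deg <= 0:
            raise ValueError("move width must be positive")


@dataclass
class SamplingResult:
    ensemble: Ensemble
    acceptance: np.ndarray             # per sweep, pooled over replicas
    e_physical: np.ndarray             # (n_frames_per_point, M) at collection
    e_restraint: np.ndarray
    final_widths_deg: np.ndarray
    ledger: dict


def physical_energy(conf: Conformation, config: SamplerConfig | None = None,
                    membrane=None) -> float:
    """Coarse physical energy (kJ/mol): torsion propensity + soft-sphere
    excluded volume between sidechain centroids, optionally plus a
    membrane slab term for a placed conformation (see
    :func:`memanchor.membrane.slab_energy`)."""
    config = config or SamplerConfig()
    tp = config.torsion_potential
    phi = conf.torsions[:, 0].copy()
    psi = conf.torsions[:, 1]
    if np.isnan(phi[0]):
        phi[0] = tp.helix_center[0]
    e_tors = sum(
        _kernels.torsion_energy_residue(
            np.deg2rad(p), np.deg2rad(q),
            tp.helix_depth, np.deg2rad(tp.helix_sigma),
            tp.extended_depth, np.deg2rad(tp.extended_sigma),
            np.deg2rad(tp.helix_center[0]), np.deg2rad(tp.helix_center[1]),
            np.deg2rad(tp.extended_center[0]),
            np.deg2rad(tp.extended_center[1]))
        for p, q in zip(phi, psi))
    if tp.coop_j != 0.0:
        h = np.array([_kernels.gaussian_basin(
            np.deg2rad(p), np.deg2rad(q),
            np.deg2rad(tp.helix_center[0]), np.deg2rad(tp.helix_center[1]),
            np.deg2rad(tp.coop_sigma)) for p, q in zip(phi, psi)])
        e_tors -= tp.coop_j * float(np.sum(h[:-1] * h[1:]))
    ev = config.excluded_volume
    e_ev = _kernels.excluded_volume(
        np.ascontiguousarray(conf.sc), ev.d0, ev.k)
    e = config.w_torsion * e_tors + config.w_excluded * e_ev
    if membrane is not None:
        from .membrane import slab_energy
        e += slab_energy(conf, membrane)
    return float(e)


def _restraint_arrays(table, restraint, predictor, chain):
    """Flatten the shift table into kernel arrays (0-based residues)."""
    if table is None or restraint.k == 0.0:
        z = np.zeros(0)
        return z.astype(np.int64), z, z, z, z
    table.validate_against(chain)
    sel = table.df[table.df.atom.isin(restraint.nuclei)]
    if sel.empty:
        raise ValueError("shift table contains no restrained nuclei")
    res = sel["residue"].to_numpy(dtype=np.int64) - 1
    dh = np.array([predictor.delta_helix[a] for a in sel["atom"]])
    coil = np.array([predictor.coil[chain.sequence[r]][ATOMS.index(a)]
                     for r, a in zip(res, sel["atom"])])
    target = sel["shift"].to_numpy(dtype=float)
    eps = (sel["sigma"].to_numpy(dtype=float) if restraint.epsilon is None
           else np.full(len(sel), float(restraint.epsilon)))
    return res, dh, target, eps, coil


def _run_kernel(chain, config, temps, collect, cycle_idx, table,
                adapt_until, init_torsions=None):
    tp = config.torsion_potential
    ev = config.excluded_volume
    pred = config.predictor
    restraint = config.restraint
    M = restraint.n_replicas
    rng = np.random.default_rng(list(config.seeds))
    kernel_seed = int(rng.integers(2 ** 31))
    n = len(chain)
    if init_torsions is None:
        init = rng.uniform(-np.pi, np.pi, size=(M, n, 2))
    else:
        init = np.deg2rad(np.asarray(init_torsions, dtype=float))
        if init.shape != (M, n, 2):
            raise ValueError("initial torsions must be shaped (M, n, 2)")
    phi = np.ascontiguousarray(init[:, :, 0])
    psi = np.ascontiguousarray(init[:, :, 1])
    nuc_res, nuc_dh, nuc_target, nuc_eps, nuc_coil = _restraint_arrays(
        table, restraint, pred, chain)
    out = _kernels.mc_run(
        phi, psi, chain.sc_distance,
        tp.helix_depth, np.deg2rad(tp.helix_sigma),
        tp.extended_depth, np.deg2rad(tp.extended_sigma),
        np.deg2rad(tp.helix_center[0]), np.deg2rad(tp.helix_center[1]),
        np.deg2rad(tp.extended_center[0]), np.deg2rad(tp.extended_center[1]),
        config.w_torsion,
        tp.coop_j, np.deg2rad(tp.coop_sigma),
        ev.d0, ev.k, config.w_excluded,
        np.deg2rad(pred.sigma_deg),
        np.deg2rad(pred.center[0]), np.deg2rad(pred.center[1]),
        nuc_res, nuc_dh, nuc_target, nuc_eps, nuc_coil, restraint.k,
        temps, collect, adapt_until, np.deg2rad(config.move_width_deg),
        kernel_seed)
    return out


def _frames_to_ensemble(chain, frames_phi, frames_psi, cycle_of_point,
                        temp_of_point):
    """Pool per-collection-point replica frames into one Ensemble."""
    n_pts, M, n = frames_phi.shape
    tors = np.empty((n_pts * M, n, 2))
    tors[:, :, 0] = np.rad2deg(frames_phi).reshape(n_pts * M, n)
    tors[:, :, 1] = np.rad2deg(frames_psi).reshape(n_pts * M, n)
    coords = np.empty((n_pts * M, n, 5, 3))
    for f in range(n_pts * M):
        _kernels.build_chain(np.deg2rad(tors[f, :, 0]),
                             np.deg2rad(tors[f, :, 1]),
                             chain.sc_distance, coords[f])
    replica = np.tile(np.arange(M), n_pts)
    cycle = np.repeat(cycle_of_point, M)
    temperature = np.repeat(temp_of_point, M)
    return Ensemble(chain, coords, tors, replica, cycle, temperature)


def run_replica_annealing(chain: PeptideChain, schedule: AnnealingSchedule,
                          shift_table: ChemicalShiftTable | None,
                          config: SamplerConfig | None = None,
                          init_torsions=None) -> SamplingResult:
    """Run the annealed replica sampling.

    Replicas start from uniform-random torsions (distinct per-replica
    seeds) unless ``init_torsions`` (degrees, shape (M, n, 2)) is given.
    Frames are collected from hold-low segments after the discard horizon,
    every ``frame_interval_ps``, from all replicas.  Fully reproducible
    given the seeds.
    """
    config = config or SamplerConfig()
    temps, collect, cycle_idx = schedule.sweep_arrays()
    disc_sweeps = (schedule.discarded_cycles * schedule.cycle_ps
                   * schedule.steps_per_ps)
    adapt_until = disc_sweeps if config.adapt_moves else 0
    (frames_phi, frames_psi, e_phys, e_rest, acc,
     widths) = _run_kernel(chain, config, temps, collect, cycle_idx,
                           shift_table, adapt_until, init_torsions)
    pts = np.where(collect == 1)[0]
    ensemble = _frames_to_ensemble(chain, frames_phi, frames_psi,
                                   cycle_idx[pts], temps[pts])
    acct = schedule_accounting(schedule, config.restraint.n_replicas)
    ledger = dict(acct)
    ledger["frames_collected"] = len(ensemble)
    ledger["frames_discarded"] = (schedule.discarded_cycles
                                  * acct["frames_per_cycle_per_replica"]
                                  * config.restraint.n_replicas)
    if len(ensemble) != acct["collected_frames_total"]:
        raise RuntimeError("frame accounting mismatch")
    return SamplingResult(ensemble, acc, e_phys, e_rest,
                          np.rad2deg(widths), ledger)


def sample_fixed_temperature(chain: PeptideChain, n_sweeps: int,
                             temperature: float = 278.0,
                             config: SamplerConfig | None = None,
                             shift_table: ChemicalShiftTable | None = None,
                             burn_in: int = 0, collect_every: int = 5,
                             init_torsions=None) -> SamplingResult:
    """Constant-temperature MC (no annealing), e.g. for sampling-correctness
    checks against Boltzmann enumeration."""
    config = config or SamplerConfig()
    temps = np.full(n_sweeps, float(temperature))
    collect = np.zeros(n_sweeps, dtype=np.uint8)
    collect[burn_in + collect_every - 1::collect_every] = 1
    cycle_idx = np.zeros(n_sweeps, dtype=int)
    (frames_phi, frames_psi, e_phys, e_rest, acc,
     widths) = _run_kernel(chain, config, temps, collect, cycle_idx,
                           shift_table, 0, init_torsions)
    pts = np.where(collect == 1)[0]
    ensemble = _frames_to_ensemble(chain, frames_phi, frames_psi,
                                   np.zeros(len(pts), dtype=int), temps[pts])
    ledger = {"n_sweeps": n_sweeps, "frames_collected": len(ensemble)}
    return SamplingResult(ensemble, acc, e_phys, e_rest,
                          np.rad2deg(widths), ledger)


#: Convergence thresholds: running-mean CA RMSD and dihedral RMSD must
#: settle below absolute values; Rg drift is absolute (Angstrom), SASA
#: drift relative.
DEFAULT_THRESHOLDS = {
    "rmsd_running_mean": 0.5,    # Angstrom, last block
    "dihedral_rmsd": 15.0,       # degrees, last block
    "radius_of_gyration": 0.5,   # Angstrom, |second half - first half|
    "sasa": 0.05,                # relative drift
}


def convergence_check(ensemble_or_result, thresholds: dict | None = None,
                      n_blocks: int = 10) -> dict:
    """Pass/fail per convergence metric from block statistics.

    The running-mean-structure RMSD and dihedral RMSD must fall below
    their thresholds in the final block; Rg and SASA must show a
    first-half/second-half drift below theirs.
    """
    ensemble = getattr(ensemble_or_result, "ensemble", ensemble_or_result)
    thr = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    metrics = convergence_metrics(ensemble, n_blocks=n_blocks)
    out = {}
    for name, series in metrics.items():
        half = len(series) // 2
        if name in ("rmsd_running_mean", "dihedral_rmsd"):
            value = float(series[-1])
        else:
            drift = abs(series[half:].mean() - series[:half].mean())
            value = (float(drift / series.mean()) if name == "sasa"
                     else float(drift))
        out[name] = {"value": value, "threshold": thr[name],
                     "passed": bool(value <= thr[name]), "series": series}
    return out
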