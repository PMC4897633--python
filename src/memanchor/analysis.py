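"""Conformational-ensemble analyses.

Free-energy surface on (CA-RMSD to the ideal helix, dipole moment),
per-residue helix population, RMSF, salt-bridge occupancies and
hydrophobic contact maps.

Free-energy convention: F = -kT ln(n / n_max) >= 0, so the most populated
bin sits at F = 0 and less populated regions are positive.  (Colour
scales that instead place the most populated state at the most negative
value are the same surface with the sign flipped.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .descriptors import DEFAULT_RANGE, dipole_moment, rmsd_ca
from .ensemble import Ensemble
from .geometry import Conformation
from ._kernels import R_GAS

#: Dihedral window counted as helical (degrees): a coarse stand-in for a
#: hydrogen-bond based secondary-structure assignment, paired with a
#: minimum run length of 4 consecutive in-window residues.
HELIX_PHI_WINDOW = (-100.0, -30.0)
HELIX_PSI_WINDOW = (-77.0, -17.0)
MIN_HELIX_RUN = 4


@dataclass
class FESGrid:
    """2-D free-energy grid over (RMSD / Angstrom, dipole / e*nm)."""

    rmsd_edges: np.ndarray
    dipole_edges: np.ndarray
    counts: np.ndarray          # (n_rmsd_bins, n_dipole_bins)
    free_energy: np.ndarray     # kJ/mol; NaN on unoccupied bins
    temperature: float
    basins: list = field(default_factory=list)

    @property
    def kt(self) -> float:
        return R_GAS * self.temperature

    def bin_centers(self):
        return (0.5 * (self.rmsd_edges[:-1] + self.rmsd_edges[1:]),
                0.5 * (self.dipole_edges[:-1] + self.dipole_edges[1:]))


@dataclass
class ContactMap:
    """Symmetric pairwise occupancy map over a residue subset."""

    residue_i: np.ndarray       # 1-based
    residue_j: np.ndarray
    occupancy: np.ndarray       # in [0, 1]
    kind: str                   # "salt-bridge" | "hydrophobic"

    def get(self, i: int, j: int) -> float:
        sel = (((self.residue_i == i) & (self.residue_j == j))
               | ((self.residue_i == j) & (self.residue_j == i)))
        if not sel.any():
            raise KeyError((i, j))
        return float(self.occupancy[sel][0])

    def pairs(self) -> list:
        return list(zip(self.residue_i.tolist(), self.residue_j.tolist()))

    def as_matrix(self, n: int) -> np.ndarray:
        m = np.zeros((n, n))
        for i, j, o in zip(self.residue_i, self.residue_j, self.occupancy):
            m[i - 1, j - 1] = o
            m[j - 1, i - 1] = o
        return m


def _find_basins(free_energy, counts):
    """Local minima of F (8-neighbourhood) with watershed populations.

    Every occupied bin is assigned to the local minimum reached by
    steepest descent on F; a basin's population is the count share of its
    drainage area.
    """
    nb1, nb2 = free_energy.shape
    total = counts.sum()

    def neighbours(a, b):
        for da in (-1, 0, 1):
            for db in (-1, 0, 1):
                if da == db == 0:
                    continue
                x, y = a + da, b + db
                if 0 <= x < nb1 and 0 <= y < nb2 and \
                        np.isfinite(free_energy[x, y]):
                    yield x, y

    sink = {}

    def descend(a, b):
        # ties broken lexicographically so plateau walks terminate
        path = []
        while (a, b) not in sink:
            path.append((a, b))
            best = min(list(neighbours(a, b)) + [(a, b)],
                       key=lambda xy: (free_energy[xy], xy))
            if best == (a, b):
                sink.update(dict.fromkeys(path, (a, b)))
                return (a, b)
            a, b = best
        sink.update(dict.fromkeys(path, sink[(a, b)]))
        return sink[(a, b)]

    pops = {}
    for a in range(nb1):
        for b in range(nb2):
            if np.isfinite(free_energy[a, b]):
                s = descend(a, b)
                pops[s] = pops.get(s, 0.0) + counts[a, b]
    basins = [{"bin": s, "free_energy": float(free_energy[s]),
               "population": float(p / total)} for s, p in pops.items()]
    basins.sort(key=lambda d: d["free_energy"])
    return basins


def project_fes(ensemble: Ensemble, ref_helix: Conformation,
                residue_range=DEFAULT_RANGE, bins: int = 40,
                temperature: float = 278.0) -> FESGrid:
    """Project the ensemble onto (CA-RMSD to the ideal helix, dipole moment)
    over the given residue range and histogram into a free-energy grid.

    Grid edges span the observed coordinate ranges padded by 5%.  With all
    frames at identical coordinates the grid degenerates to a single
    occupied bin (a warning is raised).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    r = np.array([rmsd_ca(ensemble[f], ref_helix, residue_range)
                  for f in range(len(ensemble))])
    d = np.array([dipole_moment(ensemble[f], residue_range)
                  for f in range(len(ensemble))])

    def padded_edges(x, nb):
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-9:
            warnings.warn("degenerate coordinate range; single-bin grid")
            return np.array([lo - 0.5, hi + 0.5]), 1
        pad = 0.05 * (hi - lo)
        return np.linspace(lo - pad, hi + pad, nb + 1), nb

    r_edges, _ = padded_edges(r, bins)
    d_edges, _ = padded_edges(d, bins)
    counts, r_edges, d_edges = np.histogram2d(r, d, bins=[r_edges, d_edges])
    free = np.full_like(counts, np.nan)
    occ = counts > 0
    kt = R_GAS * temperature
    free[occ] = -kt * np.log(counts[occ] / counts.max())
    grid = FESGrid(r_edges, d_edges, counts, free, temperature)
    grid.basins = _find_basins(free, counts)
    return grid


def helical_flags(ensemble: Ensemble) -> np.ndarray:
    """(F, n) boolean: residue in the helical dihedral window AND in a run
    of >= 4 consecutive in-window residues.

    phi of residue 1 does not affect the geometry and may be NaN, so
    residue 1 is assessed on psi alone.
    """
    phi = ensemble.torsions[:, :, 0]
    psi = ensemble.torsions[:, :, 1]
    in_phi = (phi >= HELIX_PHI_WINDOW[0]) & (phi <= HELIX_PHI_WINDOW[1])
    in_phi[:, 0] = True
    in_psi = (psi >= HELIX_PSI_WINDOW[0]) & (psi <= HELIX_PSI_WINDOW[1])
    window = in_phi & in_psi
    flags = np.zeros_like(window)
    F, n = window.shape
    for f in range(F):
        run = 0
        for i in range(n):
            if window[f, i]:
                run += 1
                if run >= MIN_HELIX_RUN:
                    flags[f, i - run + 1:i + 1] = True
            else:
                run = 0
    return flags


def helix_population(ensemble: Ensemble) -> np.ndarray:
    """Per-residue fraction of frames assigned helical."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    return helical_flags(ensemble).mean(axis=0)


def rmsf(ensemble: Ensemble, residue_range=DEFAULT_RANGE,
         n_iter: int = 3) -> np.ndarray:
    """Per-residue CA RMSF (Angstrom) about the ensemble mean structure.

    Frames are least-squares superposed on the iteratively refined mean
    structure using the CA atoms of ``residue_range``; the RMSF is
    reported for all residues.
    """
    from .geometry import superpose
    if len(ensemble) < 2:
        raise ValueError("need at least 2 frames")
    lo, hi = residue_range
    sl = slice(lo - 1, hi)
    ca = ensemble.coords[:, :, 1, :].copy()
    ref = ca[0, sl]
    for _ in range(n_iter):
        for f in range(ca.shape[0]):
            _, R, t = superpose(ca[f, sl], ref)
            ca[f] = ca[f] @ R.T + t
        ref = ca[:, sl].mean(axis=0)
    mean = ca.mean(axis=0)
    return np.sqrt(np.mean(np.sum((ca - mean) ** 2, axis=2), axis=0))


def _pair_occupancy(ensemble, pairs, use_n_atom_for, cutoff):
    """Occupancy of centroid-distance contacts for 1-based residue pairs.

    ``use_n_atom_for`` lists residues whose charge centre is the backbone
    N atom (the N-terminal amine) rather than the sidechain centroid.
    """
    sc = ensemble.coords[:, :, 4, :]
    natom = ensemble.coords[:, :, 0, :]
    occ = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        pi = natom[:, i - 1] if i in use_n_atom_for else sc[:, i - 1]
        pj = natom[:, j - 1] if j in use_n_atom_for else sc[:, j - 1]
        dist = np.linalg.norm(pi - pj, axis=1)
        occ[k] = float((dist <= cutoff).mean())
    return occ


def salt_bridge_occupancy(ensemble: Ensemble, cutoff: float = 5.0,
                          min_separation: int = 2) -> ContactMap:
    """Occupancy of (positive, negative) residue contacts.

    A contact counts when the charged-group centres lie within ``cutoff``
    (default 5.0 Angstrom).  In the coarse model the charged-group centre
    of mass is the sidechain centroid; the N-terminal amine (residue 1, if
    positive) uses the backbone N atom.  Pairs closer in sequence than
    ``min_separation`` are not reported.
    """
    chain = ensemble.chain
    pos = chain.positive_residues()
    if chain.nterm_positive and 1 not in pos:
        pos = [1] + pos
    neg = chain.negative_residues()
    if not pos or not neg:
        raise ValueError("chain must have both positive and negative "
                         "residues")
    pairs = [(i, j) for i in pos for j in neg
             if abs(i - j) >= min_separation]
    occ = _pair_occupancy(ensemble, pairs, {1} if chain.nterm_positive
                          else set(), cutoff)
    ri = np.array([p[0] for p in pairs])
    rj = np.array([p[1] for p in pairs])
    return ContactMap(ri, rj, occ, "salt-bridge")


def hydrophobic_contact_map(ensemble: Ensemble, cutoff: float = 5.0,
                            min_separation: int = 2) -> ContactMap:
    """Occupancy of hydrophobic sidechain-centroid contacts (pairs with
    |i - j| >= 2, cutoff 5.0 Angstrom by default)."""
    hyd = ensemble.chain.hydrophobic_residues()
    pairs = [(i, j) for a, i in enumerate(hyd) for j in hyd[a + 1:]
             if j - i >= min_separation]
    occ = _pair_occupancy(ensemble, pairs, set(), cutoff)
    ri = np.array([p[0] for p in pairs])
    rj = np.array([p[1] for p in pairs])
    return ContactMap(ri, rj, occ, "hydrophobic")


def plot_fes(grid: FESGrid, ax=None, cmap: str = "Blues_r"):
    """Filled-contour plot of the free-energy surface (optional helper)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    rc, dc = grid.bin_centers()
    f = np.where(np.isfinite(grid.free_energy), grid.free_energy, np.nan)
    pc = ax.pcolormesh(rc, dc, f.T, cmap=cmap)
    ax.set_xlabel(r"C$\alpha$ RMSD from ideal helix ($\AA$)")
    ax.set_ylabel(r"dipole moment (e$\cdot$nm)")
    plt.colorbar(pc, ax=ax, label="F (kJ/mol)")
    return ax
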