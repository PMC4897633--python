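"""Scalar structural descriptors.

These are the projection coordinates of the free-energy surface (CA-RMSD
to the ideal helix and the dipole moment of the anchor region) and the
four convergence metrics of the refinement (RMSD of the running mean
structure, backbone dihedral RMSD, radius of gyration, solvent accessible
surface area).

Units: coordinates Angstrom; dipole moments e*nm (1 e*nm = 10 e*Angstrom);
SASA Angstrom^2.
"""

from __future__ import annotations

import numpy as np

from .geometry import Conformation, kabsch_rmsd, superpose

#: Default residue window for projection coordinates: the ssNMR-assigned
#: region 6-25; the flexible termini (1-5, 26-30) are excluded.
DEFAULT_RANGE = (6, 25)


def _range_slice(residue_range, n):
    lo, hi = residue_range
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"invalid residue range {residue_range} for n={n}")
    if hi - lo + 1 < 3:
        raise ValueError("residue range must contain at least 3 residues")
    return slice(lo - 1, hi)


def rmsd_ca(conf: Conformation, ref: Conformation,
            residue_range=DEFAULT_RANGE) -> float:
    """CA RMSD (Angstrom) after optimal superposition on the same range.

    1-based inclusive residue range; default is the assigned region 6-25.
    """
    sl = _range_slice(residue_range, conf.n_residues)
    return kabsch_rmsd(conf.ca[sl], ref.ca[sl])


def dipole_from_point_charges(positions: np.ndarray, charges: np.ndarray,
                              origin: np.ndarray | None = None) -> float:
    """|sum q_i (r_i - origin)| in e*nm for positions in Angstrom.

    Defaults the origin to the unweighted centroid of the positions.  For
    a net-neutral charge set the result is origin-independent.
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if positions.shape[0] != charges.shape[0]:
        raise ValueError("positions and charges length mismatch")
    if origin is None:
        origin = positions.mean(axis=0)
    mu = ((positions - origin) * charges[:, None]).sum(axis=0)
    return float(np.linalg.norm(mu)) / 10.0


def dipole_moment(conf: Conformation, residue_range=DEFAULT_RANGE,
                  charges: np.ndarray | None = None,
                  origin: np.ndarray | None = None) -> float:
    """Dipole moment magnitude (e*nm) of the selected residues.

    charges: optional (n_residues, 5) array in e; defaults to formal
    charges (+1/-1 on charged sidechain centroids, +1 on the N-terminal
    amine).  The origin defaults to the centroid of the selected sites;
    the anchor-region selection is not net neutral, so the origin
    convention matters and is configurable.
    """
    sl = _range_slice(residue_range, conf.n_residues)
    if charges is None:
        charges = conf.chain.formal_charges()
    charges = np.asarray(charges, dtype=float)
    if charges.shape != (conf.n_residues, 5):
        raise ValueError("charges must be shaped (n_residues, 5)")
    pos = conf.coords[sl].reshape(-1, 3)
    q = charges[sl].reshape(-1)
    return dipole_from_point_charges(pos, q, origin=origin)


def radius_of_gyration(coords: np.ndarray,
                       masses: np.ndarray | None = None) -> float:
    """Rg = sqrt(sum m |r - com|^2 / sum m); unit masses by default."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    com = (coords * masses[:, None]).sum(0) / masses.sum()
    d2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt((masses * d2).sum() / masses.sum()))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_points: int = 960) -> float:
    """Shrake-Rupley solvent accessible surface area (Angstrom^2).

    Sphere-point sampling with ``n_points`` test points per atom.  Atoms
    with zero radius (e.g. the glycine centroid, which coincides with CA)
    are skipped.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    keep = radii > 0.0
    coords = coords[keep]
    radii = radii[keep]
    n = coords.shape[0]
    sphere = _fibonacci_sphere(n_points)
    ext = radii + probe
    total = 0.0
    # pairwise distances for neighbour pruning
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        neigh = np.where((d[i] < ext[i] + ext) & (np.arange(n) != i))[0]
        pts = coords[i] + ext[i] * sphere
        if neigh.size:
            dd = np.linalg.norm(pts[:, None, :] - coords[neigh][None, :, :],
                                axis=-1)
            buried = (dd < ext[neigh][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * ext[i] ** 2 * frac
    return float(total)


def sasa_conformation(conf: Conformation, probe: float = 1.4,
                      n_points: int = 960) -> float:
    """SASA of a coarse conformation with the documented atom radii."""
    return sasa(conf.flat_coords(), conf.chain.atom_radii().reshape(-1),
                probe=probe, n_points=n_points)


def circular_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMS of circular differences between two angle arrays (degrees)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = (a - b + 180.0) % 360.0 - 180.0
    d = d[np.isfinite(d)]
    return float(np.sqrt(np.mean(d ** 2)))


def _resultant(angles_deg: np.ndarray, axis=0) -> np.ndarray:
    """Mean resultant vector of angles: stack of (mean cos, mean sin).

    For concentrated angle distributions the vector difference between two
    resultants, in radians, approximates the circular difference of their
    mean angles; for diffuse distributions it decays gracefully to zero
    instead of pointing in an arbitrary direction.
    """
    rad = np.deg2rad(angles_deg)
    return np.stack([np.nanmean(np.cos(rad), axis=axis),
                     np.nanmean(np.sin(rad), axis=axis)], axis=-1)


def convergence_metrics(ensemble, n_blocks: int = 10,
                        sasa_frames_per_block: int = 5,
                        sasa_points: int = 240) -> dict:
    """Block time series of the four convergence metrics.

    The ensemble is split into ``n_blocks`` contiguous blocks (frame
    order = sampling order).  Reported per block b (1-based):

    - ``rmsd_running_mean``: CA RMSD between the cumulative mean structure
      after block b and after block b-1 (first entry compares block 1's
      mean to the first frame); frames are superposed on the first frame
      before averaging.
    - ``dihedral_rmsd``: RMS drift (reported in degrees) of the
      per-torsion mean resultant vectors between the cumulative ensemble
      after block b and after block b-1; equals the circular RMSD of the
      mean dihedrals for well-ordered ensembles and decays to zero for
      stationary disordered ones.
    - ``radius_of_gyration``: block mean Rg over all coarse sites.
    - ``sasa``: block mean SASA, estimated on at most
      ``sasa_frames_per_block`` evenly spaced frames per block with
      ``sasa_points`` sphere points (SASA is the costliest metric).
    """
    n_frames = len(ensemble)
    if n_frames < 2:
        raise ValueError("need at least 2 frames for block statistics")
    n_blocks = min(n_blocks, n_frames)
    bounds = np.linspace(0, n_frames, n_blocks + 1).astype(int)

    ca0 = ensemble.coords[0, :, 1, :]
    ca_sup = np.empty_like(ensemble.coords[:, :, 1, :])
    for f in range(n_frames):
        ca_sup[f], _, _ = superpose(ensemble.coords[f, :, 1, :], ca0)

    radii = ensemble.chain.atom_radii().reshape(-1)
    rmsd_run, dih, rg, sa = [], [], [], []
    prev_mean = ca0
    prev_res = _resultant(ensemble.torsions[:1], axis=0)
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        cum_mean = ca_sup[:hi].mean(axis=0)
        rmsd_run.append(kabsch_rmsd(cum_mean, prev_mean))
        cum_res = _resultant(ensemble.torsions[:hi], axis=0)
        diff = cum_res - prev_res
        dih.append(np.rad2deg(np.sqrt(np.nanmean(
            np.sum(diff ** 2, axis=-1)))))
        rg.append(np.mean([radius_of_gyration(ensemble.coords[f])
                           for f in range(lo, hi)]))
        pick = np.linspace(lo, hi - 1,
                           min(sasa_frames_per_block, hi - lo)).astype(int)
        sa.append(np.mean([sasa(ensemble.coords[f].reshape(-1, 3), radii,
                                n_points=sasa_points) for f in pick]))
        prev_mean = cum_mean
        prev_res = cum_res
    return {
        "rmsd_running_mean": np.array(rmsd_run),
        "dihedral_rmsd": np.array(dih),
        "radius_of_gyration": np.array(rg),
        "sasa": np.array(sa),
    }
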