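"""Torsion <-> Cartesian geometry for the coarse peptide model.

A :class:`Conformation` couples a :class:`~memanchor.chain.PeptideChain`
with per-residue (phi, psi) torsions (degrees; omega is fixed trans) and
the Cartesian coordinates (Angstrom) they generate under the fixed
internal geometry of the coarse backbone.

The phi angle of residue 1 is geometrically undefined (no preceding
carbonyl carbon); the builder ignores it and torsion extraction reports
it as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels
from .chain import PeptideChain

IDEAL_HELIX_PHI = -57.0
IDEAL_HELIX_PSI = -47.0


@dataclass
class Conformation:
    """A single coarse-model structure.

    coords has shape (n_residues, 5, 3) over atoms N, CA, C, O, SC.
    torsions has shape (n_residues, 2) in degrees; torsions[0, 0] may be
    NaN if the conformation was derived from coordinates.
    """

    chain: PeptideChain
    torsions: np.ndarray
    coords: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.chain)

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, 1, :]

    @property
    def sc(self) -> np.ndarray:
        return self.coords[:, 4, :]

    def flat_coords(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Conformation":
        """Rigidly moved copy (torsions are unchanged by construction)."""
        xyz = self.coords.reshape(-1, 3)
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        return Conformation(self.chain, self.torsions.copy(),
                            xyz.reshape(self.coords.shape))

    def copy(self) -> "Conformation":
        return Conformation(self.chain, self.torsions.copy(),
                            self.coords.copy())


def torsions_to_cartesian(torsions: np.ndarray,
                          chain: PeptideChain) -> Conformation:
    """Build a conformation from per-residue (phi, psi) torsions (degrees).

    Raises ValueError on a torsion-count mismatch.
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (len(chain), 2):
        raise ValueError(
            f"expected torsions of shape {(len(chain), 2)}, "
            f"got {torsions.shape}")
    phi = np.deg2rad(np.nan_to_num(torsions[:, 0], nan=-57.0))
    psi = np.deg2rad(torsions[:, 1])
    coords = np.empty((len(chain), 5, 3))
    _kernels.build_chain(phi, psi, chain.sc_distance, coords)
    return Conformation(chain, torsions.copy(), coords)


def torsions_from_cartesian(coords: np.ndarray) -> np.ndarray:
    """Extract (phi, psi) in degrees from (n, 5, 3) coarse coordinates.

    phi of residue 1 is NaN.  Rigid motions of the coordinates leave the
    result unchanged.
    """
    coords = np.ascontiguousarray(coords, dtype=float)
    n = coords.shape[0]
    phi = np.empty(n)
    psi = np.empty(n)
    _kernels.extract_torsions(coords, phi, psi)
    out = np.stack([np.rad2deg(phi), np.rad2deg(psi)], axis=1)
    out[0, 0] = np.nan
    return out


def conformation_from_coords(chain: PeptideChain,
                             coords: np.ndarray) -> Conformation:
    """Wrap raw coordinates, recovering torsions from the geometry."""
    return Conformation(chain, torsions_from_cartesian(coords),
                        np.asarray(coords, dtype=float).copy())


def build_ideal_helix(chain: PeptideChain) -> Conformation:
    """Canonical alpha-helix: every residue at (phi, psi) = (-57, -47) deg."""
    if len(chain) < 4:
        raise ValueError("need at least 4 residues to build a helix")
    torsions = np.tile([IDEAL_HELIX_PHI, IDEAL_HELIX_PSI], (len(chain), 1))
    return torsions_to_cartesian(torsions, chain)


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of two (k, 3) point sets.

    Returns (moved_mobile, rotation_matrix, translation) such that
    moved = mobile @ R.T + t minimises the RMSD to target.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    return mobile @ R.T + t, R, t


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of two (k, 3) point sets after optimal superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("need two equal point sets with >= 3 points")
    moved, _, _ = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
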