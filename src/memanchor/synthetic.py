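"""Synthetic-data generators with known ground truth.

These emulate the study's inputs — partially helical peptide ensembles,
coarse mixed bilayers, peptide placements at a chosen tilt and insertion
depth, and noisy chemical-shift tables — so that every stage of the
pipeline can be exercised and validated without any experimental data.
Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from .chain import AS1_30, PeptideChain
from .ensemble import Ensemble
from .geometry import Conformation, torsions_to_cartesian
from .membrane import (BilayerModel, LIPID_SPECIES, Z_GLYCEROL,
                       Z_PHOSPHORUS, carbon_depth_profile, helix_axis)
from .shifts import ATOMS, ChemicalShiftTable, ToyShiftPredictor

#: Torsion scatter (deg) around the canonical helix for helical residues.
HELIX_TORSION_SD = 10.0
#: Coil torsions: broad scatter around the extended/polyproline region.
COIL_CENTER = (-120.0, 135.0)
COIL_TORSION_SD = 35.0
#: Mean helical run length of the 2-state Markov chain along the sequence.
MEAN_HELIX_RUN = 8.0


@dataclass
class GeneratorSpec:
    """Bundle of generator parameters (seed is mandatory)."""

    seed: int
    sequence: str = AS1_30
    helical_fraction: float = 0.7
    n_frames: int = 500
    noise_sd_ppm: float = 0.3
    tilt_deg: float = 12.0
    anchor_depth: float = 8.9
    anchor_residue: int = 4
    composition: tuple = (5, 3, 2)
    n_lipids: int = 128

    def __post_init__(self):
        if not 0.0 <= self.helical_fraction <= 1.0:
            raise ValueError("helical fraction must be in [0, 1]")
        if any(c <= 0 for c in self.composition):
            raise ValueError("composition ratio must be positive")


def _markov_states(rng, n, h, mean_run):
    """2-state (helix/coil) Markov chain with stationary P(H) = h."""
    if h >= 1.0:
        return np.ones(n, dtype=bool)
    if h <= 0.0:
        return np.zeros(n, dtype=bool)
    p_hc = 1.0 / mean_run
    p_ch = min(1.0, h * p_hc / (1.0 - h))
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < h
    for i in range(1, n):
        if states[i - 1]:
            states[i] = rng.random() >= p_hc
        else:
            states[i] = rng.random() < p_ch
    return states


def generate_helical_ensemble(chain: PeptideChain, helical_fraction: float,
                              n_frames: int, seed: int,
                              mean_run: float = MEAN_HELIX_RUN):
    """Ensemble with per-residue helicity ~ ``helical_fraction``.

    Per frame, each residue is helical with the target probability,
    correlated along the sequence by a 2-state Markov chain with mean
    helical run length ``mean_run`` (so the >=4-run helix criterion is
    exercised realistically).  Helical residues draw torsions from
    N((-57, -47), 10 deg); coil residues from a broad distribution around
    the extended region.  Returns (ensemble, states) where states is the
    (n_frames, n_residues) boolean ground truth.
    """
    if not 0.0 <= helical_fraction <= 1.0:
        raise ValueError("helical fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(chain)
    states = np.empty((n_frames, n), dtype=bool)
    torsions = np.empty((n_frames, n, 2))
    for f in range(n_frames):
        st = _markov_states(rng, n, helical_fraction, mean_run)
        states[f] = st
        t = np.empty((n, 2))
        t[st] = (np.array([-57.0, -47.0])
                 + rng.normal(0.0, HELIX_TORSION_SD, size=(int(st.sum()), 2)))
        t[~st] = (np.array(COIL_CENTER)
                  + rng.normal(0.0, COIL_TORSION_SD,
                               size=(int((~st).sum()), 2)))
        torsions[f] = (t + 180.0) % 360.0 - 180.0
    confs = [torsions_to_cartesian(torsions[f], chain)
             for f in range(n_frames)]
    return Ensemble.from_conformations(confs), states


def generate_two_state_ensemble(chain: PeptideChain, p_helix: float,
                                n_frames: int, seed: int):
    """Frame-level two-state ensemble: each frame is entirely helical with
    probability ``p_helix``, otherwise entirely coil.  Ground truth per
    frame is returned alongside; useful for planting two FES basins."""
    rng = np.random.default_rng(seed)
    helical = rng.random(n_frames) < p_helix
    n = len(chain)
    torsions = np.empty((n_frames, n, 2))
    for f in range(n_frames):
        if helical[f]:
            t = (np.array([-57.0, -47.0])
                 + rng.normal(0.0, 5.0, size=(n, 2)))
        else:
            t = (np.array(COIL_CENTER)
                 + rng.normal(0.0, 20.0, size=(n, 2)))
        torsions[f] = (t + 180.0) % 360.0 - 180.0
    confs = [torsions_to_cartesian(torsions[f], chain)
             for f in range(n_frames)]
    return Ensemble.from_conformations(confs), helical


def build_bilayer(n_lipids: int, ratio=(5, 3, 2), seed: int = 0,
                  label=None, label_fraction: float = 0.02,
                  spacing: float = 8.0, xy_jitter: float = 1.0,
                  z_jitter: float = 0.3) -> BilayerModel:
    """Coarse flat bilayer patch at the requested molar ratio.

    Lipids sit on a jittered square lattice, split evenly between the two
    leaflets.  Species counts follow largest-remainder rounding of the
    ratio.  ``label`` places doxyl sites on a ``label_fraction`` of lipids
    at chain carbon 5/10/16 or at the headgroup ('headgroup'); labelled
    lipids are spread evenly through the (shuffled) lipid list so both
    leaflets are covered.  Deterministic per seed.
    """
    if n_lipids < 8:
        raise ValueError("need at least 8 lipids")
    if n_lipids % 2:
        raise ValueError("n_lipids must split evenly across leaflets")
    rng = np.random.default_rng(seed)
    ratio = np.asarray(ratio, dtype=float)
    if (ratio <= 0).any():
        raise ValueError("ratio entries must be positive")
    # largest-remainder apportionment
    quota = ratio / ratio.sum() * n_lipids
    counts = np.floor(quota).astype(int)
    rem = n_lipids - counts.sum()
    for idx in np.argsort(quota - np.floor(quota))[::-1][:rem]:
        counts[idx] += 1
    species = np.repeat(np.array(LIPID_SPECIES), counts)
    rng.shuffle(species)

    per_leaflet = n_lipids // 2
    ncol = int(np.ceil(np.sqrt(per_leaflet)))
    nrow = int(np.ceil(per_leaflet / ncol))
    xy0 = np.array([[c * spacing, r * spacing]
                    for r in range(nrow) for c in range(ncol)])
    xy0 = xy0[:per_leaflet] - xy0[:per_leaflet].mean(axis=0)
    box_xy = ((ncol - 1) * spacing + 2 * spacing,
              (nrow - 1) * spacing + 2 * spacing)

    leaflet = np.concatenate([np.ones(per_leaflet, dtype=int),
                              -np.ones(per_leaflet, dtype=int)])
    xy = np.vstack([xy0, xy0]) + rng.uniform(-xy_jitter, xy_jitter,
                                             size=(n_lipids, 2))
    zsign = leaflet.astype(float)
    head_p = np.column_stack([
        xy, zsign * (Z_PHOSPHORUS + rng.normal(0, z_jitter, n_lipids))])
    glycerol = np.column_stack([
        xy, zsign * (Z_GLYCEROL + rng.normal(0, z_jitter, n_lipids))])
    zprof = carbon_depth_profile()
    carbons = np.empty((n_lipids, 18, 3))
    carbons[:, :, 0] = xy[:, [0]] + rng.normal(0, z_jitter, (n_lipids, 18))
    carbons[:, :, 1] = xy[:, [1]] + rng.normal(0, z_jitter, (n_lipids, 18))
    carbons[:, :, 2] = (zsign[:, None]
                        * (zprof[None, :]
                           + rng.normal(0, 0.5 * z_jitter, (n_lipids, 18))))

    labelled = np.zeros(n_lipids, dtype=bool)
    if label is not None:
        n_label = int(round(label_fraction * n_lipids))
        if n_label < 1:
            raise ValueError("label fraction rounds to zero lipids")
        stride = n_lipids / n_label
        labelled[(np.arange(n_label) * stride).astype(int)] = True
    return BilayerModel(species, leaflet, head_p, glycerol, carbons,
                        labelled, label if label is not None else None,
                        box_xy)


def place_peptide(conf: Conformation, bilayer: BilayerModel,
                  tilt_deg: float, anchor_depth: float, anchor_residue: int,
                  residue_range=(6, 25), roll_deg: float = 0.0,
                  clash_distance: float = 1.5) -> Conformation:
    """Rigidly place a conformation in the bilayer at a requested tilt and
    anchor-residue insertion depth.

    The helix axis (smoothed-CA fit over ``residue_range``, oriented N->C)
    is rotated to make the requested angle with the membrane plane with
    the N-terminal end deeper, optionally rolled about itself by
    ``roll_deg``, and the peptide is translated so the anchor residue's
    sidechain centroid sits ``anchor_depth`` Angstrom above the midplane.
    Raises for tilt outside [0, 85] degrees (a steeper 30-residue helix
    would span the whole leaflet), for placements leaving the patch, and
    for placements clashing with more than half the lipid sites.
    """
    if not 0.0 <= tilt_deg <= 85.0:
        raise ValueError("tilt must be within [0, 85] degrees")
    lo, hi = residue_range
    ca = conf.ca[lo - 1:hi]
    axis, center, _ = helix_axis(ca)
    tilt = np.deg2rad(tilt_deg)
    # N->C axis pointing upward out of the membrane => N-terminus deeper
    target = np.array([np.cos(tilt), 0.0, np.sin(tilt)])
    rot, _ = Rotation.align_vectors(target[None, :], axis[None, :])
    R = rot.as_matrix()
    if roll_deg:
        R = Rotation.from_rotvec(np.deg2rad(roll_deg) * target).as_matrix() @ R
    moved = conf.transformed(R, -R @ center)
    # translate: anchor SC to the requested depth, xy to the patch centre
    patch_center = bilayer.head_p[:, :2].mean(axis=0)
    z_target = bilayer.midplane_z() + anchor_depth
    anchor_sc = moved.sc[anchor_residue - 1]
    shift = np.array([patch_center[0] - moved.ca.mean(axis=0)[0],
                      patch_center[1] - moved.ca.mean(axis=0)[1],
                      z_target - anchor_sc[2]])
    placed = moved.transformed(None, shift)

    xy = placed.flat_coords()[:, :2]
    half = np.array(bilayer.box_xy) / 2.0
    if (np.abs(xy - patch_center) > half).any():
        raise ValueError("placement leaves the bilayer patch; use a "
                         "larger patch")
    sites = bilayer.all_sites()
    clashing = (cdist(sites, placed.flat_coords()).min(axis=1)
                < clash_distance).sum()
    if clashing > 0.5 * len(sites):
        raise ValueError("placement clashes with more than half of the "
                         "lipid sites")
    return placed


def synthesize_shifts(ensemble: Ensemble,
                      predictor: ToyShiftPredictor | None = None,
                      noise_sd: float = 0.3, seed: int = 0,
                      residue_range=(6, 25),
                      atoms=ATOMS) -> ChemicalShiftTable:
    """Noisy shift table emulating the experimental restraint input.

    Rows are the ensemble-mean predicted shifts for the assigned region
    (default residues 6-25, nuclei CA/CB/C) plus i.i.d. Gaussian noise of
    SD ``noise_sd`` ppm; the sigma column records ``noise_sd`` (floored at
    1e-6 so a noise-free table stays valid).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    predictor = predictor or ToyShiftPredictor()
    rng = np.random.default_rng(seed)
    preds = [predictor.predict(ensemble[f], atoms=atoms)
             for f in range(len(ensemble))]
    import pandas as pd
    mean = (pd.concat(preds).groupby(["residue", "atom"], sort=False)
            ["shift"].mean().reset_index())
    lo, hi = residue_range
    mean = mean[(mean.residue >= lo) & (mean.residue <= hi)]
    noise = rng.normal(0.0, noise_sd, size=len(mean)) if noise_sd > 0 \
        else np.zeros(len(mean))
    mean = mean.assign(shift=mean["shift"] + noise,
                       sigma=max(noise_sd, 1e-6))
    return ChemicalShiftTable(mean.reset_index(drop=True))
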