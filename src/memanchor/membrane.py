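"""Bilayer-relative geometry and energetics.

A :class:`BilayerModel` is a coarse two-leaflet slab: each lipid carries a
headgroup phosphorus site, a glycerol site and 18 chain-carbon sites whose
mean distance from the bilayer midplane decreases monotonically with
carbon index (P at ~19 A, C5 at ~12.5 A, C10 at ~7.5 A, C16 at ~2.5 A).
A fraction of lipids may carry a doxyl spin label at a chosen carbon (or
at the headgroup), which is the paramagnetic probe of the PRE analysis.

Topology measures: membrane surface fitted through the P atoms near the
protein, helix tilt against that surface, per-residue insertion depth
along the membrane normal, sidechain-lipid contacts and Lennard-Jones /
Coulomb interaction energies, and a PRE-attenuation profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .ensemble import Ensemble
from .geometry import Conformation

LIPID_SPECIES = ("DOPE", "DOPS", "DOPC")
#: Net headgroup charge (e) at the P site.
HEADGROUP_CHARGE = {"DOPE": 0.0, "DOPS": -1.0, "DOPC": 0.0}

#: Mean |z| (Angstrom from the midplane) of the lipid sites.
Z_PHOSPHORUS = 19.0
Z_GLYCEROL = 16.5
_CARBON_KNOTS = ([1, 5, 10, 16, 18], [15.5, 12.5, 7.5, 2.5, 1.5])

#: Coulomb conversion constant f in kJ nm mol^-1 e^-2.
COULOMB_F = 138.935458


def carbon_depth_profile() -> np.ndarray:
    """|z| (Angstrom) of chain carbons 1..18, strictly decreasing."""
    idx = np.arange(1, 19)
    return np.interp(idx, *_CARBON_KNOTS)


@dataclass
class BilayerModel:
    """Coarse flat bilayer patch.

    Arrays are per lipid: ``head_p`` (n, 3), ``glycerol`` (n, 3),
    ``carbons`` (n, 18, 3); ``leaflet`` is +1 (upper) or -1 (lower).
    ``label_carbon`` is a carbon index 1..18 or the string "headgroup";
    ``labelled`` flags the doped lipids.
    """

    species: np.ndarray
    leaflet: np.ndarray
    head_p: np.ndarray
    glycerol: np.ndarray
    carbons: np.ndarray
    labelled: np.ndarray
    label_carbon: object = None
    box_xy: tuple = (0.0, 0.0)

    def __post_init__(self):
        if not (set(np.unique(self.leaflet)) <= {-1, 1}):
            raise ValueError("leaflet must be +1 or -1")
        prof = np.abs(self.carbons[:, :, 2]).mean(axis=0)
        if not np.all(np.diff(prof) < 0):
            raise ValueError("carbon |z| must decrease with index")

    @property
    def n_lipids(self) -> int:
        return len(self.species)

    def composition(self) -> dict:
        return {s: int((self.species == s).sum()) for s in LIPID_SPECIES}

    def midplane_z(self) -> float:
        up = self.head_p[self.leaflet == 1, 2].mean()
        lo = self.head_p[self.leaflet == -1, 2].mean()
        return float(0.5 * (up + lo))

    def all_sites(self) -> np.ndarray:
        """All lipid heavy sites: P, glycerol and the 18 chain carbons."""
        return np.concatenate([
            self.head_p, self.glycerol,
            self.carbons.reshape(-1, 3)], axis=0)

    def site_kinds(self) -> np.ndarray:
        """Site-type label per row of :meth:`all_sites`:
        'P', 'GL' or 'CT' (chain carbon)."""
        n = self.n_lipids
        return np.concatenate([np.full(n, "P"), np.full(n, "GL"),
                               np.full(n * 18, "CT")])

    def site_charges(self) -> np.ndarray:
        """Charge (e) per row of :meth:`all_sites` (DOPS headgroup -1)."""
        q_head = np.array([HEADGROUP_CHARGE[s] for s in self.species])
        n = self.n_lipids
        return np.concatenate([q_head, np.zeros(n), np.zeros(n * 18)])

    def label_positions(self) -> np.ndarray:
        """(k, 3) positions of the doxyl labels; empty if undoped."""
        if self.label_carbon is None or not self.labelled.any():
            return np.zeros((0, 3))
        if self.label_carbon == "headgroup":
            return self.head_p[self.labelled]
        c = int(self.label_carbon)
        if not 1 <= c <= 18:
            raise ValueError("label carbon must be 1..18 or 'headgroup'")
        return self.carbons[self.labelled, c - 1, :]


@dataclass
class MembraneFrame:
    """Fitted local membrane surface: unit normal (pointing from the
    midplane toward the proximal leaflet), a point on the fitted plane,
    the midplane point, and the plane-fit RMS residual (Angstrom)."""

    normal: np.ndarray
    plane_point: np.ndarray
    midplane_point: np.ndarray
    fit_residual: float

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal /= np.linalg.norm(self.normal)

    def depth_of(self, points: np.ndarray) -> np.ndarray:
        """Signed distance from the midplane along the normal (positive =
        toward the proximal leaflet surface)."""
        pts = np.atleast_2d(points)
        return (pts - self.midplane_point) @ self.normal


@dataclass
class PREProfile:
    """Per-residue effective label distance and predicted attenuation."""

    r_eff: np.ndarray           # Angstrom
    attenuation: np.ndarray     # in [0, 1]; ~0 = fully broadened
    broadened: np.ndarray       # attenuation < 0.5
    label: object
    r_c: float


def pack_lipids_around(bilayer: BilayerModel, conf: Conformation,
                       contact_distance: float = 4.5,
                       n_iter: int = 12) -> BilayerModel:
    """Return a copy of the bilayer with overlapping lipids displaced
    laterally so their closest approach to the placed peptide is
    ``contact_distance`` (Angstrom).

    Emulates how lipids pack against an inserted protein: the rigid
    lattice of the coarse builder cannot relax, so each clashing lipid is
    pushed outward in the membrane plane, away from the nearest peptide
    site, until it reaches van der Waals contact.
    """
    prot = conf.flat_coords()
    head_p = bilayer.head_p.copy()
    glycerol = bilayer.glycerol.copy()
    carbons = bilayer.carbons.copy()
    for _ in range(n_iter):
        moved = False
        for li in range(bilayer.n_lipids):
            sites = np.vstack([head_p[li], glycerol[li], carbons[li]])
            d = cdist(sites, prot)
            dmin = d.min()
            if dmin >= contact_distance - 1e-6:
                continue
            si, pi = np.unravel_index(np.argmin(d), d.shape)
            away = sites[si, :2] - prot[pi, :2]
            lateral = np.linalg.norm(away)
            if lateral < 1e-9:
                away = sites[si, :2] - prot[:, :2].mean(axis=0)
                away /= max(np.linalg.norm(away), 1e-9)
                lateral = 0.0
            else:
                away = away / lateral
            dz = sites[si, 2] - prot[pi, 2]
            # lateral distance needed so the full 3-D separation reaches
            # contact for this pair
            need = np.sqrt(max(contact_distance ** 2 - dz ** 2, 0.0))
            shift = np.zeros(3)
            shift[:2] = away * max(need - lateral, 0.1)
            head_p[li] += shift
            glycerol[li] += shift
            carbons[li] += shift
            moved = True
        if not moved:
            break
    return BilayerModel(bilayer.species, bilayer.leaflet, head_p, glycerol,
                        carbons, bilayer.labelled, bilayer.label_carbon,
                        bilayer.box_xy)


def fit_membrane_surface(bilayer: BilayerModel, protein_coords: np.ndarray,
                         radius: float = 10.0) -> MembraneFrame:
    """Least-squares plane through the P atoms of the proximal leaflet that
    lie within ``radius`` of any protein atom.

    Raises ValueError (naming the radius) when fewer than 3 P atoms
    qualify.  The midplane point is the mean of the two leaflets' average
    P positions; the normal points from the midplane toward the proximal
    leaflet.
    """
    prot = np.asarray(protein_coords, dtype=float).reshape(-1, 3)
    dmin = cdist(bilayer.head_p, prot).min(axis=1)
    qual = dmin <= radius
    if qual.sum() < 3:
        raise ValueError(
            f"fewer than 3 phosphorus atoms within {radius} A of the "
            f"protein")
    # proximal leaflet = the one contributing most qualifying P atoms
    up_count = (qual & (bilayer.leaflet == 1)).sum()
    lo_count = (qual & (bilayer.leaflet == -1)).sum()
    proximal = 1 if up_count >= lo_count else -1
    pts = bilayer.head_p[qual & (bilayer.leaflet == proximal)]
    if len(pts) < 3:
        raise ValueError(
            f"fewer than 3 proximal-leaflet phosphorus atoms within "
            f"{radius} A of the protein")
    center = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - center, full_matrices=False)
    normal = vt[2]
    residual = s[2] / np.sqrt(len(pts))
    up = bilayer.head_p[bilayer.leaflet == 1].mean(axis=0)
    lo = bilayer.head_p[bilayer.leaflet == -1].mean(axis=0)
    midplane = 0.5 * (up + lo)
    if np.dot(normal, center - midplane) < 0:
        normal = -normal
    return MembraneFrame(normal, center, midplane, float(residual))


def helix_axis(ca: np.ndarray, window: int = 4):
    """Helix axis from smoothed CA positions.

    Consecutive CA positions are averaged over a sliding ``window`` (the
    running centre of one helical turn), and the first principal component
    of the smoothed points, oriented N->C, is the axis.  Returns (axis,
    centroid, line-fit RMS residual of the smoothed points).
    """
    ca = np.asarray(ca, dtype=float)
    if len(ca) < window + 2:
        raise ValueError("too few CA atoms for an axis fit")
    sm = np.array([ca[k:k + window].mean(axis=0)
                   for k in range(len(ca) - window + 1)])
    center = sm.mean(axis=0)
    _, s, vt = np.linalg.svd(sm - center, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, sm[-1] - sm[0]) < 0:
        axis = -axis
    residual = float(np.sqrt((s[1] ** 2 + s[2] ** 2) / len(sm)))
    return axis, center, residual


def helix_tilt_angle(conf: Conformation, frame: MembraneFrame,
                     residue_range=(6, 25), max_residual: float = 1.0
                     ) -> float:
    """Signed tilt (degrees) between the helix axis and the membrane plane.

    The magnitude is the angle between the axis and its projection onto
    the fitted surface plane (0 = lying flat, 90 = perpendicular); the
    sign is positive when the N-terminal end sits deeper (closer to the
    midplane).  Requires the range to be helical enough for a stable axis
    (smoothed-CA line-fit residual <= ``max_residual`` Angstrom).
    """
    lo, hi = residue_range
    ca = conf.ca[lo - 1:hi]
    axis, _, residual = helix_axis(ca)
    if residual > max_residual:
        raise ValueError(
            f"degenerate helix axis: line-fit residual {residual:.2f} A "
            f"exceeds {max_residual} A")
    sin_tilt = abs(float(np.dot(axis, frame.normal)))
    tilt = np.rad2deg(np.arcsin(min(1.0, sin_tilt)))
    depth_ends = frame.depth_of(np.vstack([ca[0], ca[-1]]))
    sign = 1.0 if depth_ends[0] <= depth_ends[1] else -1.0
    return float(sign * tilt)


def residue_depths(ensemble: Ensemble, bilayer: BilayerModel,
                   frame: MembraneFrame | None = None):
    """Per-residue (mean, SD) signed distance of the sidechain centroid
    from the bilayer midplane along the membrane normal (Angstrom).

    Positive values point toward the proximal leaflet surface.  Glycine
    uses CA (its centroid).  The frame defaults to a surface fit against
    the first frame's coordinates.
    """
    if frame is None:
        frame = fit_membrane_surface(bilayer, ensemble.coords[0])
    sc = ensemble.coords[:, :, 4, :]
    depths = (sc - frame.midplane_point) @ frame.normal
    return depths.mean(axis=0), depths.std(axis=0)


def sidechain_lipid_contacts(ensemble: Ensemble, bilayer: BilayerModel,
                             cutoff: float = 5.0) -> np.ndarray:
    """Mean number of lipid heavy sites within ``cutoff`` of each residue's
    sidechain centroid, averaged over frames."""
    sites = bilayer.all_sites()
    counts = np.zeros(len(ensemble.chain))
    for f in range(len(ensemble)):
        d = cdist(ensemble.coords[f, :, 4, :], sites)
        counts += (d <= cutoff).sum(axis=1)
    return counts / len(ensemble)


@dataclass
class LipidInteractionParams:
    """Lennard-Jones and Coulomb parameters for sidechain-lipid terms.

    sigma (Angstrom) and epsilon (kJ/mol) per site type; Lorentz-Berthelot
    combination.  Protein sidechains use one parameter set for hydrophobic
    and one for polar/charged residues.
    """

    sigma_lipid: dict = field(default_factory=lambda: {
        "P": 4.2, "GL": 4.0, "CT": 3.9})
    eps_lipid: dict = field(default_factory=lambda: {
        "P": 0.60, "GL": 0.50, "CT": 0.45})
    sigma_sc: float = 4.0
    eps_sc_hydrophobic: float = 0.55
    eps_sc_polar: float = 0.30


def lj_energy(r: np.ndarray, sigma: float, eps: float) -> np.ndarray:
    """4 eps [(sigma/r)^12 - (sigma/r)^6] (zero handling left to caller)."""
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 ** 2 - sr6)


def coulomb_energy(r_angstrom: np.ndarray, qi: float,
                   qj: np.ndarray) -> np.ndarray:
    """f qi qj / r with r converted to nm; result in kJ/mol."""
    return COULOMB_F * qi * qj / (r_angstrom / 10.0)


def interaction_energies(ensemble: Ensemble, bilayer: BilayerModel,
                         params: LipidInteractionParams | None = None,
                         cutoff: float = 9.0):
    """Frame-averaged per-residue sidechain-lipid (E_vdw, E_coul) in kJ/mol.

    Pairs are truncated at ``cutoff`` (default 0.9 nm).  The sidechain is
    its centroid; charged centroids carry their formal charge and the
    N-terminal amine charge sits on the N atom of residue 1 (evaluated at
    the centroid site for residue 1 in this coarse decomposition).
    """
    params = params or LipidInteractionParams()
    chain = ensemble.chain
    kinds = bilayer.site_kinds()
    unknown = set(np.unique(kinds)) - set(params.sigma_lipid)
    if unknown:
        raise KeyError(f"missing pair parameters for site types {unknown}")
    sites = bilayer.all_sites()
    q_sites = bilayer.site_charges()
    sig_l = np.array([params.sigma_lipid[k] for k in kinds])
    eps_l = np.array([params.eps_lipid[k] for k in kinds])
    q_res = chain.formal_charges()[:, 4].copy()
    if chain.nterm_positive:
        q_res[0] += 1.0
    eps_p = np.where(chain.hydrophobic, params.eps_sc_hydrophobic,
                     params.eps_sc_polar)
    sig_pair = 0.5 * (params.sigma_sc + sig_l)        # (n_sites,)
    e_vdw = np.zeros(len(chain))
    e_coul = np.zeros(len(chain))
    for f in range(len(ensemble)):
        d = cdist(ensemble.coords[f, :, 4, :], sites)
        within = (d <= cutoff) & (d > 1e-6)
        for i in range(len(chain)):
            cols = within[i]
            if not cols.any():
                continue
            r = d[i, cols]
            eps_pair = np.sqrt(eps_p[i] * eps_l[cols])
            e_vdw[i] += float(np.sum(
                eps_pair * lj_energy(r, sig_pair[cols], 1.0)))
            if q_res[i] != 0.0:
                e_coul[i] += coulomb_energy(r, q_res[i],
                                            q_sites[cols]).sum()
    return e_vdw / len(ensemble), e_coul / len(ensemble)


def pre_attenuation(ensemble: Ensemble, bilayer: BilayerModel,
                    r_c: float = 13.0) -> PREProfile:
    """Predicted PRE attenuation per residue for the bilayer's doxyl label.

    The effective distance uses the r^-6 distance dependence of
    paramagnetic relaxation: r_eff = < min_labels r^-6 >_frames^(-1/6),
    and the attenuation is the sigmoid A = 1 / (1 + (r_eff / r_c)^-6), so
    A -> 0 (fully broadened) for residues much closer than ``r_c`` to a
    label and A -> 1 far away.  ``broadened`` flags A < 0.5.
    """
    labels = bilayer.label_positions()
    if len(labels) == 0:
        raise ValueError("bilayer carries no doxyl labels")
    n = len(ensemble.chain)
    inv6 = np.zeros(n)
    for f in range(len(ensemble)):
        dmin = cdist(ensemble.coords[f, :, 4, :], labels).min(axis=1)
        inv6 += dmin ** -6
    r_eff = (inv6 / len(ensemble)) ** (-1.0 / 6.0)
    att = 1.0 / (1.0 + (r_eff / r_c) ** -6)
    return PREProfile(r_eff, att, att < 0.5, bilayer.label_carbon, r_c)


_PDB_RES = {"DOPE": "DPE", "DOPS": "DPS", "DOPC": "DPC"}
_PDB_RES_INV = {v: k for k, v in _PDB_RES.items()}


def bilayer_to_pdb(bilayer: BilayerModel, path) -> None:
    """Serialise a bilayer as PDB: residues DPE/DPS/DPC, atoms P, GL and
    C01..C18 per lipid; labelled lipids carry B-factor 1 on the P atom and
    the label carbon is recorded in a REMARK 99 line."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = bilayer.n_lipids
    per = 20
    arr = struc.AtomArray(n * per)
    arr.chain_id = np.full(n * per, "L")
    arr.res_id = np.repeat(np.arange(1, n + 1), per)
    arr.res_name = np.repeat([_PDB_RES[s] for s in bilayer.species], per)
    names = ["P", "GL"] + [f"C{k:02d}" for k in range(1, 19)]
    arr.atom_name = np.tile(np.array(names), n)
    arr.element = np.tile(np.array(["P"] + ["C"] * 19), n)
    arr.hetero = np.full(n * per, True)
    bf = np.zeros(n * per)
    bf[::per] = bilayer.labelled.astype(float)
    arr.set_annotation("b_factor", bf)
    coords = np.concatenate(
        [np.concatenate([bilayer.head_p[li][None, :],
                         bilayer.glycerol[li][None, :],
                         bilayer.carbons[li]], axis=0)
         for li in range(n)], axis=0)
    arr.coord = coords
    pdb = PDBFile()
    pdb.set_structure(arr)
    label = bilayer.label_carbon
    lines = [f"REMARK  99 LABEL_CARBON {label}",
             f"REMARK  99 BOX_XY {bilayer.box_xy[0]:.3f} "
             f"{bilayer.box_xy[1]:.3f}"]
    pdb.lines = lines + pdb.lines
    pdb.write(str(path))


def bilayer_from_pdb(path) -> BilayerModel:
    """Read a bilayer written by :func:`bilayer_to_pdb`."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    label_carbon = None
    box_xy = (0.0, 0.0)
    for line in pdb.lines:
        if line.startswith("REMARK  99 LABEL_CARBON"):
            tok = line.split()[-1]
            if tok != "None":
                label_carbon = tok if tok == "headgroup" else int(tok)
        elif line.startswith("REMARK  99 BOX_XY"):
            parts = line.split()
            box_xy = (float(parts[-2]), float(parts[-1]))
    arr = pdb.get_structure(model=1, extra_fields=["b_factor"])
    per = 20
    if arr.array_length() % per != 0:
        raise ValueError("not a coarse bilayer PDB")
    n = arr.array_length() // per
    species = np.array([_PDB_RES_INV[rn] for rn in arr.res_name[::per]])
    coords = np.asarray(arr.coord, dtype=float).reshape(n, per, 3)
    head_p = coords[:, 0]
    glycerol = coords[:, 1]
    carbons = coords[:, 2:]
    leaflet = np.where(head_p[:, 2] >= head_p[:, 2].mean(), 1, -1)
    labelled = arr.b_factor[::per] > 0.5
    return BilayerModel(species, leaflet, head_p, glycerol, carbons,
                        labelled, label_carbon, box_xy)


def slab_energy(conf: Conformation, bilayer: BilayerModel,
                eps_hydrophobic: float = 4.0, eps_interface: float = 2.0,
                width: float = 3.0) -> float:
    """Optional membrane slab term for a placed conformation (kJ/mol).

    Hydrophobic centroids are attracted to the acyl region (|z| below the
    glycerol level); charged/polar centroids pay a desolvation penalty for
    entering it.  Smooth sigmoids of width ``width`` avoid discontinuities.
    """
    z0 = bilayer.midplane_z()
    z = np.abs(conf.sc[:, 2] - z0)
    inside = 1.0 / (1.0 + np.exp((z - Z_GLYCEROL) / width))
    hyd = np.asarray(conf.chain.hydrophobic, dtype=float)
    return float(np.sum(-eps_hydrophobic * hyd * inside
                        + eps_interface * (1.0 - hyd) * inside))
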