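"""Bilayer geometry, tilt/depth, lipid energetics and PRE prediction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from memanchor.ensemble import Ensemble
from memanchor.membrane import (COULOMB_F, LipidInteractionParams,
                                coulomb_energy, fit_membrane_surface,
                                helix_tilt_angle, interaction_energies,
                                lj_energy, pre_attenuation,
                                pack_lipids_around, residue_depths,
                                sidechain_lipid_contacts)
from memanchor.synthetic import build_bilayer, place_peptide


@pytest.fixture(scope="module")
def bilayer():
    return build_bilayer(128, seed=3)


@pytest.fixture(scope="module")
def placed_12(ideal_helix, bilayer):
    return place_peptide(ideal_helix, bilayer, 12.0, 8.9, 4)


def rotate_bilayer(bl, R):
    import dataclasses
    return dataclasses.replace(
        bl, head_p=bl.head_p @ R.T, glycerol=bl.glycerol @ R.T,
        carbons=bl.carbons @ R.T)


def test_flat_surface_fit(bilayer, placed_12):
    frame = fit_membrane_surface(bilayer, placed_12.flat_coords())
    assert abs(frame.normal @ [0, 0, 1]) > 0.9999
    assert frame.plane_point[2] == pytest.approx(19.0, abs=0.5)
    assert frame.midplane_point[2] == pytest.approx(0.0, abs=0.3)


def test_rotated_bilayer_normal_recovered(bilayer, placed_12):
    R = Rotation.from_euler("x", 20, degrees=True).as_matrix()
    bl = rotate_bilayer(bilayer, R)
    prot = placed_12.flat_coords() @ R.T
    frame = fit_membrane_surface(bl, prot)
    target = R @ np.array([0.0, 0.0, 1.0])
    ang = np.rad2deg(np.arccos(np.clip(abs(frame.normal @ target), -1, 1)))
    assert ang < 0.5


def test_far_protein_raises(bilayer, ideal_helix):
    far = ideal_helix.transformed(None, np.array([0.0, 0.0, 120.0]))
    with pytest.raises(ValueError, match="10"):
        fit_membrane_surface(bilayer, far.flat_coords())


@pytest.mark.parametrize("tilt", [0.0, 12.0])
def test_tilt_round_trip(ideal_helix, bilayer, tilt):
    placed = place_peptide(ideal_helix, bilayer, tilt, 16.0, 4)
    frame = fit_membrane_surface(bilayer, placed.flat_coords())
    assert helix_tilt_angle(placed, frame) == pytest.approx(tilt, abs=0.5)


@pytest.mark.parametrize("tilt", [0.0, 12.0, 30.0, 60.0])
def test_tilt_exact_against_flat_frame(ideal_helix, bilayer, tilt):
    """Against the exact (jitter-free) membrane frame the placement is
    recovered to numerical precision."""
    from memanchor.membrane import MembraneFrame
    flat = MembraneFrame(np.array([0.0, 0.0, 1.0]),
                         np.array([0.0, 0.0, 19.0]), np.zeros(3), 0.0)
    placed = place_peptide(ideal_helix, bilayer, tilt, 17.0, 4)
    assert helix_tilt_angle(placed, flat) == pytest.approx(tilt, abs=0.05)


def test_tilt_extremes(ideal_helix, bilayer):
    """A helix axis along the membrane normal reads 90 degrees; a steep
    placement request is rejected by the documented clamp rule."""
    frame = fit_membrane_surface(
        bilayer, place_peptide(ideal_helix, bilayer, 0.0, 19.0, 4)
        .flat_coords())
    from memanchor.membrane import helix_axis
    axis, center, _ = helix_axis(ideal_helix.ca[5:25])
    R, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]),
                                  axis[None, :])
    upright = ideal_helix.transformed(R.as_matrix(), np.array([0, 0, 40.0]))
    assert abs(helix_tilt_angle(upright, frame)) == pytest.approx(90.0,
                                                                  abs=0.5)
    with pytest.raises(ValueError):
        place_peptide(ideal_helix, bilayer, 90.0, 8.9, 4)


def test_tilt_invariant_under_joint_rotation(bilayer, placed_12):
    frame = fit_membrane_surface(bilayer, placed_12.flat_coords())
    t0 = helix_tilt_angle(placed_12, frame)
    R = Rotation.from_euler("zyx", [30, 15, -25], degrees=True).as_matrix()
    bl = rotate_bilayer(bilayer, R)
    prot = placed_12.transformed(R)
    frame2 = fit_membrane_surface(bl, prot.flat_coords())
    assert helix_tilt_angle(prot, frame2) == pytest.approx(t0, abs=0.05)


def test_degenerate_axis_raises(chain, bilayer):
    from memanchor.geometry import torsions_to_cartesian
    rng = np.random.default_rng(5)
    coil = torsions_to_cartesian(rng.uniform(-180, 180, (len(chain), 2)),
                                 chain)
    frame = fit_membrane_surface(
        bilayer, coil.transformed(None, np.array([0, 0, 25.0]))
        .flat_coords())
    with pytest.raises(ValueError, match="residual"):
        helix_tilt_angle(coil, frame, max_residual=0.5)


def test_depth_anchoring_and_rigid_sd(bilayer, placed_12):
    ens = Ensemble.from_conformations([placed_12] * 4)
    frame = fit_membrane_surface(bilayer, placed_12.flat_coords())
    mean, sd = residue_depths(ens, bilayer, frame)
    assert mean[3] == pytest.approx(8.9, abs=0.05)
    assert np.allclose(sd, 0.0, atol=1e-9)


def test_depth_profile_affine_with_tilt(ideal_helix, bilayer):
    """CA depth difference along a straight tilted helix follows
    rise * sin(tilt) per residue."""
    tilt = 20.0
    placed = place_peptide(ideal_helix, bilayer, tilt, 14.0, 4)
    frame = fit_membrane_surface(bilayer, placed.flat_coords())
    ca_depth = frame.depth_of(placed.ca)
    idx = np.arange(5, 25)
    slope = np.polyfit(idx, ca_depth[5:25], 1)[0]
    expected = 1.5577 * np.sin(np.deg2rad(tilt))  # rise * sin(tilt)
    assert slope == pytest.approx(expected, rel=0.10)


def test_contacts_zero_far_and_planted(chain, bilayer, ideal_helix):
    high = place_peptide(ideal_helix, bilayer, 0.0, 40.0, 4)
    ens = Ensemble.from_conformations([high])
    assert np.allclose(sidechain_lipid_contacts(ens, bilayer), 0.0)
    # residue centroid placed 4 A from exactly 3 sites counts 3.0
    import dataclasses
    bl = build_bilayer(8, seed=1)
    sc = ideal_helix.sc[9]
    # move everything far away laterally, then plant 3 sites 4 A from SC10
    shift = np.array([500.0, 0.0, 0.0])
    carbons = bl.carbons + shift
    head_p = bl.head_p + shift
    glycerol = bl.glycerol + shift
    # plant along outward directions so no other centroid is within reach
    out = sc - ideal_helix.ca.mean(axis=0)
    out /= np.linalg.norm(out)
    perp = np.cross(out, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    head_p[0] = sc + 4.0 * out
    head_p[1] = sc + 4.0 * (np.cos(0.3) * out + np.sin(0.3) * perp)
    glycerol[0] = sc + 4.0 * (np.cos(0.3) * out - np.sin(0.3) * perp)
    bl = dataclasses.replace(bl, carbons=carbons, head_p=head_p,
                             glycerol=glycerol)
    counts = sidechain_lipid_contacts(
        Ensemble.from_conformations([ideal_helix]), bl)
    assert counts[9] == 3.0


def test_inserted_nterm_ordering(ideal_helix, bilayer):
    """With the N-terminal residues deeper (tilt 12, F4 at 8.9 A), contacts
    and |E_vdw| for residues 1-12 exceed those for residues 20-30."""
    placed = place_peptide(ideal_helix, bilayer, 12.0, 8.9, 4)
    bl = pack_lipids_around(bilayer, placed)
    ens = Ensemble.from_conformations([placed])
    contacts = sidechain_lipid_contacts(ens, bl)
    assert contacts[:12].mean() > contacts[19:].mean()
    e_vdw, e_coul = interaction_energies(ens, bl)
    assert np.abs(e_vdw[:12]).mean() > np.abs(e_vdw[19:]).mean()
    # charged N-terminal residues see the anionic DOPS headgroups
    charged = [0, 1, 5, 9, 11]  # M1 (amine), D2, K6, K10, K12
    assert np.any(e_coul[charged] != 0.0)


def test_contacts_monotone_on_z_scan(ideal_helix, bilayer):
    """Pulling the peptide away from the bilayer monotonically removes
    contacts."""
    totals = []
    for depth in (16.0, 22.0, 28.0, 34.0):
        placed = place_peptide(ideal_helix, bilayer, 0.0, depth, 4)
        ens = Ensemble.from_conformations([placed])
        totals.append(sidechain_lipid_contacts(ens, bilayer).sum())
    assert all(a >= b for a, b in zip(totals, totals[1:]))
    assert totals[0] > totals[-1]


def test_lj_analytic_points():
    assert lj_energy(np.array([4.0]), 4.0, 0.7)[0] == pytest.approx(0.0)
    rmin = 2 ** (1 / 6) * 4.0
    assert lj_energy(np.array([rmin]), 4.0, 0.7)[0] == pytest.approx(-0.7)


def test_coulomb_analytic():
    # +1 e / -1 e at 0.5 nm -> -2 f
    e = coulomb_energy(np.array([5.0]), 1.0, np.array([-1.0]))[0]
    assert e == pytest.approx(-2 * COULOMB_F)


def test_missing_pair_parameters(bilayer, placed_12):
    ens = Ensemble.from_conformations([placed_12])
    params = LipidInteractionParams(sigma_lipid={"P": 4.2})
    with pytest.raises(KeyError):
        interaction_energies(ens, bilayer, params)


def test_pre_limits(chain, ideal_helix):
    import dataclasses
    bl = build_bilayer(64, seed=9, label=5, label_fraction=1.0)
    near = ideal_helix.transformed(
        None, bl.label_positions()[0] - ideal_helix.sc[0] + [0, 0, 2.0])
    prof = pre_attenuation(Ensemble.from_conformations([near]), bl)
    assert prof.attenuation[0] < 0.05 and prof.broadened[0]
    far = ideal_helix.transformed(None, np.array([0, 0, 60.0]))
    prof_far = pre_attenuation(Ensemble.from_conformations([far]), bl)
    assert np.all(prof_far.attenuation > 0.95)
    assert not prof_far.broadened.any()
    undoped = dataclasses.replace(bl, labelled=np.zeros(64, dtype=bool))
    with pytest.raises(ValueError):
        pre_attenuation(Ensemble.from_conformations([far]), undoped)


def test_pre_label_depth_ordering(ideal_helix):
    """For residues sitting above the carbon-5 level, attenuation grows
    with label depth: A(C16) >= A(C10) >= A(C5)."""
    placed = None
    atts = {}
    for c in (5, 10, 16):
        bl = build_bilayer(128, seed=3, label=c, label_fraction=1.0)
        if placed is None:
            placed = place_peptide(ideal_helix, bl, 12.0, 14.0, 4)
            ens = Ensemble.from_conformations([placed])
            frame = fit_membrane_surface(bl, placed.flat_coords())
            depth, _ = residue_depths(ens, bl, frame)
        atts[c] = pre_attenuation(ens, bl).attenuation
    above = depth > 12.5
    assert above.any()
    assert np.all(atts[16][above] >= atts[10][above] - 1e-9)
    assert np.all(atts[10][above] >= atts[5][above] - 1e-9)


def test_pre_attenuation_monotone_in_reff(ideal_helix):
    bl = build_bilayer(128, seed=3, label=5, label_fraction=1.0)
    placed = place_peptide(ideal_helix, bl, 12.0, 10.0, 4)
    prof = pre_attenuation(Ensemble.from_conformations([placed]), bl)
    order = np.argsort(prof.r_eff)
    assert np.all(np.diff(prof.attenuation[order]) >= -1e-12)
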