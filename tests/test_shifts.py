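"""Shift tables, toy predictor, replica-averaged restraint energy."""

import numpy as np
import pandas as pd
import pytest

from memanchor import build_ideal_helix, torsions_to_cartesian
from memanchor.shifts import (ChemicalShiftTable, RANDOM_COIL,
                              ReplicaRestraint, ToyShiftPredictor,
                              backcalc_validate, read_shift_table,
                              replica_averaged_energy, write_shift_table)
from memanchor.ensemble import Ensemble
from memanchor.synthetic import synthesize_shifts


@pytest.fixture(scope="module")
def predictor():
    return ToyShiftPredictor()


def make_table(rows):
    return ChemicalShiftTable(pd.DataFrame(
        rows, columns=["residue", "atom", "shift", "sigma"]))


# -- table I/O ---------------------------------------------------------------

def test_table_roundtrip(tmp_path, chain, ideal_helix, predictor):
    ens = Ensemble.from_conformations([ideal_helix])
    table = synthesize_shifts(ens, predictor, noise_sd=0.2, seed=4)
    path = tmp_path / "shifts.tsv"
    write_shift_table(table, path)
    again = read_shift_table(path)
    pd.testing.assert_frame_equal(table.df, again.df, rtol=1e-5)
    header = path.read_text().splitlines()[0]
    assert header.split("\t") == ["residue", "atom", "shift", "sigma"]


def test_duplicate_keys_rejected():
    with pytest.raises(ValueError):
        make_table([(6, "CA", 55.0, 0.3), (6, "CA", 55.1, 0.3)])


def test_nonpositive_sigma_rejected():
    with pytest.raises(ValueError):
        make_table([(6, "CA", 55.0, 0.0)])


def test_default_table_covers_assigned_region(partially_helical):
    ens, _ = partially_helical
    table = synthesize_shifts(ens, noise_sd=0.3, seed=2)
    assert len(table) == 60  # residues 6-25 x {CA, CB, C}
    assert set(table.df.residue) == set(range(6, 26))


# -- toy predictor -----------------------------------------------------------

def test_predictor_helix_and_coil_limits(chain, ideal_helix, predictor):
    pred = predictor.predict(ideal_helix).set_index(["residue", "atom"])
    for i, aa in enumerate(chain.sequence, start=1):
        coil = RANDOM_COIL[aa]
        # ideal helix -> w = 1 -> coil + full helical secondary shift
        assert pred.loc[(i, "CA"), "shift"] == pytest.approx(coil[0] + 2.6)
        assert pred.loc[(i, "CB"), "shift"] == pytest.approx(coil[1] - 0.4)
        assert pred.loc[(i, "C"), "shift"] == pytest.approx(coil[2] + 1.9)
    far = torsions_to_cartesian(np.tile([-140.0, 140.0], (len(chain), 1)),
                                chain)
    pred_far = predictor.predict(far).set_index(["residue", "atom"])
    for i, aa in enumerate(chain.sequence, start=1):
        assert pred_far.loc[(i, "CA"), "shift"] == pytest.approx(
            RANDOM_COIL[aa][0], abs=0.05)


def test_basin_weight_value(predictor):
    # one sigma along phi: w = exp(-1/2)
    assert predictor.basin_weight(-57.0 + 25.0, -47.0) == pytest.approx(
        np.exp(-0.5))
    assert predictor.basin_weight(-57.0, -47.0) == 1.0


def test_predictor_unknown_atom(ideal_helix, predictor):
    with pytest.raises(ValueError):
        predictor.predict(ideal_helix, atoms=("CA", "HB"))


# -- replica-averaged restraint ---------------------------------------------

def exact_table(conf, predictor, sigma=0.3):
    pred = predictor.predict(conf)
    return ChemicalShiftTable(pred.assign(sigma=sigma))


def test_energy_zero_on_exact_match(ideal_helix, predictor):
    table = exact_table(ideal_helix, predictor)
    restraint = ReplicaRestraint(k=1.0, n_replicas=4)
    e = replica_averaged_energy([ideal_helix] * 4, table, restraint,
                                predictor)
    assert e == 0.0


def test_energy_single_violation_is_k_d_squared(ideal_helix, predictor):
    table = exact_table(ideal_helix, predictor, sigma=0.3)
    # shift one nucleus by eps + d
    d = 1.0
    df = table.df.copy()
    df.loc[0, "shift"] += 0.3 + d
    table2 = ChemicalShiftTable(df)
    restraint = ReplicaRestraint(k=1.0, n_replicas=4)
    e = replica_averaged_energy([ideal_helix] * 4, table2, restraint,
                                predictor)
    assert e == pytest.approx(1.0 * d ** 2)


def test_energy_replica_permutation_invariant(chain, ideal_helix, predictor):
    rng = np.random.default_rng(5)
    confs = [torsions_to_cartesian(rng.uniform(-180, 180, (len(chain), 2)),
                                   chain) for _ in range(4)]
    table = exact_table(ideal_helix, predictor)
    restraint = ReplicaRestraint(k=2.0, n_replicas=4)
    e1 = replica_averaged_energy(confs, table, restraint, predictor)
    e2 = replica_averaged_energy(confs[::-1], table, restraint, predictor)
    assert e1 == pytest.approx(e2)
    assert e1 > 0


def test_opposite_deviations_cancel(chain, predictor):
    """M=2 with +d and -d deviations on the basin weight: the replica mean
    matches and the energy is zero -- the defining property of
    replica-averaged restraints."""
    w_hi, w_lo = 0.8, 0.2
    def conf_with_w(w):
        dphi = np.sqrt(-2 * 25.0 ** 2 * np.log(w))
        t = np.tile([-57.0 + dphi, -47.0], (len(chain), 1))
        return torsions_to_cartesian(t, chain)
    hi, lo = conf_with_w(w_hi), conf_with_w(w_lo)
    # target = mean prediction of the two replicas
    mean_pred = (predictor.predict(hi).set_index(["residue", "atom"])
                 + predictor.predict(lo).set_index(["residue", "atom"])) / 2
    table = ChemicalShiftTable(mean_pred.reset_index().assign(sigma=1e-6))
    restraint = ReplicaRestraint(k=5.0, epsilon=0.0, n_replicas=2)
    e = replica_averaged_energy([hi, lo], table, restraint, predictor)
    assert e == pytest.approx(0.0, abs=1e-12)
    # a single replica alone violates the same table
    solo = ReplicaRestraint(k=5.0, epsilon=0.0, n_replicas=1)
    assert replica_averaged_energy([hi], table, solo, predictor) > 0.1


def test_m1_reduces_to_flat_bottom_harmonic(ideal_helix, predictor):
    table = exact_table(ideal_helix, predictor, sigma=0.2)
    df = table.df.copy()
    rng = np.random.default_rng(6)
    df["shift"] += rng.normal(0, 0.5, len(df))
    table2 = ChemicalShiftTable(df)
    restraint = ReplicaRestraint(k=3.0, n_replicas=1)
    e = replica_averaged_energy([ideal_helix], table2, restraint, predictor)
    pred = predictor.predict(ideal_helix).set_index(["residue", "atom"])
    merged = table2.df.set_index(["residue", "atom"]).join(
        pred.rename(columns={"shift": "pred"}))
    excess = np.maximum(0, np.abs(merged["pred"] - merged["shift"]) - 0.2)
    assert e == pytest.approx(3.0 * np.sum(excess ** 2))


def test_energy_decreases_as_replica_approaches_target(chain, predictor):
    """Moving one replica's shifts toward the experimental values while the
    others sit on them never increases the energy."""
    target = build_ideal_helix(chain)
    table = exact_table(target, predictor, sigma=0.1)
    restraint = ReplicaRestraint(k=1.0, n_replicas=3)
    energies = []
    for dphi in (60.0, 40.0, 20.0, 5.0, 0.0):
        off = torsions_to_cartesian(
            np.tile([-57.0 + dphi, -47.0], (len(chain), 1)), chain)
        energies.append(replica_averaged_energy(
            [target, target, off], table, restraint, predictor))
    assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))
    assert energies[-1] == 0.0


def test_replica_count_mismatch(ideal_helix, predictor):
    table = exact_table(ideal_helix, predictor)
    with pytest.raises(ValueError):
        replica_averaged_energy([ideal_helix] * 3, table,
                                ReplicaRestraint(n_replicas=4), predictor)


# -- back-calculation validation ---------------------------------------------

def test_backcalc_exact_match_passes(ideal_helix, predictor):
    ens = Ensemble.from_conformations([ideal_helix] * 5)
    table = exact_table(ideal_helix, predictor)
    report = backcalc_validate(ens, table, predictor)
    assert report["passed"].all()
    assert np.allclose(report["mean_dev"], 0.0, atol=1e-9)


def test_backcalc_flags_shifted_ca(ideal_helix, predictor):
    ens = Ensemble.from_conformations([ideal_helix] * 5)
    df = exact_table(ideal_helix, predictor).df.copy()
    df.loc[df.atom == "CA", "shift"] += 10.0
    report = backcalc_validate(ens, ChemicalShiftTable(df), predictor)
    row = report.set_index("atom")
    assert not row.loc["CA", "passed"]
    assert row.loc["C", "passed"]


def test_backcalc_with_known_noise(partially_helical, predictor):
    """Noise sd 0.3 ppm against an error estimate of 0.4 ppm: PASS with
    observed SD near 0.3."""
    ens, _ = partially_helical
    sub = ens.subset(np.arange(0, len(ens), 4))
    table = synthesize_shifts(sub, predictor, noise_sd=0.3, seed=11)
    report = backcalc_validate(sub, table, predictor).set_index("atom")
    assert report.loc["CA", "sd_dev"] == pytest.approx(0.3, abs=0.12)
    assert report.loc["CA", "passed"]


def test_cross_validation_with_perturbed_predictor(partially_helical,
                                                   predictor):
    """The packaged perturbed predictor differs from the restraining one
    but stays within its error estimate on a consistent ensemble."""
    other = predictor.perturbed()
    assert other.delta_helix != predictor.delta_helix
    ens, _ = partially_helical
    sub = ens.subset(np.arange(0, len(ens), 8))
    table = synthesize_shifts(sub, predictor, noise_sd=0.0, seed=0)
    report = backcalc_validate(sub, table, other).set_index("atom")
    # mean deviations reflect the rescaled secondary shifts, but SDs stay
    # bounded by the error estimates
    assert report["sd_dev"].max() < 0.6
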