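"""Chemical-shift tables, a toy torsion->shift predictor, and the
replica-averaged restraint energy.

The predictor is a deliberately simple, documented stand-in for a full
structure-based shift calculator: the backbone-carbon secondary shift is
proportional to a Gaussian weight of the (phi, psi) pair around the
helical basin,

    delta(res, atom) = delta_coil(aa, atom) + w(phi, psi) * ddelta_helix(atom)
    w(phi, psi) = exp(-[(phi+57)^2 + (psi+47)^2] / (2 s^2)),  s = 25 deg

with circular angle differences, a packaged random-coil table and helical
secondary shifts (+2.6, -0.4, +1.9) ppm for (CA, CB, C).  It is
deterministic given a conformation, smooth in the torsions, and has the
correct qualitative behaviour (helix raises CA/C, lowers CB), which is all
the restrained-sampling machinery requires.

The restraint is a flat-bottom harmonic on the across-replica mean of the
predicted shifts:

    E = k * sum_j max(0, |mean_m delta_pred(m, j) - delta_exp(j)| - eps_j)^2

so the experimental value is enforced as an ensemble average and
compensating deviations between replicas carry no penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import PeptideChain
from .geometry import Conformation

#: Random-coil shifts (ppm) for (CA, CB, C).  Glycine has no physical CB;
#: the coarse model assigns it a nominal value so that every residue
#: carries the same three backbone-carbon reporters.
RANDOM_COIL = {
    "A": (52.5, 19.1, 177.8), "R": (56.0, 30.9, 176.3),
    "N": (53.1, 38.9, 175.2), "D": (54.2, 41.1, 176.3),
    "C": (58.2, 28.0, 174.6), "Q": (55.7, 29.4, 176.0),
    "E": (56.6, 29.9, 176.6), "G": (45.1, 43.0, 174.9),
    "H": (55.0, 29.0, 174.1), "I": (61.1, 38.8, 176.4),
    "L": (55.1, 42.4, 177.6), "K": (56.2, 33.1, 176.6),
    "M": (55.4, 32.9, 176.3), "F": (57.7, 39.6, 175.8),
    "P": (63.3, 32.1, 177.3), "S": (58.3, 63.8, 174.6),
    "T": (61.8, 69.8, 174.7), "W": (57.5, 29.6, 176.1),
    "Y": (57.9, 38.8, 175.9), "V": (62.2, 32.9, 176.3),
}

ATOMS = ("CA", "CB", "C")
DELTA_HELIX = {"CA": 2.6, "CB": -0.4, "C": 1.9}

#: Assigned region of the ssNMR data: residues 6-25.
ASSIGNED_RANGE = (6, 25)


class ChemicalShiftTable:
    """Rows of (residue index, atom name, shift ppm, sigma ppm).

    Keys (residue, atom) are unique; sigma must be positive.
    """

    COLUMNS = ("residue", "atom", "shift", "sigma")

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["residue"] = df["residue"].astype(int)
        df["atom"] = df["atom"].astype(str)
        df["shift"] = pd.to_numeric(df["shift"], errors="raise")
        df["sigma"] = pd.to_numeric(df["sigma"], errors="raise")
        if df.duplicated(subset=["residue", "atom"]).any():
            dup = df[df.duplicated(subset=["residue", "atom"])]
            raise ValueError(f"duplicate (residue, atom) keys:\n{dup}")
        if (df["sigma"] <= 0).any():
            raise ValueError("sigma must be > 0")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate_against(self, chain: PeptideChain) -> None:
        bad = self.df[(self.df.residue < 1) | (self.df.residue > len(chain))]
        if len(bad):
            raise ValueError(f"residue indices outside chain:\n{bad}")

    @classmethod
    def from_records(cls, records) -> "ChemicalShiftTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))


def read_shift_table(path) -> ChemicalShiftTable:
    """Read a TSV with header ``residue atom shift sigma``."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ChemicalShiftTable.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return ChemicalShiftTable(df)


def write_shift_table(table: ChemicalShiftTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class ToyShiftPredictor:
    """Torsion-based backbone-carbon shift predictor (see module docstring).

    ``error_estimate`` is the per-nucleus accuracy claimed by the
    predictor, used as the pass threshold in back-calculation validation.
    """

    sigma_deg: float = 25.0
    center: tuple = (-57.0, -47.0)
    delta_helix: dict = field(default_factory=lambda: dict(DELTA_HELIX))
    coil: dict = field(default_factory=lambda: dict(RANDOM_COIL))
    error_estimate: dict = field(
        default_factory=lambda: {"CA": 0.4, "CB": 0.5, "C": 0.4})

    def basin_weight(self, phi, psi):
        """Helical basin weight w in (0, 1], circular differences."""
        dphi = (np.asarray(phi) - self.center[0] + 180.0) % 360.0 - 180.0
        dpsi = (np.asarray(psi) - self.center[1] + 180.0) % 360.0 - 180.0
        return np.exp(-(dphi ** 2 + dpsi ** 2) / (2.0 * self.sigma_deg ** 2))

    def predict(self, conf: Conformation, atoms=ATOMS) -> pd.DataFrame:
        """Predicted shifts for every residue and requested atom.

        phi of residue 1 is undefined in the coarse model; it is treated
        as sitting at the basin centre so that only psi discriminates.
        """
        unknown = set(atoms) - set(ATOMS)
        if unknown:
            raise ValueError(f"unknown atom names: {sorted(unknown)}")
        phi = conf.torsions[:, 0].copy()
        psi = conf.torsions[:, 1]
        if np.isnan(phi[0]):
            phi[0] = self.center[0]
        w = self.basin_weight(phi, psi)
        rows = []
        for i, aa in enumerate(conf.chain.sequence):
            for atom in atoms:
                coil = self.coil[aa][ATOMS.index(atom)]
                rows.append((i + 1, atom,
                             coil + w[i] * self.delta_helix[atom]))
        return pd.DataFrame(rows, columns=["residue", "atom", "shift"])

    def perturbed(self, scale: float = 0.85,
                  center_shift: float = 6.0) -> "ToyShiftPredictor":
        """An independent variant (rescaled secondary shifts, displaced
        basin) for cross-validating a refined ensemble against a predictor
        other than the restraining one."""
        return ToyShiftPredictor(
            sigma_deg=self.sigma_deg * 1.15,
            center=(self.center[0] + center_shift,
                    self.center[1] - center_shift),
            delta_helix={a: v * scale for a, v in self.delta_helix.items()},
            coil=self.coil,
            error_estimate=dict(self.error_estimate),
        )


@dataclass
class ReplicaRestraint:
    """Replica-averaged flat-bottom harmonic restraint parameters.

    k in kJ mol^-1 ppm^-2; epsilon (ppm) defaults to the per-row sigma of
    the shift table; n_replicas is the number of simultaneously evolving
    copies whose mean prediction is restrained.
    """

    k: float = 200.0
    epsilon: float | None = None
    n_replicas: int = 4
    nuclei: tuple = ATOMS

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def _merged_predictions(confs, table, restraint, predictor):
    """Mean predicted shift per table row over the given conformations."""
    sel = table.df[table.df.atom.isin(restraint.nuclei)]
    if sel.empty:
        raise ValueError("shift table contains no restrained nuclei")
    preds = [predictor.predict(c) for c in confs]
    stacked = pd.concat(preds).groupby(["residue", "atom"])["shift"].mean()
    merged = sel.merge(stacked.rename("pred"), on=["residue", "atom"],
                       how="left")
    if merged["pred"].isna().any():
        raise ValueError("predictor did not cover all table nuclei")
    return merged


def replica_averaged_energy(replica_confs, table: ChemicalShiftTable,
                            restraint: ReplicaRestraint,
                            predictor: ToyShiftPredictor) -> float:
    """E = k * sum_j max(0, |mean_m pred - exp| - eps_j)^2 (kJ/mol)."""
    if len(replica_confs) != restraint.n_replicas:
        raise ValueError(
            f"expected {restraint.n_replicas} replica conformations, "
            f"got {len(replica_confs)}")
    merged = _merged_predictions(replica_confs, table, restraint, predictor)
    eps = (merged["sigma"].to_numpy() if restraint.epsilon is None
           else np.full(len(merged), restraint.epsilon))
    excess = np.abs(merged["pred"] - merged["shift"]).to_numpy() - eps
    return float(restraint.k * np.sum(np.maximum(0.0, excess) ** 2))


def backcalc_validate(ensemble, table: ChemicalShiftTable,
                      predictor: ToyShiftPredictor,
                      nuclei=ATOMS) -> pd.DataFrame:
    """Per-nucleus-type deviation report of ensemble-mean back-calculated
    shifts against the table.

    Returns one row per atom type with the mean deviation and the RMS
    deviation about zero of (mean-predicted - experimental) over residues,
    the predictor's error estimate, and PASS iff the RMS deviation is
    within the error estimate (a constant offset therefore fails, unlike a
    mean-centred SD).  Cross-validation should use a predictor different
    from the restraining one (see :meth:`ToyShiftPredictor.perturbed`).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    restraint = ReplicaRestraint(n_replicas=1, nuclei=tuple(nuclei))
    merged = _merged_predictions(
        [ensemble[f] for f in range(len(ensemble))], table, restraint,
        predictor)
    merged["dev"] = merged["pred"] - merged["shift"]
    rows = []
    for atom, grp in merged.groupby("atom"):
        rms = float(np.sqrt(np.mean(grp["dev"] ** 2)))
        err = predictor.error_estimate[atom]
        rows.append((atom, float(grp["dev"].mean()), rms, err, rms <= err))
    return pd.DataFrame(
        rows, columns=["atom", "mean_dev", "sd_dev", "error_estimate",
                       "passed"])
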