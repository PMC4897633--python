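"""Coarse peptide representation.

Each residue carries five sites: backbone N, CA, C, O plus a single
sidechain centroid (SC).  Glycine's centroid coincides with CA.  The
representation is deliberately minimal: every descriptor and analysis in
this package is defined on CA/centroid geometry, which is sufficient for
helix RMSD, dipole moments, contact occupancies and membrane depths.

Residue classification tables (charge class, hydrophobicity, centroid
geometry) are module-level constants and can be overridden per chain,
e.g. from a YAML file via :func:`tables_from_yaml`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: N-terminal 30 residues of human alpha-synuclein (the membrane anchor).
AS1_30 = "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAA"

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

#: Sidechain charge class at neutral pH (formal charges; His treated neutral).
CHARGE_CLASS = {aa: "0" for aa in THREE_LETTER}
CHARGE_CLASS.update({"K": "+", "R": "+", "D": "-", "E": "-"})

#: Hydrophobic residues for contact-map purposes.
HYDROPHOBIC = frozenset("AVLIMF")

#: Distance (Angstrom) of the sidechain centroid from CA, per residue type.
#: Approximate heavy-atom sidechain centroid distances.
SC_DISTANCE = {
    "G": 0.00, "A": 1.53, "S": 1.90, "C": 2.05, "T": 1.95, "V": 1.97,
    "P": 1.85, "I": 2.30, "L": 2.60, "N": 2.50, "D": 2.50, "M": 2.95,
    "Q": 3.10, "E": 3.10, "K": 3.50, "H": 3.10, "F": 3.41, "R": 4.10,
    "Y": 3.85, "W": 3.80,
}

#: Nominal sidechain radius (Angstrom) used for excluded volume and SASA.
SC_RADIUS = {
    "G": 0.00, "A": 1.80, "S": 1.90, "C": 2.10, "T": 2.10, "V": 2.30,
    "P": 2.20, "I": 2.45, "L": 2.50, "N": 2.30, "D": 2.20, "M": 2.50,
    "Q": 2.40, "E": 2.30, "K": 2.40, "H": 2.50, "F": 2.80, "R": 2.60,
    "Y": 2.90, "W": 3.00,
}

#: Coarse van der Waals radii for the backbone sites (Angstrom).
BACKBONE_RADII = {"N": 1.55, "CA": 1.70, "C": 1.70, "O": 1.52}

ATOM_NAMES = ("N", "CA", "C", "O", "SC")


def tables_from_yaml(path) -> dict:
    """Load residue-table overrides from a YAML file.

    Recognised top-level keys: ``charge_class`` (one-letter residue ->
    "+"/"-"/"0"), ``hydrophobic`` (list of one-letter residues),
    ``sc_distance`` and ``sc_radius`` (one-letter residue -> Angstrom).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    allowed = {"charge_class", "hydrophobic", "sc_distance", "sc_radius"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown residue-table keys: {sorted(unknown)}")
    return data


@dataclass(frozen=True)
class PeptideChain:
    """A peptide sequence plus per-residue coarse-model parameters.

    Residue indexing is 1-based throughout the public API (``residue 1``
    is the N-terminal residue); internal arrays are 0-based.
    """

    sequence: str
    charge_class: tuple = field(default=None)   # per residue: "+", "-", "0"
    hydrophobic: tuple = field(default=None)    # per residue: bool
    sc_distance: np.ndarray = field(default=None, repr=False)
    sc_radius: np.ndarray = field(default=None, repr=False)
    nterm_positive: bool = True

    @classmethod
    def from_sequence(cls, sequence: str, overrides: dict | None = None,
                      nterm_positive: bool = True) -> "PeptideChain":
        sequence = sequence.upper().strip()
        if len(sequence) < 2:
            raise ValueError("chain must have at least 2 residues")
        bad = [aa for aa in sequence if aa not in THREE_LETTER]
        if bad:
            raise ValueError(f"unknown residue letters: {bad}")
        overrides = overrides or {}
        cc = dict(CHARGE_CLASS, **overrides.get("charge_class", {}))
        hyd = set(overrides.get("hydrophobic", HYDROPHOBIC))
        scd = dict(SC_DISTANCE, **overrides.get("sc_distance", {}))
        scr = dict(SC_RADIUS, **overrides.get("sc_radius", {}))
        return cls(
            sequence=sequence,
            charge_class=tuple(cc[aa] for aa in sequence),
            hydrophobic=tuple(aa in hyd for aa in sequence),
            sc_distance=np.array([scd[aa] for aa in sequence]),
            sc_radius=np.array([scr[aa] for aa in sequence]),
            nterm_positive=nterm_positive,
        )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_name(self, i: int) -> str:
        """Three-letter residue name for 1-based residue index ``i``."""
        return THREE_LETTER[self.sequence[i - 1]]

    def positive_residues(self) -> list:
        """1-based indices of positively charged sidechains."""
        return [i + 1 for i, c in enumerate(self.charge_class) if c == "+"]

    def negative_residues(self) -> list:
        """1-based indices of negatively charged sidechains."""
        return [i + 1 for i, c in enumerate(self.charge_class) if c == "-"]

    def hydrophobic_residues(self) -> list:
        """1-based indices of hydrophobic residues."""
        return [i + 1 for i, h in enumerate(self.hydrophobic) if h]

    def formal_charges(self, include_nterm: bool = True) -> np.ndarray:
        """Formal charges (e) as an (n_residues, 5) array over N,CA,C,O,SC.

        Charged sidechain centroids carry +/-1 e; the N-terminal amine
        (the N atom of residue 1) carries +1 e when ``include_nterm``.
        Backbone partial dipoles are not included by default.
        """
        q = np.zeros((self.n_residues, 5))
        for i, c in enumerate(self.charge_class):
            if c == "+":
                q[i, 4] = 1.0
            elif c == "-":
                q[i, 4] = -1.0
        if include_nterm and self.nterm_positive:
            q[0, 0] = 1.0
        return q

    def atom_radii(self) -> np.ndarray:
        """(n_residues, 5) coarse radii (Angstrom) over N,CA,C,O,SC."""
        r = np.empty((self.n_residues, 5))
        r[:, 0] = BACKBONE_RADII["N"]
        r[:, 1] = BACKBONE_RADII["CA"]
        r[:, 2] = BACKBONE_RADII["C"]
        r[:, 3] = BACKBONE_RADII["O"]
        r[:, 4] = self.sc_radius
        return r


def alpha_synuclein_anchor() -> PeptideChain:
    """The alpha-synuclein 1-30 membrane-anchor chain fixture."""
    return PeptideChain.from_sequence(AS1_30)
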