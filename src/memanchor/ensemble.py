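"""Ensemble container and multi-model PDB I/O.

An :class:`Ensemble` is an ordered set of coarse conformations sharing one
:class:`~memanchor.chain.PeptideChain`, with per-frame provenance
(replica id, annealing cycle, temperature) and uniform weights.

Ensembles serialise to multi-model PDB (MODEL/ENDMDL records) with the
coarse atoms named N, CA, C, O, SC and 1-based residue numbering, via
biotite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chain import ATOM_NAMES, ONE_LETTER, PeptideChain
from .geometry import Conformation, torsions_from_cartesian


@dataclass
class Ensemble:
    """Frames share one chain; weights are uniform."""

    chain: PeptideChain
    coords: np.ndarray                 # (F, n_res, 5, 3) Angstrom
    torsions: np.ndarray               # (F, n_res, 2) degrees
    replica: np.ndarray = None         # (F,) int
    cycle: np.ndarray = None           # (F,) int
    temperature: np.ndarray = None     # (F,) K

    def __post_init__(self):
        f = self.coords.shape[0]
        if self.coords.shape[1] != len(self.chain):
            raise ValueError("coords do not match chain length")
        if self.replica is None:
            self.replica = np.zeros(f, dtype=int)
        if self.cycle is None:
            self.cycle = np.zeros(f, dtype=int)
        if self.temperature is None:
            self.temperature = np.full(f, np.nan)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """Uniform frame weights summing to 1."""
        return np.full(len(self), 1.0 / len(self))

    def __getitem__(self, f: int) -> Conformation:
        return Conformation(self.chain, self.torsions[f].copy(),
                            self.coords[f].copy())

    @classmethod
    def from_conformations(cls, confs, replica=None, cycle=None,
                           temperature=None) -> "Ensemble":
        confs = list(confs)
        if not confs:
            raise ValueError("empty conformation list")
        chain = confs[0].chain
        if any(c.chain.sequence != chain.sequence for c in confs):
            raise ValueError("all frames must share one chain")
        coords = np.stack([c.coords for c in confs])
        torsions = np.stack([c.torsions for c in confs])
        return cls(chain, coords, torsions, replica=replica, cycle=cycle,
                   temperature=temperature)

    def subset(self, idx) -> "Ensemble":
        idx = np.asarray(idx)
        return Ensemble(self.chain, self.coords[idx], self.torsions[idx],
                        self.replica[idx], self.cycle[idx],
                        self.temperature[idx])

    # -- PDB I/O -----------------------------------------------------------

    def to_pdb(self, path) -> None:
        """Write a multi-model PDB (atoms N, CA, C, O, SC per residue)."""
        n = len(self.chain)
        n_atoms = n * 5
        template = struc.AtomArray(n_atoms)
        template.chain_id = np.full(n_atoms, "A")
        template.res_id = np.repeat(np.arange(1, n + 1), 5)
        template.res_name = np.repeat(
            [self.chain.residue_name(i) for i in range(1, n + 1)], 5)
        template.atom_name = np.tile(np.array(ATOM_NAMES), n)
        template.element = np.tile(np.array(["N", "C", "C", "O", "C"]), n)
        template.hetero = np.full(n_atoms, False)
        stack = struc.stack([template] * len(self))
        stack.coord = self.coords.reshape(len(self), n_atoms, 3)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))

    @classmethod
    def from_pdb(cls, path, chain: PeptideChain | None = None) -> "Ensemble":
        """Read a multi-model coarse PDB written by :meth:`to_pdb`.

        Torsions are re-extracted from the coordinates (phi of residue 1 is
        NaN).  If ``chain`` is omitted the sequence is inferred from the
        residue names.
        """
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
        if stack.array_length() % 5 != 0:
            raise ValueError("not a coarse 5-site model PDB")
        n = stack.array_length() // 5
        names = stack.atom_name
        if not np.array_equal(names, np.tile(np.array(ATOM_NAMES), n)):
            raise ValueError("unexpected atom ordering; expected "
                             "N, CA, C, O, SC per residue")
        if chain is None:
            seq = "".join(ONE_LETTER[rn] for rn in stack.res_name[::5])
            chain = PeptideChain.from_sequence(seq)
        coords = np.asarray(stack.coord, dtype=float).reshape(-1, n, 5, 3)
        torsions = np.stack([torsions_from_cartesian(c) for c in coords])
        return cls(chain, coords, torsions)
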