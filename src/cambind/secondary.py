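"""Minimal Kabsch-Sander style backbone hydrogen-bond assignment.

Only the alpha-helical 4-turn pattern is implemented: it is sufficient to
segment a bound helical peptide into helix runs separated by turns.  Amide
hydrogens are placed geometrically because crystal structures carry none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_io import AtomRecord, StructureFrame

__all__ = [
    "BackboneHBond",
    "HBOND_ENERGY_CUTOFF",
    "CLASH_ENERGY",
    "place_amide_hydrogens",
    "hbond_energy",
    "assign_helix",
    "helix_segments",
]

# E = Q * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN), kcal/mol
_KS_Q = 27.888
HBOND_ENERGY_CUTOFF = -0.5   # bond called when E < cutoff (strict)
CLASH_ENERGY = -9.9          # sentinel for r < 0.5 A overlaps
_N_H_LENGTH = 1.0


@dataclass(frozen=True)
class BackboneHBond:
    donor_residue: tuple[str, int]      # (chain, residue_seq) providing N-H
    acceptor_residue: tuple[str, int]   # (chain, residue_seq) providing C=O
    energy: float


def _atom_map(atoms: list[AtomRecord]) -> dict[str, AtomRecord]:
    return {a.atom_name: a for a in atoms}


def place_amide_hydrogens(frame: StructureFrame, chain: str
                          ) -> StructureFrame:
    """Return a copy of ``frame`` with one amide H added per eligible residue.

    H sits 1.0 A from N, in the C(i-1)/N(i)/CA(i) plane, along the outward
    bisector of the C(i-1)->N and CA->N directions.  Prolines and the
    chain-initial residue get no H; residues with missing backbone atoms are
    skipped with a warning.
    """
    out = frame.copy()
    residues = out.residues(chain, hetero=False)
    seqs = list(residues)
    new_atoms: list[AtomRecord] = []
    for idx, seq in enumerate(seqs):
        atoms = _atom_map(residues[seq])
        if idx == 0 or atoms.get("N") is None:
            continue
        if residues[seq][0].residue_name == "PRO":
            continue
        prev = _atom_map(residues[seqs[idx - 1]])
        missing = [n for n in ("N", "CA") if n not in atoms]
        if "C" not in prev:
            missing.append("C(i-1)")
        if missing:
            warnings.warn(f"chain {chain} residue {seq}: backbone atoms "
                          f"{missing} missing; no amide H placed")
            continue
        n_pos = atoms["N"].coords
        if np.linalg.norm(n_pos - prev["C"].coords) > 2.5:
            continue  # chain break: no peptide bond to receive H from
        u = n_pos - prev["C"].coords
        v = n_pos - atoms["CA"].coords
        direction = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        direction /= np.linalg.norm(direction)
        template = atoms["N"]
        new_atoms.append(AtomRecord(
            "H", "H", "", n_pos + _N_H_LENGTH * direction, 1.0, 0.0,
            template.residue_name, seq, chain, False,
            template.insertion_code))
    out.atoms.extend(new_atoms)
    return StructureFrame(out.atoms, out.model_index, out.metadata)


def hbond_energy(donor_atoms: list[AtomRecord],
                 acceptor_atoms: list[AtomRecord]) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol).

    Donor residue supplies N and H, acceptor supplies C and O.  Any
    inter-atom distance below 0.5 A returns the clash sentinel.
    """
    d = _atom_map(donor_atoms)
    a = _atom_map(acceptor_atoms)
    for name, pool in (("N", d), ("H", d), ("C", a), ("O", a)):
        if name not in pool:
            raise ValueError(f"hbond_energy: required atom {name} missing")
    r_on = np.linalg.norm(a["O"].coords - d["N"].coords)
    r_ch = np.linalg.norm(a["C"].coords - d["H"].coords)
    r_oh = np.linalg.norm(a["O"].coords - d["H"].coords)
    r_cn = np.linalg.norm(a["C"].coords - d["N"].coords)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        warnings.warn("hbond_energy: atomic clash (r < 0.5 A); "
                      "capped at sentinel energy")
        return CLASH_ENERGY
    energy = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(max(energy, CLASH_ENERGY))


def _four_turn_bonds(frame: StructureFrame, chain: str
                     ) -> tuple[list[int], list[bool], list[BackboneHBond]]:
    residues = frame.residues(chain, hetero=False)
    seqs = list(residues)
    bonds: list[BackboneHBond] = []
    turn = [False] * len(seqs)
    for i in range(len(seqs) - 4):
        acceptor = residues[seqs[i]]
        donor = residues[seqs[i + 4]]
        try:
            e = hbond_energy(donor, acceptor)
        except ValueError:
            continue
        if e < HBOND_ENERGY_CUTOFF:
            turn[i] = True
            bonds.append(BackboneHBond((chain, seqs[i + 4]),
                                       (chain, seqs[i]), e))
    return seqs, turn, bonds


def assign_helix(frame: StructureFrame, chain: str) -> dict[int, str]:
    """Per-residue helix labels ('H' or '-') for one chain.

    Residues i..i+3 are helical when 4-turns start at both i-1 and i,
    i.e. two consecutive i->i+4 hydrogen bonds support the turn.  Chains
    shorter than 5 residues are all '-'.
    """
    work = frame
    if not any(a.atom_name == "H" and a.chain_id == chain
               for a in frame.atoms):
        work = place_amide_hydrogens(frame, chain)
    residues = work.residues(chain, hetero=False)
    seqs = list(residues)
    labels = {s: "-" for s in seqs}
    if len(seqs) < 5:
        return labels
    _, turn, _ = _four_turn_bonds(work, chain)
    for i in range(1, len(seqs) - 3):
        if turn[i - 1] and turn[i]:
            for j in range(i, i + 4):
                labels[seqs[j]] = "H"
    return labels


def helix_segments(labels: dict[int, str]) -> list[tuple[int, int]]:
    """Contiguous (start_seq, end_seq) runs labelled 'H'."""
    runs: list[tuple[int, int]] = []
    start = None
    prev = None
    for seq, lab in labels.items():
        if lab == "H":
            if start is None or (prev is not None and seq != prev + 1):
                if start is not None:
                    runs.append((start, prev))
                start = seq
            prev = seq
        else:
            if start is not None:
                runs.append((start, prev))
                start = None
    if start is not None:
        runs.append((start, prev))
    return runs
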