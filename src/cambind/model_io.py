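"""Coordinate-file parsing, chain pairing and report writing.

PDB-format text (ATOM/HETATM/MODEL/ENDMDL/SEQRES) is the input contract.
Single-model files yield a :class:`StructureFrame`; multi-model files yield a
:class:`Trajectory` whose frames share one atom-identity list.  Alternate
locations are collapsed to the highest-occupancy conformer (ties keep the
first encountered), so downstream analyses always see one position per atom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "StructureFrame",
    "Trajectory",
    "ComplexPairing",
    "ParseError",
    "ChainNotFoundError",
    "read_structure",
    "write_structure",
    "pair_complexes",
    "extract_sequence",
    "write_report",
    "read_fasta",
    "write_fasta",
]

# Residues shorter than this are "peptide-like"; longer chains are
# "CaM-like" (melittin has 26 residues, CaM about 148).
PEPTIDE_MAX_RESIDUES = 40

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}

_ION_ELEMENTS = {"CA": "CA", "MG": "MG", "ZN": "ZN", "NA": "NA", "K": "K",
                 "CL": "CL", "MN": "MN", "FE": "FE"}


class ParseError(ValueError):
    """Malformed coordinate file."""


class ChainNotFoundError(KeyError):
    """Requested chain (or model) is absent."""


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    alt_loc: str
    coords: np.ndarray  # float64 (3,)  Angstrom
    occupancy: float
    b_factor: float
    residue_name: str
    residue_seq: int
    chain_id: str
    is_hetero: bool
    insertion_code: str = ""

    def key(self) -> tuple:
        """Identity of the atom within a frame (alt-locs already collapsed)."""
        return (self.chain_id, self.residue_seq, self.insertion_code,
                self.atom_name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_sidechain(self) -> bool:
        return (not self.is_hydrogen and not self.is_hetero
                and self.atom_name not in BACKBONE_NAMES)


class StructureFrame:
    """One coordinate model: an ordered collection of atoms plus metadata."""

    def __init__(self, atoms: Sequence[AtomRecord], model_index: int = 1,
                 metadata: dict | None = None):
        self.atoms = list(atoms)
        self.model_index = model_index
        self.metadata = dict(metadata or {})
        seen = set()
        for a in self.atoms:
            k = a.key() + (a.alt_loc,)
            if k in seen:
                raise ParseError(f"duplicate atom {k} within one model")
            seen.add(k)

    # -- access helpers -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def chain_atoms(self, chain: str, hetero: bool | None = None
                    ) -> list[AtomRecord]:
        sel = [a for a in self.atoms if a.chain_id == chain]
        if hetero is not None:
            sel = [a for a in sel if a.is_hetero == hetero]
        return sel

    def residues(self, chain: str, hetero: bool | None = False
                 ) -> dict[int, list[AtomRecord]]:
        """Ordered residue_seq -> atoms mapping for one chain."""
        out: dict[int, list[AtomRecord]] = {}
        for a in self.chain_atoms(chain, hetero=hetero):
            out.setdefault(a.residue_seq, []).append(a)
        return out

    def residue_atoms(self, chain: str, residue_seq: int) -> list[AtomRecord]:
        sel = [a for a in self.atoms
               if a.chain_id == chain and a.residue_seq == residue_seq]
        if not sel:
            raise ChainNotFoundError(
                f"residue {residue_seq} of chain {chain!r} not found")
        return sel

    def coords(self, atoms: Iterable[AtomRecord] | None = None) -> np.ndarray:
        pool = self.atoms if atoms is None else list(atoms)
        if not pool:
            return np.empty((0, 3))
        return np.vstack([a.coords for a in pool])

    def atom_keys(self) -> list[tuple]:
        return [a.key() for a in self.atoms]

    def copy(self) -> "StructureFrame":
        atoms = [AtomRecord(a.atom_name, a.element, a.alt_loc,
                            a.coords.copy(), a.occupancy, a.b_factor,
                            a.residue_name, a.residue_seq, a.chain_id,
                            a.is_hetero, a.insertion_code)
                 for a in self.atoms]
        return StructureFrame(atoms, self.model_index, dict(self.metadata))


@dataclass
class Trajectory:
    """Ordered frames sharing a single per-atom identity list."""

    frames: list[StructureFrame]
    frame_stride_note: str = ""

    def __post_init__(self):
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        key0 = self.frames[0].atom_keys()
        for i, fr in enumerate(self.frames[1:], start=2):
            if fr.atom_keys() != key0:
                raise ValueError(f"model {i} has a different atom identity "
                                 "list from model 1")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def topology_key(self) -> list[tuple]:
        return self.frames[0].atom_keys()

    def coords_array(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        stack = np.stack([f.coords() for f in self.frames])
        if indices is not None:
            stack = stack[:, list(indices), :]
        return stack


@dataclass(frozen=True)
class ComplexPairing:
    cam_chain: str
    peptide_chain: str
    label: str = ""


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _guess_element(name: str, residue_name: str, hetero: bool) -> str:
    if hetero and residue_name.strip() in _ION_ELEMENTS:
        return _ION_ELEMENTS[residue_name.strip()]
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        return "C"
    if stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "SE"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int, hetero: bool) -> AtomRecord:
    try:
        name = line[12:16].strip()
        alt = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21]
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_s = line[54:60].strip()
        b_s = line[60:66].strip()
        occ = float(occ_s) if occ_s else 1.0
        b = float(b_s) if b_s else 0.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: "
                         f"{line.rstrip()!r}") from exc
    if not name:
        raise ParseError(f"missing atom name at line {lineno}")
    if not element:
        element = _guess_element(name, resname, hetero)
    coords = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ParseError(f"non-finite coordinates at line {lineno}")
    return AtomRecord(name, element, alt, coords, occ, b, resname,
                      resseq, chain.strip() or " ", hetero, icode)


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    best: dict[tuple, int] = {}
    out: list[AtomRecord] = []
    for a in atoms:
        k = a.key()
        if k not in best:
            best[k] = len(out)
            out.append(a)
        else:
            # keep the highest occupancy; tie keeps the first encountered
            if a.occupancy > out[best[k]].occupancy:
                out[best[k]] = a
    return out


def read_structure(path: str | Path, model: int | str | None = None
                   ) -> StructureFrame | Trajectory:
    """Read a PDB-format file.

    Parameters
    ----------
    path:
        PDB-format text file.
    model:
        ``None`` returns a single :class:`StructureFrame` for single-model
        files and a :class:`Trajectory` for multi-model files; an integer
        selects one model (1-based); ``"all"`` always returns a
        :class:`Trajectory`.
    """
    path = Path(path)
    seqres: dict[str, list[str]] = {}
    header: list[str] = []
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "ATOM  " or rec == "HETATM":
                current.append(_parse_atom_line(line, lineno,
                                                hetero=rec == "HETATM"))
            elif rec.startswith("MODEL"):
                if current and not in_model:
                    models.append(current)
                    current = []
                in_model = True
            elif rec.startswith("ENDMDL"):
                models.append(current)
                current = []
                in_model = False
            elif rec == "SEQRES":
                chain = line[11].strip() or " "
                seqres.setdefault(chain, []).extend(line[19:].split())
            elif rec.startswith(("HEADER", "TITLE ", "COMPND")):
                header.append(line.rstrip())
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")

    metadata: dict = {}
    if seqres:
        metadata["seqres"] = seqres
    if header:
        metadata["header"] = header

    frames = [StructureFrame(_collapse_altlocs(m), model_index=i + 1,
                             metadata=metadata)
              for i, m in enumerate(models)]

    if isinstance(model, int):
        for fr in frames:
            if fr.model_index == model:
                return fr
        raise ChainNotFoundError(f"model {model} not present in {path} "
                                 f"({len(frames)} model(s))")
    if model == "all":
        return Trajectory(frames)
    if model is None:
        return frames[0] if len(frames) == 1 else Trajectory(frames)
    raise ValueError(f"model must be an integer, 'all' or None, got {model!r}")


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _atom_line(a: AtomRecord, serial: int) -> str:
    rec = "HETATM" if a.is_hetero else "ATOM  "
    name = _format_atom_name(a.atom_name, a.element)
    return (f"{rec}{serial % 100000:5d} {name}{a.alt_loc[:1] or ' '}"
            f"{a.residue_name:>3} {a.chain_id[:1]}{a.residue_seq:4d}"
            f"{a.insertion_code[:1] or ' '}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2}")


def write_structure(obj: StructureFrame | Trajectory, path: str | Path
                    ) -> None:
    """Write a frame or trajectory as PDB-format text."""
    path = Path(path)
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    lines: list[str] = []
    seqres = frames[0].metadata.get("seqres")
    if seqres:
        for chain, resnames in seqres.items():
            for i in range(0, len(resnames), 13):
                chunk = resnames[i:i + 13]
                lines.append(f"SEQRES {i // 13 + 1:3d} {chain[:1]} "
                             f"{len(resnames):4d}  " + " ".join(chunk))
    multi = len(frames) > 1
    for fr in frames:
        if multi:
            lines.append(f"MODEL {fr.model_index:8d}")
        serial = 0
        for a in fr.atoms:
            serial += 1
            lines.append(_atom_line(a, serial))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Chain pairing
# ---------------------------------------------------------------------------

def _polymer_residue_count(frame: StructureFrame, chain: str) -> int:
    return len(frame.residues(chain, hetero=False))


def classify_chains(frame: StructureFrame
                    ) -> tuple[list[str], list[str]]:
    """Split chains into (CaM-like, peptide-like) by polymer length."""
    cam, pep = [], []
    for chain in frame.chains():
        n = _polymer_residue_count(frame, chain)
        if n == 0:
            continue
        (pep if n <= PEPTIDE_MAX_RESIDUES else cam).append(chain)
    return cam, pep


def _contact_count(frame: StructureFrame, chain_a: str, chain_b: str,
                   cutoff: float) -> int:
    xa = [a for a in frame.chain_atoms(chain_a, hetero=False)
          if not a.is_hydrogen]
    xb = [a for a in frame.chain_atoms(chain_b, hetero=False)
          if not a.is_hydrogen]
    if not xa or not xb:
        return 0
    ta = cKDTree(frame.coords(xa))
    tb = cKDTree(frame.coords(xb))
    return int(ta.count_neighbors(tb, cutoff))


def pair_complexes(frame: StructureFrame, cutoff: float = 4.0
                   ) -> list[ComplexPairing]:
    """Pair each peptide-length chain with its contacting CaM-length chain.

    The CaM chain with the most inter-chain non-hydrogen atom pairs within
    ``cutoff`` wins.  Peptides with no contacts are dropped with a warning.
    """
    cam_chains, pep_chains = classify_chains(frame)
    if not cam_chains or not pep_chains:
        raise ValueError("need at least one CaM-length chain (>%d residues) "
                         "and one peptide chain" % PEPTIDE_MAX_RESIDUES)
    pairings: list[ComplexPairing] = []
    for pep in pep_chains:
        counts = {cam: _contact_count(frame, cam, pep, cutoff)
                  for cam in cam_chains}
        best = max(sorted(counts), key=lambda c: counts[c])
        if counts[best] == 0:
            warnings.warn(f"peptide chain {pep!r} has no contacts within "
                          f"{cutoff} A of any CaM chain; excluded")
            continue
        pairings.append(ComplexPairing(best, pep, label=f"{best}/{pep}"))
    return pairings


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def extract_sequence(frame: StructureFrame, chain: str,
                     source: str = "coords") -> str:
    """One-letter sequence of a chain from SEQRES or from modelled residues."""
    if source == "seqres":
        seqres = frame.metadata.get("seqres", {})
        if chain not in seqres:
            raise ChainNotFoundError(f"no SEQRES for chain {chain!r}")
        return "".join(THREE_TO_ONE.get(r, "X") for r in seqres[chain])
    if source == "coords":
        residues = frame.residues(chain, hetero=False)
        if not residues:
            raise ChainNotFoundError(f"chain {chain!r} has no polymer atoms")
        return "".join(THREE_TO_ONE.get(atoms[0].residue_name, "X")
                       for atoms in residues.values())
    raise ValueError(f"source must be 'seqres' or 'coords', got {source!r}")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line
    return out


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_ONE_DP = ("angle", "dihedral", "bend")
_TWO_DP = ("occupancy", "fraction", "identity", "distance", "rmsd", "com")


def _format_value(column: str, value):
    col = column.lower()
    if isinstance(value, (float, np.floating)):
        if any(k in col for k in _ONE_DP):
            return round(float(value), 1)
        if any(k in col for k in _TWO_DP):
            return round(float(value), 2)
        return float(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    return value


def _as_rows(table) -> tuple[list[str], list[dict]]:
    if isinstance(table, pd.DataFrame):
        return list(table.columns), table.to_dict(orient="records")
    rows = list(table)
    cols: list[str] = []
    for r in rows:
        for c in r:
            if c not in cols:
                cols.append(c)
    return cols, rows


def write_report(tables: Mapping[str, object], path: str | Path,
                 format: str = "tsv") -> None:
    """Write named analysis tables with deterministic column order.

    Angles are printed with one decimal, fractions with two.  The JSON form
    round-trips losslessly through :func:`json.load`.
    """
    path = Path(path)
    if format == "json":
        payload = {}
        for name, table in tables.items():
            cols, rows = _as_rows(table)
            payload[name] = [
                {c: _format_value(c, r.get(c)) for c in cols} for r in rows]
        path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    lines: list[str] = []
    for name, table in tables.items():
        cols, rows = _as_rows(table)
        if len(tables) > 1:
            lines.append(f"# table: {name}")
        lines.append("\t".join(cols))
        for r in rows:
            lines.append("\t".join(str(_format_value(c, r.get(c, "")))
                                   for c in cols))
    path.write_text("\n".join(lines) + "\n")
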