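"""Chemical cross-linking distance-restraint validation over ensembles.

A restraint is satisfied when, in at least one frame, the minimum distance
between the reactive groups of the two residues is below the reagent cutoff
(strict <).  EDC measures amine-N to carboxyl-O; sulfo-DST and BS3 are
amine-amine.  Residues whose reactive atoms are absent from every frame are
reported as unevaluable, which is distinct from unsatisfied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_io import (AtomRecord, ChainNotFoundError, ComplexPairing,
                       StructureFrame, Trajectory)

__all__ = [
    "REAGENT_CUTOFFS",
    "NEAR_MISS_FACTOR",
    "RestraintSpec",
    "RestraintResult",
    "reactive_atoms",
    "evaluate_restraint",
    "restraint_report",
    "read_restraints",
]

REAGENT_CUTOFFS = {"EDC": 5.0, "sulfo-DST": 8.5, "BS3": 13.4}
# Chemistry of each reagent: roles of (residue_a, residue_b).
_REAGENT_ROLES = {"EDC": ("carboxyl", "amine"),
                  "sulfo-DST": ("amine", "amine"),
                  "BS3": ("amine", "amine")}
NEAR_MISS_FACTOR = 1.2

_AMINE_RESIDUES = {"LYS": ("NZ",)}
_CARBOXYL_RESIDUES = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


@dataclass(frozen=True)
class RestraintSpec:
    reagent: str
    residue_a: tuple[str, int]          # (chain role or chain id, residue)
    residue_b: tuple[str, int]
    cutoff: float | None = None         # per-restraint override
    alt_candidates: tuple[tuple[str, int], ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.reagent not in REAGENT_CUTOFFS:
            raise ValueError(f"unknown reagent {self.reagent!r}; expected "
                             f"one of {sorted(REAGENT_CUTOFFS)}")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def effective_cutoff(self) -> float:
        return self.cutoff if self.cutoff is not None \
            else REAGENT_CUTOFFS[self.reagent]

    @property
    def roles(self) -> tuple[str, str]:
        return _REAGENT_ROLES[self.reagent]


@dataclass
class RestraintResult:
    spec: RestraintSpec
    min_distance: float                 # nan when unevaluable
    frames_satisfied: int
    satisfied: bool
    near_miss: bool
    unevaluable: bool = False
    alt_within: list[tuple[str, int]] = field(default_factory=list)

    @property
    def status(self) -> str:
        if self.unevaluable:
            return "unevaluable"
        if self.satisfied:
            return "satisfied"
        if self.near_miss:
            return "near"
        return "unsatisfied"


def reactive_atoms(residue_atoms: list[AtomRecord], role: str,
                   chain_initial: bool = False) -> list[AtomRecord]:
    """Reactive-group atoms of one residue for a given chemistry role.

    Amine: Lys NZ, or the backbone N of the chain-initial residue (the
    alpha-amine).  Carboxyl: Glu OE1/OE2 or Asp OD1/OD2.
    """
    if not residue_atoms:
        raise ValueError("empty residue")
    resname = residue_atoms[0].residue_name
    if role == "amine":
        names = _AMINE_RESIDUES.get(resname)
        if names is None:
            if chain_initial:
                names = ("N",)
            else:
                raise ValueError(f"residue {resname} cannot act as an amine "
                                 "(not Lys and not chain-initial)")
        elif chain_initial:
            names = names + ("N",)
    elif role == "carboxyl":
        names = _CARBOXYL_RESIDUES.get(resname)
        if names is None:
            raise ValueError(f"residue {resname} cannot act as a carboxyl")
    else:
        raise ValueError(f"role must be 'amine' or 'carboxyl', got {role!r}")
    return [a for a in residue_atoms if a.atom_name in names]


def _resolve_chain(role_or_chain: str, pairing: ComplexPairing | None) -> str:
    if pairing is not None:
        if role_or_chain.lower() in ("cam", "protein"):
            return pairing.cam_chain
        if role_or_chain.lower() in ("peptide", "pep", "melittin"):
            return pairing.peptide_chain
    return role_or_chain


def _reactive_coords(frame: StructureFrame, chain: str, seq: int,
                     role: str) -> np.ndarray:
    try:
        atoms = frame.residue_atoms(chain, seq)
    except ChainNotFoundError:
        return np.empty((0, 3))
    polymer = [a for a in atoms if not a.is_hetero]
    if not polymer:
        return np.empty((0, 3))
    first_seq = min(frame.residues(chain, hetero=False))
    try:
        reactive = reactive_atoms(polymer, role,
                                  chain_initial=seq == first_seq)
    except ValueError:
        raise
    if not reactive:
        return np.empty((0, 3))
    return np.vstack([a.coords for a in reactive])


def evaluate_restraint(ensemble: Trajectory | StructureFrame,
                       spec: RestraintSpec,
                       pairing: ComplexPairing | None = None
                       ) -> RestraintResult:
    """Minimum reactive-group distance over the ensemble and its verdict."""
    frames = ensemble.frames if isinstance(ensemble, Trajectory) \
        else [ensemble]
    role_a, role_b = spec.roles
    chain_a = _resolve_chain(spec.residue_a[0], pairing)
    chain_b = _resolve_chain(spec.residue_b[0], pairing)
    cutoff = spec.effective_cutoff
    min_d = math.inf
    n_sat = 0
    for fr in frames:
        ca = _reactive_coords(fr, chain_a, spec.residue_a[1], role_a)
        cb = _reactive_coords(fr, chain_b, spec.residue_b[1], role_b)
        if ca.size == 0 or cb.size == 0:
            continue
        d = float(cdist(ca, cb).min())
        min_d = min(min_d, d)
        if d < cutoff:
            n_sat += 1
    if math.isinf(min_d):
        return RestraintResult(spec, math.nan, 0, satisfied=False,
                               near_miss=False, unevaluable=True)
    alt_within = []
    for alt in spec.alt_candidates:
        alt_chain = _resolve_chain(alt[0], pairing)
        for fr in frames:
            ca = _reactive_coords(fr, chain_a, spec.residue_a[1], role_a)
            cb = _reactive_coords(fr, alt_chain, alt[1], role_b)
            if ca.size and cb.size and float(cdist(ca, cb).min()) < cutoff:
                alt_within.append(alt)
                break
    satisfied = n_sat >= 1
    near = (not satisfied) and min_d < NEAR_MISS_FACTOR * cutoff
    return RestraintResult(spec, min_d, n_sat, satisfied, near,
                           alt_within=alt_within)


def restraint_report(results: list[RestraintResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "restraint": r.spec.label or
            f"{r.spec.residue_a[0]}{r.spec.residue_a[1]}-"
            f"{r.spec.residue_b[0]}{r.spec.residue_b[1]}",
            "reagent": r.spec.reagent,
            "cutoff": r.spec.effective_cutoff,
            "min_distance": "" if r.unevaluable else round(r.min_distance, 2),
            "frames_satisfied": r.frames_satisfied,
            "status": r.status,
        })
    return pd.DataFrame(rows, columns=["restraint", "reagent", "cutoff",
                                       "min_distance", "frames_satisfied",
                                       "status"])


def read_restraints(path: str | Path) -> list[RestraintSpec]:
    """Read a restraint table: TSV columns
    reagent, chainA, resA, chainB, resB[, cutoff][, alternatives].

    ``alternatives`` is a comma-separated list of chain:residue entries for
    ambiguous cross-links.  Unknown reagents raise an error naming the row.
    """
    specs: list[RestraintSpec] = []
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if lines and lines[0].lower().startswith("reagent"):
        lines = lines[1:]
    for row_no, line in enumerate(lines, start=1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 5:
            raise ValueError(f"restraint row {row_no}: expected at least 5 "
                             f"tab-separated fields, got {len(parts)}")
        reagent, chain_a, res_a, chain_b, res_b = parts[:5]
        if reagent not in REAGENT_CUTOFFS:
            raise ValueError(f"restraint row {row_no}: unknown reagent "
                             f"{reagent!r}")
        cutoff = None
        if len(parts) > 5 and parts[5].strip():
            cutoff = float(parts[5])
        alts: tuple[tuple[str, int], ...] = ()
        if len(parts) > 6 and parts[6].strip():
            alts = tuple((c, int(r)) for c, r in
                         (item.split(":") for item in parts[6].split(",")))
        specs.append(RestraintSpec(reagent, (chain_a, int(res_a)),
                                   (chain_b, int(res_b)), cutoff, alts))
    return specs
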