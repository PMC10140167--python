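"""Binding-mode analytics for CaM-peptide complexes.

Covers the hydrophobic-pocket machinery (FLMM tetrads and anchoring
detection against the pocket side-chain mass center), anchor-spacing motif
labels, salt-bridge occupancy over ensembles, generic contact residues,
tryptophan shielding and peptide orientation.  All distance comparisons are
strict (<).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import center_of_mass, virtual_dihedral
from .model_io import (AtomRecord, ChainNotFoundError, ComplexPairing,
                       StructureFrame, Trajectory)

__all__ = [
    "N_LOBE_FLMM",
    "C_LOBE_FLMM",
    "FLMMPocket",
    "AnalysisConfig",
    "AnchorTimeline",
    "MotifLabel",
    "SaltBridgeStat",
    "default_pockets",
    "pocket_com",
    "detect_anchors",
    "anchor_timeline",
    "classify_motif",
    "salt_bridges",
    "pooled_salt_bridges",
    "contact_residues",
    "trp_shielding",
    "classify_orientation",
    "calcium_sites",
    "lobe_dihedral",
]

# Hydrophobic tetrad residue numbers of the two lobes (author numbering).
N_LOBE_FLMM = (19, 32, 51, 71)
C_LOBE_FLMM = (92, 105, 124, 144)

DONOR_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
ACCEPTOR_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


@dataclass(frozen=True)
class FLMMPocket:
    lobe: str                      # "N" or "C"
    residues: tuple[int, int, int, int]
    chain: str | None = None       # bound to a CaM chain when analysing

    def __post_init__(self):
        if self.lobe not in ("N", "C"):
            raise ValueError("lobe must be 'N' or 'C'")
        if len(self.residues) != 4:
            raise ValueError("a pocket has exactly four residues")


@dataclass(frozen=True)
class AnalysisConfig:
    anchor_com_cutoff: float = 2.5
    contact_cutoff: float = 4.0
    saltbridge_cutoff: float = 4.0
    minor_occupancy: float = 0.10
    major_occupancy: float = 0.50
    shield_occupancy_ref: float = 0.85
    cluster_cutoff_complex: float = 1.5
    cluster_cutoff_peptide: float = 1.0
    shield_cam_residues: tuple[int, ...] = (124, 127, 128)
    shield_peptide_residues: tuple[int, ...] = (23,)

    def __post_init__(self):
        for name in ("anchor_com_cutoff", "contact_cutoff",
                     "saltbridge_cutoff", "cluster_cutoff_complex",
                     "cluster_cutoff_peptide"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("minor_occupancy", "major_occupancy",
                     "shield_occupancy_ref"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class AnchorTimeline:
    pocket: str                        # lobe label
    per_frame: list[set[int]]
    occupancy: dict[int, float]

    def minor(self, threshold: float = 0.10) -> set[int]:
        return {r for r, f in self.occupancy.items() if f < threshold}


@dataclass(frozen=True)
class MotifLabel:
    label: str
    anchor_positions: tuple[int, ...]


@dataclass
class SaltBridgeStat:
    basic_residue: tuple[str, int]
    acidic_residue: tuple[str, int]
    occupancy: float
    min_distance: float
    major: bool = False
    per_run: list[float] = field(default_factory=list)


def default_pockets(cam_chain: str | None = None) -> list[FLMMPocket]:
    return [FLMMPocket("N", N_LOBE_FLMM, cam_chain),
            FLMMPocket("C", C_LOBE_FLMM, cam_chain)]


# ---------------------------------------------------------------------------
# Pockets and anchoring
# ---------------------------------------------------------------------------

def _sidechain_atoms(atoms: list[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if a.is_sidechain]


def pocket_com(frame: StructureFrame, pocket: FLMMPocket,
               cam_chain: str | None = None) -> np.ndarray:
    """Mass center of the pocket residues' side chains, for this frame."""
    chain = cam_chain or pocket.chain
    if chain is None:
        raise ValueError("pocket has no chain bound and none was given")
    residues = frame.residues(chain, hetero=False)
    pool: list[AtomRecord] = []
    for seq in pocket.residues:
        atoms = _sidechain_atoms(residues.get(seq, []))
        if not atoms:
            warnings.warn(f"pocket residue {seq} of chain {chain} has no "
                          "side-chain atoms; mass center uses the rest")
            continue
        pool.extend(atoms)
    if not pool:
        raise ValueError(f"no side-chain atoms found for {pocket.lobe}-lobe "
                         f"pocket on chain {chain}")
    return center_of_mass(pool)


def detect_anchors(frame: StructureFrame, pairing: ComplexPairing,
                   pocket: FLMMPocket, cutoff: float = 2.5) -> set[int]:
    """Peptide residues with a side-chain atom closer than ``cutoff`` to the
    pocket side-chain mass center.  Glycine never anchors."""
    com = pocket_com(frame, pocket, cam_chain=pairing.cam_chain)
    anchors: set[int] = set()
    for seq, atoms in frame.residues(pairing.peptide_chain,
                                     hetero=False).items():
        side = _sidechain_atoms(atoms)
        if not side:
            continue
        d = np.linalg.norm(np.vstack([a.coords for a in side]) - com, axis=1)
        if np.any(d < cutoff):
            anchors.add(seq)
    return anchors


def anchor_timeline(traj: Trajectory, pairing: ComplexPairing,
                    pockets: list[FLMMPocket],
                    config: AnalysisConfig = AnalysisConfig()
                    ) -> dict[str, AnchorTimeline]:
    """Per-lobe anchoring occupancy over a trajectory."""
    out: dict[str, AnchorTimeline] = {}
    for pocket in pockets:
        per_frame = [detect_anchors(fr, pairing, pocket,
                                    config.anchor_com_cutoff)
                     for fr in traj.frames]
        counts: dict[int, int] = {}
        for anchors in per_frame:
            for r in anchors:
                counts[r] = counts.get(r, 0) + 1
        occupancy = {r: c / len(traj) for r, c in sorted(counts.items())}
        out[pocket.lobe] = AnchorTimeline(pocket.lobe, per_frame, occupancy)
    return out


def classify_motif(n_anchors, c_anchors) -> MotifLabel:
    """Anchor-spacing motif label, rebased so the smallest anchor is 1."""
    positions = sorted(set(n_anchors) | set(c_anchors))
    if not positions:
        raise ValueError("cannot classify a motif with no anchors")
    base = positions[0]
    label = "-".join(str(p - base + 1) for p in positions)
    return MotifLabel(label, tuple(positions))


# ---------------------------------------------------------------------------
# Electrostatics
# ---------------------------------------------------------------------------

def _named_coords(atoms: list[AtomRecord], names: tuple[str, ...]
                  ) -> np.ndarray:
    sel = [a.coords for a in atoms if a.atom_name in names]
    return np.vstack(sel) if sel else np.empty((0, 3))


def _charged_residues(frame: StructureFrame, chain: str,
                      table: dict[str, tuple[str, ...]]
                      ) -> dict[int, tuple[str, ...]]:
    out = {}
    for seq, atoms in frame.residues(chain, hetero=False).items():
        resname = atoms[0].residue_name
        if resname in table:
            out[seq] = table[resname]
    return out


def salt_bridges(traj: Trajectory, pairing: ComplexPairing,
                 config: AnalysisConfig = AnalysisConfig()
                 ) -> list[SaltBridgeStat]:
    """Occupancy of basic(peptide)-acidic(CaM) donor-acceptor pairs.

    A pair is listed when its donor-acceptor distance is below the cutoff in
    at least ``minor_occupancy`` of the frames, and flagged major at
    ``major_occupancy``.
    """
    frames = traj.frames
    basic = _charged_residues(frames[0], pairing.peptide_chain, DONOR_ATOMS)
    acidic = _charged_residues(frames[0], pairing.cam_chain, ACCEPTOR_ATOMS)
    stats: list[SaltBridgeStat] = []
    for bseq, dnames in basic.items():
        for aseq, anames in acidic.items():
            hits = 0
            seen = 0
            min_d = np.inf
            for fr in frames:
                d_atoms = _named_coords(
                    fr.residue_atoms(pairing.peptide_chain, bseq), dnames)
                a_atoms = _named_coords(
                    fr.residue_atoms(pairing.cam_chain, aseq), anames)
                if d_atoms.size == 0 or a_atoms.size == 0:
                    continue  # disordered side chain in this frame
                seen += 1
                d = cdist(d_atoms, a_atoms).min()
                min_d = min(min_d, d)
                if d < config.saltbridge_cutoff:
                    hits += 1
            if seen == 0:
                continue
            occ = hits / seen
            if occ >= config.minor_occupancy:
                stats.append(SaltBridgeStat(
                    (pairing.peptide_chain, bseq), (pairing.cam_chain, aseq),
                    occ, float(min_d), major=occ >= config.major_occupancy))
    stats.sort(key=lambda s: (s.basic_residue[1], s.acidic_residue[1]))
    return stats


def pooled_salt_bridges(trajs: list[Trajectory], pairing: ComplexPairing,
                        config: AnalysisConfig = AnalysisConfig()
                        ) -> list[SaltBridgeStat]:
    """Salt bridges pooled over parallel runs, with per-run occupancies."""
    per_run_stats = []
    for t in trajs:
        loose = replace(config, minor_occupancy=1e-9)
        per_run_stats.append({(s.basic_residue, s.acidic_residue): s
                              for s in salt_bridges(t, pairing, loose)})
    all_frames = [fr for t in trajs for fr in t.frames]
    pooled = salt_bridges(Trajectory(all_frames), pairing, config)
    for s in pooled:
        key = (s.basic_residue, s.acidic_residue)
        s.per_run = [r[key].occupancy if key in r else 0.0
                     for r in per_run_stats]
    return pooled


# ---------------------------------------------------------------------------
# Contacts, shielding, orientation
# ---------------------------------------------------------------------------

def _heavy_coords(atoms: list[AtomRecord]) -> np.ndarray:
    sel = [a.coords for a in atoms if not a.is_hydrogen]
    return np.vstack(sel) if sel else np.empty((0, 3))


def contact_residues(frame: StructureFrame, pairing: ComplexPairing,
                     target_residue: tuple[str, int],
                     cutoff: float = 4.0) -> set[int]:
    """Partner-chain residues with any non-hydrogen atom pair < cutoff."""
    chain, seq = target_residue
    if chain == pairing.cam_chain:
        partner = pairing.peptide_chain
    elif chain == pairing.peptide_chain:
        partner = pairing.cam_chain
    else:
        raise ChainNotFoundError(
            f"target chain {chain!r} is not part of pairing {pairing.label}")
    target = _heavy_coords(frame.residue_atoms(chain, seq))
    out: set[int] = set()
    for pseq, atoms in frame.residues(partner, hetero=False).items():
        pc = _heavy_coords(atoms)
        if pc.size and target.size and cdist(target, pc).min() < cutoff:
            out.add(pseq)
    return out


def _find_trp(frame: StructureFrame, chain: str) -> int:
    for seq, atoms in frame.residues(chain, hetero=False).items():
        if atoms[0].residue_name == "TRP":
            return seq
    raise ValueError(f"no tryptophan in peptide chain {chain!r}")


def trp_shielding(traj: Trajectory, pairing: ComplexPairing,
                  config: AnalysisConfig = AnalysisConfig(),
                  shield_residues: list[tuple[str, int]] | None = None
                  ) -> tuple[list[bool], float]:
    """Per-frame shielding flags for the peptide tryptophan, and the
    shielded-frame fraction.

    A frame is shielded when at least one shield residue has a side-chain
    non-hydrogen atom closer than ``contact_cutoff`` to any tryptophan
    side-chain non-hydrogen atom.
    """
    trp_seq = _find_trp(traj.frames[0], pairing.peptide_chain)
    if shield_residues is None:
        shield_residues = (
            [(pairing.cam_chain, r) for r in config.shield_cam_residues]
            + [(pairing.peptide_chain, r)
               for r in config.shield_peptide_residues])
    flags: list[bool] = []
    for fr in traj.frames:
        trp = _heavy_coords(_sidechain_atoms(
            fr.residue_atoms(pairing.peptide_chain, trp_seq)))
        shielded = False
        for chain, seq in shield_residues:
            try:
                atoms = fr.residue_atoms(chain, seq)
            except ChainNotFoundError:
                continue
            sc = _heavy_coords(_sidechain_atoms(atoms))
            if sc.size and trp.size and \
                    cdist(sc, trp).min() < config.contact_cutoff:
                shielded = True
                break
        flags.append(shielded)
    fraction = sum(flags) / len(flags)
    return flags, fraction


def classify_orientation(frame: StructureFrame, pairing: ComplexPairing,
                         pockets: list[FLMMPocket],
                         ambiguity: float = 0.1) -> str:
    """'parallel' when the peptide's N-terminal half sits nearer the N-lobe
    pocket than the C-lobe pocket, else 'antiparallel'."""
    by_lobe = {p.lobe: p for p in pockets}
    com_n = pocket_com(frame, by_lobe["N"], cam_chain=pairing.cam_chain)
    com_c = pocket_com(frame, by_lobe["C"], cam_chain=pairing.cam_chain)
    residues = frame.residues(pairing.peptide_chain, hetero=False)
    seqs = sorted(residues)
    half = seqs[:max(1, len(seqs) // 2)]
    pool = [a for s in half for a in residues[s] if not a.is_hydrogen]
    centroid = np.vstack([a.coords for a in pool]).mean(axis=0)
    d_n = np.linalg.norm(centroid - com_n)
    d_c = np.linalg.norm(centroid - com_c)
    if abs(d_n - d_c) < ambiguity:
        return "ambiguous"
    return "parallel" if d_n < d_c else "antiparallel"


# ---------------------------------------------------------------------------
# Calcium sites and the inter-lobe dihedral
# ---------------------------------------------------------------------------

def calcium_sites(frame: StructureFrame, cam_chain: str,
                  coordination_cutoff: float = 3.5) -> list[AtomRecord]:
    """The four Ca2+ ions of one CaM chain, in EF-hand site order.

    Ions are assigned to the CaM chain whose protein atoms are nearest, and
    ordered by the median residue number of their coordinating atoms (loop
    order along the sequence); ions without coordinating protein atoms fall
    back to their own residue numbering.
    """
    ions = [a for a in frame.atoms if a.is_hetero and a.element == "CA"]
    if not ions:
        raise ValueError("no calcium heteroatoms in frame")
    chain_atoms: dict[str, np.ndarray] = {}
    chain_seqs: dict[str, np.ndarray] = {}
    for chain in frame.chains():
        atoms = [a for a in frame.chain_atoms(chain, hetero=False)
                 if not a.is_hydrogen]
        if atoms:
            chain_atoms[chain] = np.vstack([a.coords for a in atoms])
            chain_seqs[chain] = np.array([a.residue_seq for a in atoms])
    mine: list[tuple[float, AtomRecord]] = []
    for ion in ions:
        dists = {c: np.linalg.norm(coords - ion.coords, axis=1)
                 for c, coords in chain_atoms.items()}
        nearest = min(dists, key=lambda c: dists[c].min())
        if ion.chain_id == cam_chain or nearest == cam_chain:
            near = dists[cam_chain] < coordination_cutoff
            if np.any(near):
                order = float(np.median(chain_seqs[cam_chain][near]))
            else:
                order = float(ion.residue_seq)
            mine.append((order, ion))
    if len(mine) != 4:
        raise ValueError(f"expected 4 Ca2+ ions for chain {cam_chain!r}, "
                         f"found {len(mine)}")
    mine.sort(key=lambda t: (t[0], t[1].residue_seq))
    return [ion for _, ion in mine]


def lobe_dihedral(frame: StructureFrame, cam_chain: str) -> float:
    """Signed virtual dihedral through the four Ca2+ ions in EF-hand order.

    Compare magnitudes across complexes; the sign depends only on the
    handedness convention of the torsion.
    """
    ions = calcium_sites(frame, cam_chain)
    return virtual_dihedral(*(ion.coords for ion in ions))
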