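"""Synthetic structure generators with analytically known answers.

Three generators stand in for the study's raw data so every analysis
operation can be validated in a closed loop:

* :func:`build_helix` — ideal or kinked alpha-helical peptides built by
  internal-to-Cartesian placement, with side chains reduced to CB plus one
  tip pseudo-atom at the residue-typical centroid distance;
* :func:`build_scaffold` — a two-lobe pseudo-receptor carrying four ion
  sites at a prescribed virtual dihedral and two four-residue hydrophobic
  pockets;
* :func:`build_ensemble` — multi-frame ensembles with scripted anchoring,
  salt-bridge and shielding occupancies recovered exactly by the analyzers.

Scheduled placements are applied after the Gaussian coordinate noise, so
scripted statistics are exact rather than approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import bend_angle, chain_segment_axis, fit_helix_axis, \
    virtual_dihedral
from .interface import FLMMPocket, default_pockets, pocket_com
from .model_io import AtomRecord, ComplexPairing, ONE_TO_THREE, \
    StructureFrame, Trajectory

__all__ = [
    "HelixSpec",
    "ScaffoldSpec",
    "EnsembleScript",
    "MELITTIN_SEQUENCE",
    "build_helix",
    "build_scaffold",
    "build_complex",
    "build_ensemble",
    "merge_frames",
    "translate_frame",
    "rotate_frame",
    "reverse_chain_numbering",
]

MELITTIN_SEQUENCE = "GIGAVLKVLTTGLPALISWIKRKRQQ"

# Backbone internal coordinates (lengths A, angles deg).
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 117.2, 121.7
_B_C_O, _A_CA_C_O = 1.231, 120.5
_B_CA_CB, _A_N_CA_CB, _T_CB = 1.521, 110.4, -122.0

# Side-chain tip pseudo-atom: name, element, distance from CA (A).
_TIP = {
    "ARG": ("NH1", "N", 4.1), "LYS": ("NZ", "N", 3.5),
    "GLU": ("OE1", "O", 3.1), "ASP": ("OD1", "O", 2.5),
    "GLN": ("NE2", "N", 3.1), "ASN": ("OD1", "O", 2.5),
    "HIS": ("NE2", "N", 3.2), "PHE": ("CZ", "C", 3.4),
    "TYR": ("OH", "O", 4.2), "TRP": ("CH2", "C", 3.9),
    "LEU": ("CD1", "C", 2.6), "ILE": ("CD1", "C", 2.8),
    "VAL": ("CG1", "C", 2.0), "MET": ("SD", "S", 2.9),
    "CYS": ("SG", "S", 2.4), "SER": ("OG", "O", 2.4),
    "THR": ("OG1", "O", 2.4), "PRO": ("CG", "C", 2.4),
}


@dataclass(frozen=True)
class HelixSpec:
    sequence: str
    phi: float = -57.0
    psi: float = -47.0
    kink_residue: int | None = None
    kink_angle: float = 180.0          # target inter-axis angle
    chain_id: str = "B"
    seed: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [c for c in self.sequence.upper() if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"invalid residue letter(s): {bad}")
        if not 90.0 < self.kink_angle <= 180.0:
            raise ValueError("kink_angle must lie in (90, 180]")


@dataclass(frozen=True)
class ScaffoldSpec:
    lobe_separation: float = 30.0
    ion_dihedral: float = 120.0
    pocket_positions: tuple[tuple, tuple] | None = None
    pocket_residue_types: tuple[tuple, tuple] = (
        ("PHE", "LEU", "MET", "MET"), ("PHE", "LEU", "MET", "MET"))
    pocket_seqs: tuple[tuple, tuple] = ((19, 32, 51, 71), (92, 105, 124, 144))
    acidic_sites: tuple[int, ...] = (114, 120, 127)
    n_residues: int = 148
    chain_id: str = "A"

    def __post_init__(self):
        if not -180.0 < self.ion_dihedral <= 180.0:
            raise ValueError("ion_dihedral must lie in (-180, 180]")
        if self.lobe_separation <= 0:
            raise ValueError("lobe_separation must be positive")

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        if self.pocket_positions is not None:
            p = tuple(np.asarray(q, dtype=float)
                      for q in self.pocket_positions)
            if np.linalg.norm(p[1] - p[0]) < 1e-6:
                raise ValueError("degenerate pocket placement (coincident)")
            return p
        half = self.lobe_separation / 2.0
        return (np.array([-half, 0.0, 0.0]), np.array([half, 0.0, 0.0]))


@dataclass(frozen=True)
class EnsembleScript:
    n_frames: int
    anchor_schedule: dict = field(default_factory=dict)  # (lobe, res) -> occ
    bridge_schedule: dict = field(default_factory=dict)  # (basic, acidic) -> occ
    shield_schedule: dict = field(default_factory=dict)  # shield res -> occ
    noise_sigma: float = 0.0
    seed: int = 0
    anchor_cutoff: float = 2.5
    bridge_cutoff: float = 4.0
    shield_cutoff: float = 4.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for sched in (self.anchor_schedule, self.bridge_schedule,
                      self.shield_schedule):
            for occ in sched.values():
                if not 0.0 <= occ <= 1.0:
                    raise ValueError("occupancies must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Internal-to-Cartesian placement
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth point from bond length, bond angle b-c-d and
    torsion a-b-c-d (degrees)."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    return c + bond * (-np.cos(ang) * bc
                       + np.sin(ang) * np.cos(tor) * m
                       + np.sin(ang) * np.sin(tor) * n)


def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Proper rotation mapping ``direction`` onto +z."""
    d = _unit(direction)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(d, z)
    s, c = np.linalg.norm(v), float(np.dot(d, z))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = _unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


# ---------------------------------------------------------------------------
# Helix builder
# ---------------------------------------------------------------------------

def _backbone_trace(seq3: list[str], phi: float, psi: float
                    ) -> list[dict[str, np.ndarray]]:
    n = len(seq3)
    res: list[dict[str, np.ndarray]] = [{} for _ in range(n)]
    res[0]["N"] = np.zeros(3)
    res[0]["CA"] = np.array([_B_N_CA, 0.0, 0.0])
    res[0]["C"] = _place(np.array([0.0, 0.0, 1.0]), res[0]["N"],
                         res[0]["CA"], _B_CA_C, _A_N_CA_C, 0.0)
    for i in range(n - 1):
        res[i + 1]["N"] = _place(res[i]["N"], res[i]["CA"], res[i]["C"],
                                 _B_C_N, _A_CA_C_N, psi)
        res[i + 1]["CA"] = _place(res[i]["CA"], res[i]["C"], res[i + 1]["N"],
                                  _B_N_CA, _A_C_N_CA, 180.0)
        res[i + 1]["C"] = _place(res[i]["C"], res[i + 1]["N"],
                                 res[i + 1]["CA"], _B_CA_C, _A_N_CA_C, phi)
    for i in range(n):
        res[i]["O"] = _place(res[i]["N"], res[i]["CA"], res[i]["C"],
                             _B_C_O, _A_CA_C_O, psi + 180.0)
        if seq3[i] != "GLY":
            cb = _place(res[i]["C"], res[i]["N"], res[i]["CA"],
                        _B_CA_CB, _A_N_CA_CB, _T_CB)
            res[i]["CB"] = cb
            if seq3[i] != "ALA":
                name, _, dist = _TIP[seq3[i]]
                res[i][name] = res[i]["CA"] + \
                    dist * _unit(cb - res[i]["CA"])
    return res


def _helix_frame(seq3: list[str], res: list[dict[str, np.ndarray]],
                 chain_id: str) -> StructureFrame:
    atoms: list[AtomRecord] = []
    for i, (rn, rd) in enumerate(zip(seq3, res), start=1):
        order = ["N", "CA", "C", "O"] + \
            [k for k in rd if k not in ("N", "CA", "C", "O")]
        for name in order:
            if name in ("N", "CA", "C", "O"):
                element = name[0]
            elif name == "CB":
                element = "C"
            else:
                element = _TIP[rn][1]
            atoms.append(AtomRecord(name, element, "", rd[name].copy(),
                                    1.0, 0.0, rn, i, chain_id, False))
    return StructureFrame(atoms)


def _bend_segments(n: int, kink: int) -> tuple[tuple[int, int],
                                               tuple[int, int]]:
    if n >= 22 and 12 <= kink <= 15:
        return (3, 11), (15, 22)
    s1 = (max(1, kink - 9), kink - 2)
    s2 = (kink + 1, min(n, kink + 8))
    return s1, s2


def build_helix(spec: HelixSpec) -> StructureFrame:
    """Build an ideal (or kinked) alpha-helical peptide.

    The straight helix is aligned with its fitted axis along +z (N->C) and
    its C-alpha centroid at the origin.  When a kink is requested, the
    C-terminal part is rigid-rotated about the kink C-alpha until the fitted
    inter-axis angle matches ``kink_angle`` (within 0.5 degrees).
    """
    seq3 = [ONE_TO_THREE[c] for c in spec.sequence.upper()]
    res = _backbone_trace(seq3, spec.phi, spec.psi)
    frame = _helix_frame(seq3, res, spec.chain_id)

    ca = np.vstack([a.coords for a in frame.atoms if a.atom_name == "CA"])
    if len(ca) >= 4:
        axis = fit_helix_axis(ca)
        rot = _rotation_to_z(axis.direction)
        centroid = ca.mean(axis=0)
        for a in frame.atoms:
            a.coords = rot @ (a.coords - centroid)

    kink = spec.kink_residue
    if kink is not None and spec.kink_angle < 180.0:
        n = len(seq3)
        if not 4 <= kink <= n - 4:
            raise ValueError("kink_residue too close to a terminus")
        straight = np.vstack([a.coords for a in frame.atoms])
        pivot_idx = next(i for i, a in enumerate(frame.atoms)
                         if a.residue_seq == kink and a.atom_name == "CA")
        tail = np.array([a.residue_seq > kink for a in frame.atoms])
        seg1, seg2 = _bend_segments(n, kink)
        theta = 180.0 - spec.kink_angle
        for _ in range(12):
            coords = straight.copy()
            rot = _axis_rotation([1.0, 0.0, 0.0], theta)
            pivot = straight[pivot_idx]
            coords[tail] = (straight[tail] - pivot) @ rot.T + pivot
            for a, c in zip(frame.atoms, coords):
                a.coords = c
            got = bend_angle(
                chain_segment_axis(frame, spec.chain_id, *seg1),
                chain_segment_axis(frame, spec.chain_id, *seg2))
            err = got - spec.kink_angle
            if abs(err) <= 0.5:
                break
            theta += err
    return frame


# ---------------------------------------------------------------------------
# Scaffold builder
# ---------------------------------------------------------------------------

_POCKET_DIRS = (np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0]),
                np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0]))


def _ion_positions(p_n: np.ndarray, p_c: np.ndarray, chi: float
                   ) -> list[np.ndarray]:
    lift = np.array([0.0, 0.0, -12.0])
    p2, p3 = p_n + lift, p_c + lift
    a = _unit(p3 - p2)
    u1 = np.array([0.0, 0.0, 1.0])
    u1 = _unit(u1 - np.dot(u1, a) * a)
    for sign in (1.0, -1.0):
        u2 = _axis_rotation(a, sign * chi) @ u1
        p1 = p2 - 4.0 * a + 3.5 * u1
        p4 = p3 + 4.0 * a + 3.5 * u2
        got = virtual_dihedral(p1, p2, p3, p4)
        delta = (got - chi + 180.0) % 360.0 - 180.0
        if abs(delta) < 1e-9:
            return [p1, p2, p3, p4]
    raise AssertionError("ion dihedral construction failed")  # pragma: no cover


def build_scaffold(spec: ScaffoldSpec) -> StructureFrame:
    """Two-lobe pseudo-receptor: filler backbone ring, two FLMM-like
    pockets whose side-chain mass centers sit at the pocket positions, and
    four pseudo-ion heteroatoms realizing the requested virtual dihedral."""
    p_n, p_c = spec.positions()
    center = (p_n + p_c) / 2.0
    chain = spec.chain_id
    pocket_lookup: dict[int, tuple[np.ndarray, str, int]] = {}
    for pos, types, seqs in zip((p_n, p_c), spec.pocket_residue_types,
                                spec.pocket_seqs):
        for k, (seq, typ) in enumerate(zip(seqs, types)):
            pocket_lookup[seq] = (pos, typ, k)

    atoms: list[AtomRecord] = []

    def add(name, element, pos, resname, seq, hetero=False):
        atoms.append(AtomRecord(name, element, "", np.asarray(pos, float),
                                1.0, 0.0, resname, seq, chain, hetero))

    ring_r = 30.0
    for seq in range(1, spec.n_residues + 1):
        if seq in pocket_lookup:
            pos, typ, k = pocket_lookup[seq]
            d = _POCKET_DIRS[k]
            ca = pos + 6.0 * d
            add("N", "N", ca + [-1.2, 0.0, 0.0], typ, seq)
            add("CA", "C", ca, typ, seq)
            add("C", "C", ca + [1.2, 0.0, 0.4], typ, seq)
            add("O", "O", ca + [1.8, 0.0, 1.4], typ, seq)
            add("CB", "C", pos + 3.2 * d, typ, seq)
            tip_name, tip_el, _ = _TIP[typ]
            add(tip_name, tip_el, pos + 2.0 * d, typ, seq)
        else:
            resname = "GLU" if seq in spec.acidic_sites else "ALA"
            t = 2.0 * np.pi * (seq - 1) / spec.n_residues
            base = center + np.array([ring_r * np.cos(t),
                                      ring_r * np.sin(t), 25.0])
            add("N", "N", base + [-1.2, 0.0, 0.0], resname, seq)
            add("CA", "C", base, resname, seq)
            add("C", "C", base + [1.2, 0.0, 0.4], resname, seq)
            add("O", "O", base + [1.8, 0.0, 1.4], resname, seq)
            add("CB", "C", base + [0.0, 0.0, 1.5], resname, seq)
            if resname == "GLU":
                add("OE1", "O", base + [0.0, 0.0, 3.0], resname, seq)

    for i, pos in enumerate(_ion_positions(p_n, p_c, spec.ion_dihedral)):
        add("CA", "CA", pos, "CA", 200 + i + 1, hetero=True)

    meta = {"pocket_positions": (tuple(p_n), tuple(p_c)),
            "cam_chain": chain}
    return StructureFrame(atoms, metadata=meta)


# ---------------------------------------------------------------------------
# Frame manipulation helpers
# ---------------------------------------------------------------------------

def merge_frames(*frames: StructureFrame) -> StructureFrame:
    atoms: list[AtomRecord] = []
    meta: dict = {}
    for fr in frames:
        atoms.extend(fr.copy().atoms)
        meta.update(fr.metadata)
    return StructureFrame(atoms, metadata=meta)


def translate_frame(frame: StructureFrame, shift) -> StructureFrame:
    out = frame.copy()
    shift = np.asarray(shift, dtype=float)
    for a in out.atoms:
        a.coords = a.coords + shift
    return out


def rotate_frame(frame: StructureFrame, rotation: np.ndarray,
                 center=(0.0, 0.0, 0.0)) -> StructureFrame:
    out = frame.copy()
    center = np.asarray(center, dtype=float)
    for a in out.atoms:
        a.coords = rotation @ (a.coords - center) + center
    return out


def reverse_chain_numbering(frame: StructureFrame, chain: str
                            ) -> StructureFrame:
    """Renumber one chain back-to-front (residue i -> n+1-i)."""
    out = frame.copy()
    seqs = sorted(out.residues(chain, hetero=False))
    lo, hi = seqs[0], seqs[-1]
    for a in out.atoms:
        if a.chain_id == chain and not a.is_hetero:
            a.residue_seq = hi + lo - a.residue_seq
    out.atoms.sort(key=lambda a: (a.chain_id, a.is_hetero, a.residue_seq))
    return StructureFrame(out.atoms, out.model_index, out.metadata)


def _tip_atom(frame: StructureFrame, chain: str, seq: int) -> AtomRecord:
    atoms = frame.residue_atoms(chain, seq)
    resname = atoms[0].residue_name
    if resname not in _TIP:
        raise ValueError(f"residue {resname} {seq} has no side-chain tip")
    name = _TIP[resname][0]
    for a in atoms:
        if a.atom_name == name:
            return a
    raise ValueError(f"tip atom {name} missing on {resname} {seq}")


# ---------------------------------------------------------------------------
# Complex and ensemble builders
# ---------------------------------------------------------------------------

def build_complex(scaffold_spec: ScaffoldSpec | None = None,
                  helix_spec: HelixSpec | None = None,
                  n_anchors: tuple[int, ...] = (6,),
                  c_anchors: tuple[int, ...] = (16,),
                  anchor_distance: float = 1.5,
                  helix_offset: float = 10.0
                  ) -> tuple[StructureFrame, ComplexPairing,
                             list[FLMMPocket]]:
    """Scaffold plus bound helix with chosen residues placed in anchoring
    position; returns (frame, pairing, pockets)."""
    scaffold_spec = scaffold_spec or ScaffoldSpec()
    helix_spec = helix_spec or HelixSpec(MELITTIN_SEQUENCE)
    scaffold = build_scaffold(scaffold_spec)
    helix = build_helix(helix_spec)

    p_n, p_c = scaffold_spec.positions()
    center = (p_n + p_c) / 2.0
    axis = _unit(p_c - p_n)
    rot = _rotation_to_z(axis).T          # maps +z onto the pocket axis
    helix = rotate_frame(helix, rot)
    # keep the helix clear of the pocket mass centers; anchors are placed
    # explicitly below
    offset_dir = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(offset_dir, axis)) > 0.9:
        offset_dir = np.array([0.0, 1.0, 0.0])
    offset_dir = _unit(offset_dir - np.dot(offset_dir, axis) * axis)
    helix = translate_frame(helix, center + helix_offset * offset_dir)

    frame = merge_frames(scaffold, helix)
    pairing = ComplexPairing(scaffold_spec.chain_id, helix_spec.chain_id,
                             f"{scaffold_spec.chain_id}/"
                             f"{helix_spec.chain_id}")
    pockets = [FLMMPocket("N", tuple(scaffold_spec.pocket_seqs[0]),
                          scaffold_spec.chain_id),
               FLMMPocket("C", tuple(scaffold_spec.pocket_seqs[1]),
                          scaffold_spec.chain_id)]
    for pocket, anchors in zip(pockets, (n_anchors, c_anchors)):
        com = pocket_com(frame, pocket)
        for seq in anchors:
            tip = _tip_atom(frame, pairing.peptide_chain, seq)
            tip.coords = com + anchor_distance * offset_dir
    return frame, pairing, pockets


def _pick_frames(rng: np.random.Generator, n: int, occupancy: float
                 ) -> set[int]:
    k = int(round(occupancy * n))
    if occupancy > 0 and k == 0:
        warnings.warn("occupancy * n_frames below 1; rounding up to 1 frame")
        k = 1
    return set(int(i) for i in rng.permutation(n)[:k])


def build_ensemble(base: StructureFrame, script: EnsembleScript,
                   pairing: ComplexPairing | None = None,
                   pockets: list[FLMMPocket] | None = None) -> Trajectory:
    """Multi-frame ensemble around ``base`` with scripted statistics.

    Gaussian coordinate noise is applied first; each scheduled event then
    moves the relevant side-chain tip inside or outside its criterion
    distance, so the scheduled occupancy is exact by construction.
    """
    if pairing is None:
        cam = base.metadata.get("cam_chain")
        chains = [c for c in base.chains() if c != cam]
        if cam is None or len(chains) != 1:
            raise ValueError("cannot infer pairing from frame metadata; "
                             "pass pairing explicitly")
        pairing = ComplexPairing(cam, chains[0], f"{cam}/{chains[0]}")
    if pockets is None:
        pockets = default_pockets(pairing.cam_chain)
    by_lobe = {p.lobe: p for p in pockets}

    rng = np.random.default_rng(script.seed)
    n = script.n_frames
    frames: list[StructureFrame] = []
    for i in range(n):
        fr = base.copy()
        fr.model_index = i + 1
        if script.noise_sigma > 0:
            noise = rng.normal(0.0, script.noise_sigma, (len(fr.atoms), 3))
            for a, dv in zip(fr.atoms, noise):
                a.coords = a.coords + dv
        frames.append(fr)

    up = np.array([0.0, 0.0, 1.0])
    for (lobe, seq), occ in sorted(script.anchor_schedule.items()):
        chosen = _pick_frames(rng, n, occ)
        for i, fr in enumerate(frames):
            com = pocket_com(fr, by_lobe[lobe], pairing.cam_chain)
            tip = _tip_atom(fr, pairing.peptide_chain, seq)
            d = 0.5 * script.anchor_cutoff if i in chosen \
                else script.anchor_cutoff + 2.0
            tip.coords = com + d * up

    for (basic, acidic), occ in sorted(script.bridge_schedule.items()):
        chosen = _pick_frames(rng, n, occ)
        for i, fr in enumerate(frames):
            acceptor = next(
                a for a in fr.residue_atoms(pairing.cam_chain, acidic)
                if a.atom_name in ("OE1", "OE2", "OD1", "OD2"))
            donor = _tip_atom(fr, pairing.peptide_chain, basic)
            d = 0.75 * script.bridge_cutoff if i in chosen \
                else 2.0 * script.bridge_cutoff
            donor.coords = acceptor.coords + d * up

    trp_seq = next((s for s, at in
                    base.residues(pairing.peptide_chain, hetero=False).items()
                    if at[0].residue_name == "TRP"), None)
    for seq, occ in sorted(script.shield_schedule.items()):
        if trp_seq is None:
            raise ValueError("shield schedule requires a Trp in the peptide")
        chosen = _pick_frames(rng, n, occ)
        for i, fr in enumerate(frames):
            trp_tip = _tip_atom(fr, pairing.peptide_chain, trp_seq)
            shield = _tip_atom(fr, pairing.peptide_chain, seq)
            d = 0.75 * script.shield_cutoff if i in chosen \
                else 2.0 * script.shield_cutoff
            shield.coords = trp_tip.coords + d * up
    return Trajectory(frames, frame_stride_note=f"synthetic, seed="
                      f"{script.seed}, sigma={script.noise_sigma}")
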