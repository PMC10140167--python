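"""Vector geometry core: mass centers, torsions, helix axes, Kabsch RMSD.

All angles are degrees.  Helix axes use a local-center construction (radial
second differences of consecutive C-alpha positions), which is insensitive
to helical phase even for short segments; directions are oriented N-to-C.
The bend angle between two segments is mapped so that a perfectly straight
helix scores 180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model_io import AtomRecord, StructureFrame, ChainNotFoundError

__all__ = [
    "ATOMIC_MASSES",
    "HelixAxis",
    "DegenerateGeometryError",
    "mass_of",
    "center_of_mass",
    "virtual_dihedral",
    "fit_helix_axis",
    "chain_segment_axis",
    "bend_angle",
    "kabsch_superpose",
    "rmsd_after_superposition",
]

ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998,
    "CA": 40.078, "MG": 24.305, "ZN": 65.38, "NA": 22.99, "K": 39.098,
    "CL": 35.45, "MN": 54.938, "FE": 55.845,
}


class DegenerateGeometryError(ValueError):
    """Points are coincident or collinear where a plane/axis is required."""


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"no atomic mass for element {element!r}") from None


def center_of_mass(atoms: Iterable[AtomRecord] | np.ndarray,
                   weights: Sequence[float] | None = None) -> np.ndarray:
    """Mass-weighted mean position of an atom set.

    Accepts either :class:`AtomRecord` objects (masses from the element) or
    a raw (N, 3) coordinate array with explicit ``weights``.
    """
    if isinstance(atoms, np.ndarray):
        coords = np.asarray(atoms, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("expected an (N, 3) coordinate array")
        masses = (np.ones(len(coords)) if weights is None
                  else np.asarray(weights, dtype=float))
    else:
        pool = list(atoms)
        if not pool:
            raise ValueError("center_of_mass of an empty atom set")
        coords = np.vstack([a.coords for a in pool])
        masses = (np.array([mass_of(a.element) for a in pool])
                  if weights is None else np.asarray(weights, dtype=float))
    if coords.size == 0:
        raise ValueError("center_of_mass of an empty atom set")
    total = masses.sum()
    if total <= 0:
        raise ValueError("non-positive total mass")
    return (coords * masses[:, None]).sum(axis=0) / total


def virtual_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion of four points, degrees in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-10 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError(
            "collinear or coincident points define no torsion")
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2),
                                  np.dot(n1, n2)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


@dataclass
class HelixAxis:
    origin: np.ndarray
    direction: np.ndarray  # unit vector, oriented N->C
    residue_range: tuple[int, int] | None = None

    def __post_init__(self):
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")


def _local_helix_centers(ca: np.ndarray) -> np.ndarray:
    """Axis points from radial second differences of consecutive CA atoms."""
    n = len(ca)
    d = ca[:-2] - 2.0 * ca[1:-1] + ca[2:]      # radial (inward) at 1..n-2
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-8):
        raise DegenerateGeometryError("collinear C-alpha run; no helix axis")
    units = d / norms[:, None]
    centers = np.empty((n - 2, 3))
    for i in range(n - 2):
        j = i + 1 if i + 1 < n - 2 else i - 1
        cos_t = float(np.clip(np.dot(units[i], units[j]), -1.0, 1.0))
        if cos_t > 1.0 - 1e-9:
            raise DegenerateGeometryError("degenerate helical twist")
        radius = np.sqrt(norms[i] * norms[j]) / (2.0 * (1.0 - cos_t))
        centers[i] = ca[i + 1] + radius * units[i]
    return centers


def fit_helix_axis(ca_coords: np.ndarray,
                   residue_range: tuple[int, int] | None = None) -> HelixAxis:
    """Fit a straight axis to an ordered run of C-alpha positions.

    Local axis points are computed per interior residue and the principal
    direction of those centers is taken, oriented from the first toward the
    last center (N->C).
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or len(ca) < 4:
        raise ValueError("need at least 4 ordered C-alpha positions")
    centers = _local_helix_centers(ca)
    origin = centers.mean(axis=0)
    _, _, vt = np.linalg.svd(centers - origin)
    direction = vt[0]
    if np.dot(direction, centers[-1] - centers[0]) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    return HelixAxis(origin, direction, residue_range)


def chain_segment_axis(frame: StructureFrame, chain: str,
                       start: int, end: int) -> HelixAxis:
    """Helix axis of chain residues ``start``..``end`` (inclusive, author
    numbering), from their C-alpha atoms in sequence order."""
    residues = frame.residues(chain, hetero=False)
    ca = []
    for seq in sorted(r for r in residues if start <= r <= end):
        for a in residues[seq]:
            if a.atom_name == "CA":
                ca.append(a.coords)
                break
    if len(ca) < 4:
        raise ChainNotFoundError(
            f"chain {chain!r} residues {start}-{end}: only {len(ca)} "
            "C-alpha atoms present (need >= 4)")
    return fit_helix_axis(np.array(ca), residue_range=(start, end))


def bend_angle(seg1: HelixAxis, seg2: HelixAxis) -> float:
    """Inter-segment angle with the straight-helix limit at 180 degrees."""
    cos_t = float(np.clip(np.dot(seg1.direction, seg2.direction), -1.0, 1.0))
    return 180.0 - float(np.degrees(np.arccos(cos_t)))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det = +1).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    if len(mob) < 3:
        raise ValueError("need at least 3 paired points")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    h = (mob - cm).T @ (ref - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    return kabsch_superpose(a, b)[2]
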