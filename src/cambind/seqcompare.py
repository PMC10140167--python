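"""Position-wise ortholog comparison: identity, similar substitutions and
overlap of differing positions with a binding interface.

Orthologs are expected to align without gaps (equal length) or to arrive
pre-aligned with ``-`` gap characters.  "Similar" means both residues fall
in the same physicochemical class; the class table is configurable because
different authors draw the groups differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SIMILARITY_GROUPS",
    "SequencePairStats",
    "compare_orthologs",
    "differing_in_interface",
]

SIMILARITY_GROUPS = (
    "ILVM", "FWY", "KR", "DE", "ST", "NQ", "AG", "C", "P", "H",
)


@dataclass
class SequencePairStats:
    length_aligned: int
    identical: int
    nonidentical: int
    similar_substitutions: int
    identity_pct: float
    differing_positions: list[int] = field(default_factory=list)  # 1-based
    differing_in_interface: int | None = None

    def as_dict(self) -> dict:
        return {
            "length_aligned": self.length_aligned,
            "identical": self.identical,
            "nonidentical": self.nonidentical,
            "similar_substitutions": self.similar_substitutions,
            "identity_pct": round(self.identity_pct, 2),
            "differing_positions": list(self.differing_positions),
            "differing_in_interface": self.differing_in_interface,
        }


def _class_lookup(groups: Sequence[str]) -> dict[str, int]:
    table: dict[str, int] = {}
    for i, group in enumerate(groups):
        for aa in group:
            table[aa.upper()] = i
    return table


def compare_orthologs(seq_a: str, seq_b: str,
                      similarity_groups: Sequence[str] = SIMILARITY_GROUPS
                      ) -> SequencePairStats:
    """Position-wise comparison of two aligned one-letter sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequences have different lengths ({len(seq_a)} "
                         f"vs {len(seq_b)}) and carry no gap characters")
    table = _class_lookup(similarity_groups)
    identical = similar = 0
    differing: list[int] = []
    for pos, (a, b) in enumerate(zip(seq_a.upper(), seq_b.upper()), start=1):
        if a == b and a != "-":
            identical += 1
        else:
            differing.append(pos)
            if a != "-" and b != "-" and \
                    table.get(a) is not None and table.get(a) == table.get(b):
                similar += 1
    n = len(seq_a)
    return SequencePairStats(
        length_aligned=n,
        identical=identical,
        nonidentical=n - identical,
        similar_substitutions=similar,
        identity_pct=100.0 * identical / n,
        differing_positions=differing,
    )


def differing_in_interface(differing_positions: Iterable[int],
                           interface_residues: Iterable[int] |
                           Iterable[Iterable[int]]) -> int:
    """Count differing positions that contact the peptide in any binding
    mode.  ``interface_residues`` is one residue set or a collection of
    per-mode sets (their union is used)."""
    pool: set[int] = set()
    for item in interface_residues:
        if isinstance(item, int):
            pool.add(item)
        else:
            pool.update(item)
    return len(set(differing_positions) & pool)
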