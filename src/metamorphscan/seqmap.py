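"""Pairwise global alignment and alignment-mapped salt-bridge distances.

Residues equivalent to a reference interdomain salt bridge (E48–R138 in
the *E. coli* reference numbering) are located in each query sequence by
Needleman–Wunsch global alignment with affine gaps, and the Cβ–Cβ
distance between the mapped residues (Cα for glycine) is the statistic
summarised per fold class.  A gap of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from metamorphscan.structures import ProteinStructure

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass
class PairwiseAlignment:
    """A global alignment of sequence A (reference) to sequence B (query)."""

    aligned_a: str
    aligned_b: str
    score: float
    map_a_to_b: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if not self.map_a_to_b:
            self.map_a_to_b = _column_map(self.aligned_a, self.aligned_b)

    @property
    def identity(self) -> float:
        """Fraction of aligned (non-gap) columns with identical residues."""
        pairs = [
            (a, b)
            for a, b in zip(self.aligned_a, self.aligned_b)
            if a != "-" and b != "-"
        ]
        if not pairs:
            return 0.0
        return sum(a == b for a, b in pairs) / len(pairs)


def _column_map(aligned_a: str, aligned_b: str) -> Dict[int, int]:
    mapping: Dict[int, int] = {}
    pos_a = pos_b = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            pos_a += 1
        if cb != "-":
            pos_b += 1
        if ca != "-" and cb != "-":
            mapping[pos_a] = pos_b
    return mapping


@dataclass(frozen=True)
class SaltBridgePair:
    """Reference-numbering positions of the two salt-bridge residues."""

    ref_pos_a: int = 48
    ref_pos_b: int = 138

    def __post_init__(self) -> None:
        if self.ref_pos_a < 1 or self.ref_pos_b < 1:
            raise ValueError("positions are 1-based and must be >= 1")


@dataclass(frozen=True)
class DistanceSummary:
    """Box-plot style summary: median, quartiles and the 1/99 percentiles."""

    median: float
    q25: float
    q75: float
    p1: float
    p99: float
    n: int

    def __post_init__(self) -> None:
        if not (self.p1 <= self.q25 <= self.median <= self.q75 <= self.p99):
            raise ValueError("summary quantiles out of order")


def _load_matrix(substitution) -> Align.substitution_matrices.Array:
    if isinstance(substitution, str):
        return substitution_matrices.load(substitution)
    return substitution


def global_align(
    seq_a: str,
    seq_b: str,
    substitution="BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment with affine gap costs.

    Ties are broken deterministically (the first optimal traceback).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(substitution)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    return PairwiseAlignment(str(best[0]), str(best[1]), best.score)


def map_equivalent_positions(
    alignment: PairwiseAlignment, pair: SaltBridgePair
) -> Tuple[Optional[int], Optional[int]]:
    """Query positions aligned to the reference salt-bridge positions.

    The reference must be sequence A of the alignment.  A reference
    position sitting on a gap column maps to None ("missing"); callers
    exclude such records from distance statistics.
    """
    return (
        alignment.map_a_to_b.get(pair.ref_pos_a),
        alignment.map_a_to_b.get(pair.ref_pos_b),
    )


def salt_bridge_distance(
    structure: ProteinStructure, pos_a: int, pos_b: int
) -> float:
    """Cβ–Cβ Euclidean distance (Å) between two residues (Cα for glycine)."""
    coords = []
    for pos in (pos_a, pos_b):
        res = structure.residue_at(pos)
        if res is None:
            raise ValueError(f"no residue at position {pos}")
        atom_name = "CA" if res.name3.upper() == "GLY" else "CB"
        atom = res.get(atom_name)
        if atom is None:
            raise ValueError(
                f"missing atom {atom_name} in residue {pos} ({res.name3})"
            )
        coords.append(atom.coords)
    return float(np.linalg.norm(coords[0] - coords[1]))


def summarize_distances(values: Iterable[float]) -> DistanceSummary:
    """Median, quartiles and 1st/99th percentiles by linear interpolation."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty distance list")
    p1, q25, med, q75, p99 = np.percentile(arr, [1, 25, 50, 75, 99])
    return DistanceSummary(
        median=float(med), q25=float(q25), q75=float(q75),
        p1=float(p1), p99=float(p99), n=int(arr.size),
    )
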