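"""Per-residue secondary structure from backbone hydrogen-bond patterns.

The assigner follows the classical Kabsch–Sander electrostatic model: an
amide hydrogen is rebuilt geometrically, a backbone (CO, NH) pair is
hydrogen-bonded when

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

falls below -0.5 kcal/mol, and the letter classes are derived from
n-turn and bridge patterns: H (α-helix, runs of i→i+4 bonds),
G (3₁₀), I (π), E (strand in a bridge ladder), B (isolated bridge),
T (turn), C (coil).  Downstream fold classification counts only strict
'H' as helix and strict 'E' as strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from metamorphscan.structures import ProteinStructure, RegionSpec

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q = 0.084 * 332.0  # Kabsch-Sander coupling constant
_NH_BOND = 1.01  # Å, rebuilt amide H
_CHAIN_BREAK = 2.5  # Å, max C(i)–N(i+1) peptide-bond distance

ALLOWED_CODES = set("HGIEBTC")


@dataclass(frozen=True)
class SSContent:
    """Helix/strand percentages over a region (strict 'H' and 'E' only)."""

    percent_helix: float
    percent_strand: float

    def __post_init__(self) -> None:
        if self.percent_helix + self.percent_strand > 100.0 + 1e-9:
            raise ValueError("helix + strand content cannot exceed 100%")


def _backbone(structure: ProteinStructure):
    """Per-residue backbone coordinates (or None where atoms are missing)."""
    n = len(structure)
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    O = [None] * n
    for i, res in enumerate(structure.residues):
        for name, store in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            atom = res.get(name)
            if atom is not None:
                store[i] = atom.coords
    return N, CA, C, O


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _build_amide_hydrogens(N, CA, C) -> List[Optional[np.ndarray]]:
    """Place H on each backbone N along the bisector away from C(prev) and CA."""
    n = len(N)
    H: List[Optional[np.ndarray]] = [None] * n
    for i in range(1, n):
        if N[i] is None or CA[i] is None or C[i - 1] is None:
            continue
        if np.linalg.norm(N[i] - C[i - 1]) > _CHAIN_BREAK:
            continue  # chain break: no defined amide direction
        direction = _unit(_unit(N[i] - C[i - 1]) + _unit(N[i] - CA[i]))
        H[i] = N[i] + _NH_BOND * direction
    return H


def _hbond_energy(c, o, n, h) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing atoms: not a bond
        return 0.0
    return _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_map(structure: ProteinStructure) -> Tuple[np.ndarray, int]:
    """Boolean matrix hb[i, j]: CO of residue i bonded to NH of residue j."""
    N, CA, C, O = _backbone(structure)
    H = _build_amide_hydrogens(N, CA, C)
    n = len(structure)
    hb = np.zeros((n, n), dtype=bool)
    ca_arr = np.array([c if c is not None else [1e6, 1e6, 1e6] for c in CA])
    # CA-CA prefilter at 9 Å, as in the classical implementation
    for i in range(n):
        if C[i] is None or O[i] is None:
            continue
        d2 = np.sum((ca_arr - ca_arr[i]) ** 2, axis=1)
        for j in np.nonzero(d2 < 81.0)[0]:
            if j == i or j == i + 1:
                continue  # the shared peptide bond is not a hydrogen bond
            if N[j] is None or H[j] is None:
                continue
            if _hbond_energy(C[i], O[i], N[j], H[j]) < HB_ENERGY_CUTOFF:
                hb[i, j] = True
    return hb, n


def _mark(codes: List[str], start: int, stop: int, letter: str) -> None:
    for i in range(start, stop):
        if codes[i] == "C":
            codes[i] = letter


def assign_secondary_structure(structure: ProteinStructure) -> str:
    """One letter from {H, G, I, E, B, T, C} per residue.

    Residues with missing backbone atoms get 'C'; structures shorter
    than 3 residues are all-'C'.
    """
    n = len(structure)
    if n < 3:
        return "C" * n
    hb, _ = _hbond_map(structure)

    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if hb[i, i + k]:
                turn[k][i] = True

    codes = ["C"] * n

    # α-helix: two consecutive i→i+4 turns cover residues i+1..i+4
    for i in range(1, n - 4):
        if turn[4][i] and turn[4][i - 1]:
            for j in range(i, i + 4):
                codes[j] = "H"

    # bridges → ladders → E / B
    bridges: List[Tuple[int, int, str]] = []
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para:
                bridges.append((i, j, "P"))
            if anti:
                bridges.append((i, j, "A"))
    in_ladder = np.zeros(n, dtype=bool)
    lone = np.zeros(n, dtype=bool)
    bridge_set = set((i, j, t) for i, j, t in bridges)
    for i, j, t in bridges:
        if t == "P":
            extended = (i + 1, j + 1, "P") in bridge_set or (i - 1, j - 1, "P") in bridge_set
        else:
            extended = (i + 1, j - 1, "A") in bridge_set or (i - 1, j + 1, "A") in bridge_set
        if extended:
            in_ladder[i] = in_ladder[j] = True
        else:
            lone[i] = lone[j] = True
    for i in range(n):
        if in_ladder[i] and codes[i] == "C":
            codes[i] = "E"
    for i in range(n):
        if lone[i] and codes[i] == "C":
            codes[i] = "B"

    # 3₁₀ and π helices on the remaining residues
    for i in range(1, n - 3):
        if turn[3][i] and turn[3][i - 1]:
            _mark(codes, i, i + 3, "G")
    for i in range(1, n - 5):
        if turn[5][i] and turn[5][i - 1]:
            _mark(codes, i, i + 5, "I")

    # turns: interior residues of any single n-turn
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn[k][i]:
                _mark(codes, i + 1, i + k, "T")

    return "".join(codes)


def ss_content(codes: str, region: RegionSpec) -> SSContent:
    """Percent 'H' and percent 'E' over a region of the code string.

    G, I and B never count toward either class.
    """
    if region.end > len(codes):
        raise ValueError(
            f"region [{region.start}, {region.end}] exceeds code length {len(codes)}"
        )
    window = codes[region.start - 1 : region.end]
    if not window:
        raise ValueError("empty region")
    bad = set(window) - ALLOWED_CODES
    if bad:
        raise ValueError(f"invalid secondary-structure codes: {sorted(bad)}")
    length = len(window)
    return SSContent(
        percent_helix=100.0 * window.count("H") / length,
        percent_strand=100.0 * window.count("E") / length,
    )


def ss_table(structure: ProteinStructure, codes: str) -> List[Dict[str, object]]:
    """Rows of (residue_index, aa, ss_code) for TSV emission."""
    return [
        {"residue_index": r.index, "aa": r.one_letter, "ss_code": codes[i]}
        for i, r in enumerate(structure.residues)
    ]
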