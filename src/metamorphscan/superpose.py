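"""Rigid-body superposition (Kabsch), RMSD and TM-score.

The TM-score of a model against a reference of matched length N is

    TM = max over superpositions of (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2)

with d0 = 1.24 * (L_norm - 15)^(1/3) - 1.8 Å.  The maximisation uses the
standard iterative heuristic: initial superpositions seeded from sliding
fragments (lengths L, L/2, L/4), then repeated refitting on the residue
subset within d0, keeping the best score seen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from metamorphscan.seqmap import global_align
from metamorphscan.structures import ProteinStructure, RegionSpec


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TMScoreResult:
    score: float
    d0: float
    aligned_length: int


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rotation/translation mapping coords_a onto coords_b.

    Reflections are excluded (det(R) = +1).  Requires >= 3 points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point count mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need two N x 3 arrays with N >= 3")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = a @ R.T + t - b
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _map_region_ca(
    model: ProteinStructure, ref: ProteinStructure, region: RegionSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Paired Cα coordinates (model, ref) over a reference-numbered region.

    Identical sequences use the identity mapping; otherwise residue
    correspondence comes from a global alignment (reference = sequence A).
    """
    if model.sequence == ref.sequence:
        pairs = [(p, p) for p in region.indices() if ref.residue_at(p) is not None]
    else:
        aln = global_align(ref.sequence, model.sequence)
        pairs = [
            (aln.map_a_to_b[p], p)
            for p in region.indices()
            if p in aln.map_a_to_b
        ]
    missing = [
        (mp, rp)
        for mp, rp in pairs
        if model.residue_at(mp) is None
        or "CA" not in model.residue_at(mp).atoms
        or "CA" not in ref.residue_at(rp).atoms
    ]
    if missing:
        raise ValueError(f"missing CA for mapped residue pairs: {missing[:5]}")
    if len(pairs) < 3:
        raise ValueError("fewer than 3 mapped residues in region")
    m = np.array([model.residue_at(mp).coord("CA") for mp, _ in pairs])
    r = np.array([ref.residue_at(rp).coord("CA") for _, rp in pairs])
    return m, r


def region_rmsd(
    model: ProteinStructure,
    ref: ProteinStructure,
    region: RegionSpec,
    fit_region: Optional[RegionSpec] = None,
) -> float:
    """Cα RMSD over `region` after superposition.

    With `fit_region` (e.g. the rigid N-terminal domain) the
    superposition is computed on that region only and the RMSD is then
    evaluated on `region` without refitting.
    """
    m_eval, r_eval = _map_region_ca(model, ref, region)
    if fit_region is None:
        sup = kabsch_superpose(m_eval, r_eval)
        return sup.rmsd
    m_fit, r_fit = _map_region_ca(model, ref, fit_region)
    sup = kabsch_superpose(m_fit, r_fit)
    diff = sup.apply(m_eval) - r_eval
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def region_rmsd_to_references(
    model: ProteinStructure,
    ref_alpha: ProteinStructure,
    ref_beta: ProteinStructure,
    region: RegionSpec,
    fit_region: Optional[RegionSpec] = None,
) -> Tuple[float, float]:
    """Cα RMSD of a model region against the two reference native states."""
    return (
        region_rmsd(model, ref_alpha, region, fit_region),
        region_rmsd(model, ref_beta, region, fit_region),
    )


def tm_d0(l_norm: int) -> float:
    if l_norm < 16:
        raise ValueError(f"TM-score normalisation length must be >= 16, got {l_norm}")
    return 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8


def _tm_from_transform(
    ref: np.ndarray, mob: np.ndarray, sup: SuperpositionResult, d0: float, l_norm: int
) -> float:
    d = np.linalg.norm(sup.apply(mob) - ref, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def tm_score(
    coords_ref: np.ndarray,
    coords_model: np.ndarray,
    l_norm: Optional[int] = None,
) -> TMScoreResult:
    """TM-score of a model against a reference with 1:1 correspondence."""
    ref = np.asarray(coords_ref, dtype=float)
    mob = np.asarray(coords_model, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must be equal-shape N x 3")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 residues")
    if l_norm is None:
        l_norm = n
    d0 = tm_d0(l_norm)

    best = 0.0
    frag_lengths = sorted({n, max(4, n // 2), max(4, n // 4)}, reverse=True)
    for flen in frag_lengths:
        step = max(1, flen // 2)
        for start in range(0, n - flen + 1, step):
            sel = np.arange(start, start + flen)
            try:
                sup = kabsch_superpose(mob[sel], ref[sel])
            except np.linalg.LinAlgError:  # pragma: no cover
                continue
            score = _tm_from_transform(ref, mob, sup, d0, l_norm)
            best = max(best, score)
            # iterative refinement on the residues within d0
            cutoff = d0
            for _ in range(20):
                d = np.linalg.norm(sup.apply(mob) - ref, axis=1)
                inc = np.nonzero(d < cutoff)[0]
                while len(inc) < 3:
                    cutoff += 0.5
                    inc = np.nonzero(d < cutoff)[0]
                sup_new = kabsch_superpose(mob[inc], ref[inc])
                score_new = _tm_from_transform(ref, mob, sup_new, d0, l_norm)
                best = max(best, score_new)
                if abs(score_new - score) < 1e-7:
                    break
                sup, score = sup_new, score_new
    return TMScoreResult(score=min(best, 1.0), d0=d0, aligned_length=n)
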