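"""Synthetic inputs with planted ground truth.

Structures are built from ideal internal coordinates by the Natural
Extension Reference Frame (NeRF) construction (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, standard angles).  An ideal α-helix uses
(φ, ψ) = (−57°, −47°); β-strands use (−139°, 135°).  A β-hairpin is
built as two antiparallel strands whose mutual placement is optimised
against the same Kabsch–Sander energy the assigner uses, so the
inter-strand hydrogen-bond register is consistent with its bridge
rules by construction.

Two-domain decoys emulate the structural classes seen in large-scale
predictions of a fold-switching family: an N-terminal domain stub, a
linker, and a C-terminal domain that is an α-helical hairpin (ALPHA),
a β-hairpin (BETA), one helix plus one strand pair (MIXED) or an
extended coil (NONE), with two marker residues planted at a chosen
Cβ–Cβ distance.  Transition trajectories are linear coordinate
interpolations with seeded isotropic Gaussian noise — statistical
stand-ins for steered-MD output, not physics.  Gene neighborhoods
surround a focal gene with background genes spaced so that only the
planted operon can satisfy the operon criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from metamorphscan.foldclass import FoldClassLabel
from metamorphscan.genomic_context import GeneRecord, OperonCriteria, ProximityCategory
from metamorphscan.secstruct import _hbond_energy, HB_ENERGY_CUTOFF
from metamorphscan.structures import AtomRecord, ProteinStructure, RegionSpec, Residue
from metamorphscan.trajcluster import Trajectory

# ideal backbone geometry (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.0, 116.2, 121.7
A_CA_C_O, A_N_CA_CB = 120.8, 110.5
T_CB = -122.5  # C(i)-N(i)-CA(i)-CB chirality torsion for L-amino acids

HELIX_PHI_PSI = (-57.0, -47.0)
# β-strand dihedrals: ψ is nudged from the textbook 135° to the value that
# makes the 2-residue repeat an exact translation (zero strand twist), so
# rigid antiparallel pairing holds at any strand length
STRAND_PHI_PSI = (-139.0, 136.46)


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, ∠(b,c,d)=angle (deg),
    dihedral(a,b,c,d)=torsion (deg)."""
    angle_r = math.radians(angle)
    torsion_r = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle_r),
            bond * math.sin(angle_r) * math.cos(torsion_r),
            bond * math.sin(angle_r) * math.sin(torsion_r),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi_psi: Sequence[Tuple[float, float]]):
    """N, CA, C positions for a chain with the given per-residue (φ, ψ)."""
    n = len(phi_psi)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([B_N_CA, 0.0, 0.0])]
    c0 = CA[0] + B_CA_C * np.array(
        [math.cos(math.pi - math.radians(A_N_CA_C)),
         math.sin(math.pi - math.radians(A_N_CA_C)), 0.0]
    )
    C = [c0]
    for i in range(1, n):
        psi_prev = phi_psi[i - 1][1]
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psi_prev))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, 180.0))
        phi = phi_psi[i][0]
        C.append(_place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phi))
    return N, CA, C


def _chain_atoms(phi_psi: Sequence[Tuple[float, float]]) -> List[Dict[str, np.ndarray]]:
    """Full backbone + CB atom dictionaries for a poly-ALA chain."""
    n = len(phi_psi)
    N, CA, C = _build_backbone(phi_psi)
    residues = []
    for i in range(n):
        atoms = {"N": N[i], "CA": CA[i], "C": C[i]}
        # carbonyl O in the peptide plane, trans to the next N
        psi = phi_psi[i][1]
        atoms["O"] = _place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi + 180.0)
        atoms["CB"] = _place_atom(C[i], N[i], CA[i], B_CA_CB, A_N_CA_CB, T_CB)
        residues.append(atoms)
    return residues


def _to_structure(
    atom_dicts: Sequence[Dict[str, np.ndarray]],
    names3: Optional[Sequence[str]] = None,
    plddt: float = 90.0,
    model_id: str = "synthetic",
) -> ProteinStructure:
    residues = []
    for i, atoms in enumerate(atom_dicts):
        name3 = names3[i] if names3 is not None else "ALA"
        recs = {n: AtomRecord(n, xyz.copy(), plddt) for n, xyz in atoms.items()}
        if name3 == "GLY":
            recs.pop("CB", None)
        residues.append(Residue(i + 1, name3, recs))
    return ProteinStructure("A", residues, model_id)


def _random_rigid(rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation (QR-based) and a bounded translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return Q, t


def _transform_atoms(atom_dicts, rotation, translation):
    return [
        {n: rotation @ xyz + translation for n, xyz in atoms.items()}
        for atoms in atom_dicts
    ]


def build_ideal_helix(n: int, seed: int = 0, plddt: float = 90.0) -> ProteinStructure:
    """Ideal poly-ALA α-helix (φ=−57°, ψ=−47°), randomly oriented by seed."""
    if n < 5:
        raise ValueError("an ideal helix needs at least 5 residues")
    atoms = _chain_atoms([HELIX_PHI_PSI] * n)
    rng = np.random.default_rng(seed)
    R, t = _random_rigid(rng)
    return _to_structure(_transform_atoms(atoms, R, t), plddt=plddt, model_id="helix")


def _strand_atoms(n: int) -> List[Dict[str, np.ndarray]]:
    return _chain_atoms([STRAND_PHI_PSI] * n)


def _strand_arrays(atoms):
    C = np.array([a["C"] for a in atoms])
    O = np.array([a["O"] for a in atoms])
    N = np.array([a["N"] for a in atoms])
    H = np.full_like(N, np.nan)
    for i in range(1, len(atoms)):
        v1 = N[i] - C[i - 1]
        v2 = N[i] - atoms[i]["CA"]
        v1 = v1 / np.linalg.norm(v1)
        v2 = v2 / np.linalg.norm(v2)
        d = v1 + v2
        H[i] = N[i] + 1.01 * d / np.linalg.norm(d)
    return C, O, N, H


def _dir_energy(C1, O1, N2, H2):
    """(bond count, clamped energy sum) for CO of strand 1 vs NH of strand 2.

    Individual Kabsch–Sander energies are clamped at −3 kcal/mol so that
    near-contact 1/r singularities cannot dominate the placement search.
    """
    q = 0.084 * 332.0

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        E = q * (
            1.0 / dist(O1, N2) + 1.0 / dist(C1, H2)
            - 1.0 / dist(O1, H2) - 1.0 / dist(C1, N2)
        )
    E = np.where(np.isfinite(E), E, 0.0)
    bonds = E < HB_ENERGY_CUTOFF
    return int(bonds.sum()), float(np.clip(E[bonds], -3.0, 0.0).sum())


def _strand_frame(CA: np.ndarray):
    """Deterministic orthonormal frame (u, e1, e2) of a flat strand:
    u along the exact 2-residue repeat, e1 in the pleat plane."""
    u = CA[2] - CA[0]
    u = u / np.linalg.norm(u)
    d1 = CA[1] - CA[0]
    e1 = d1 - (d1 @ u) * u
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return u, e1, e2


class _DyadScorer:
    """Scores a 2-fold placement of a strand against its own image."""

    def __init__(self, n: int):
        self.s1 = _strand_atoms(n)
        self.C, self.O, self.N, self.H = _strand_arrays(self.s1)
        self.CA = np.array([a["CA"] for a in self.s1])
        self.centroid = self.CA.mean(axis=0)
        self.u, self.e1, self.e2 = _strand_frame(self.CA)
        self.heavy = np.vstack([self.N, self.CA, self.C, self.O])

    def transform(self, alpha: float, gamma: float, delta: float):
        v = math.cos(alpha) * self.e1 + math.sin(alpha) * self.e2
        w = np.cross(self.u, v)
        p = self.centroid - gamma * w - delta * self.u
        R = 2.0 * np.outer(v, v) - np.eye(3)
        return lambda X: (X - p) @ R.T + p

    def score(self, alpha: float, gamma: float, delta: float):
        """(−bond count, clamped energy); None when strands clash."""
        tr = self.transform(alpha, gamma, delta)
        other = tr(self.heavy)
        dmin = np.min(
            np.linalg.norm(self.heavy[:, None, :] - other[None, :, :], axis=2)
        )
        if dmin < 2.5:
            return None
        n_ab, e_ab = _dir_energy(self.C, self.O, tr(self.N), tr(self.H))
        n_ba, e_ba = _dir_energy(tr(self.C), tr(self.O), self.N, self.H)
        if n_ab + n_ba == 0:
            return None
        return (-(n_ab + n_ba), e_ab + e_ba)


@lru_cache(maxsize=4)
def _dyad_params(n_mod4: int) -> Tuple[float, float, float]:
    """Optimal dyad placement, scanned once on a short reference strand.

    Flat strands repeat exactly every 2 residues, so the optimum is
    length-independent apart from the register phase, which cycles with
    the residue count modulo 4; one scan per congruence class suffices.
    """
    scorer = _DyadScorer(8 + n_mod4)
    best = (None, None)
    for alpha in np.linspace(0.0, 2 * math.pi, 60, endpoint=False):
        for gamma in np.arange(1.6, 3.21, 0.1):
            for delta in np.arange(-1.8, 1.81, 0.15):
                s = scorer.score(alpha, gamma, delta)
                if s is not None and (best[0] is None or s < best[0]):
                    best = (s, (alpha, gamma, delta))
    if best[1] is None:
        raise RuntimeError("no hydrogen-bonded strand placement found")
    return best[1]


def _paired_antiparallel_strands(n_per_strand: int):
    return _paired_antiparallel_strands_cached(n_per_strand)


@lru_cache(maxsize=64)
def _paired_antiparallel_strands_cached(n: int):
    """Two antiparallel strands related by an exact 2-fold (dyad) rotation,
    locally refined around the cached per-phase optimum."""
    scorer = _DyadScorer(n)
    a0, g0, d0 = _dyad_params(n % 4)
    best = (scorer.score(a0, g0, d0), (a0, g0, d0))
    for da in np.linspace(-0.05, 0.05, 5):
        for dg in np.linspace(-0.05, 0.05, 5):
            for dd in np.linspace(-0.075, 0.075, 5):
                s = scorer.score(a0 + da, g0 + dg, d0 + dd)
                if s is not None and (best[0] is None or s < best[0]):
                    best = (s, (a0 + da, g0 + dg, d0 + dd))
    if best[0] is None:
        raise RuntimeError("no hydrogen-bonded strand placement found")
    tr = scorer.transform(*best[1])
    s2 = [{k: tr(xyz[None, :])[0] for k, xyz in a.items()} for a in scorer.s1]
    # the image strand runs antiparallel; chain order stays N→C
    return scorer.s1, s2


def _turn_atoms(anchor_c: np.ndarray, anchor_n: np.ndarray, n_res: int = 2):
    """Approximate connecting residues bridging two backbone anchors."""
    atoms = []
    gap = anchor_n - anchor_c
    perp = np.cross(gap, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp) * 1.8
    for i in range(n_res):
        f0 = (i + 0.25) / n_res
        f1 = (i + 0.55) / n_res
        f2 = (i + 0.85) / n_res
        bulge = math.sin(math.pi * (i + 0.5) / n_res)
        n_pos = anchor_c + f0 * gap + bulge * perp
        ca_pos = anchor_c + f1 * gap + bulge * perp
        c_pos = anchor_c + f2 * gap + bulge * perp
        atoms.append(
            {
                "N": n_pos,
                "CA": ca_pos,
                "C": c_pos,
                "O": c_pos + np.array([0.0, 0.0, B_C_O]),
                "CB": ca_pos + np.array([0.0, 0.0, -B_CA_CB]),
            }
        )
    return atoms


def build_beta_hairpin(
    n_per_strand: int, seed: int = 0, plddt: float = 90.0
) -> ProteinStructure:
    """Antiparallel two-strand β-hairpin with a 2-residue turn."""
    if n_per_strand < 4:
        raise ValueError("a hairpin strand needs at least 4 residues")
    atoms = _hairpin_atoms(n_per_strand)
    rng = np.random.default_rng(seed)
    R, t = _random_rigid(rng)
    return _to_structure(_transform_atoms(atoms, R, t), plddt=plddt, model_id="hairpin")


def _hairpin_atoms(n_per_strand: int) -> List[Dict[str, np.ndarray]]:
    s1, s2 = _paired_antiparallel_strands(n_per_strand)
    turn = _turn_atoms(s1[-1]["C"], s2[0]["N"])
    return list(s1) + turn + list(s2)


def _helix_hairpin_atoms(n_total: int) -> List[Dict[str, np.ndarray]]:
    """Two α-helices joined by a short loop (an α-helical hairpin)."""
    n1 = (n_total - 3) // 2
    n2 = n_total - 3 - n1
    phi_psi = (
        [HELIX_PHI_PSI] * n1
        + [(-80.0, 80.0), (-120.0, 120.0), (-80.0, 80.0)]
        + [HELIX_PHI_PSI] * n2
    )
    return _chain_atoms(phi_psi)


@dataclass(frozen=True)
class StructureRecipe:
    """Recipe for a two-domain decoy with a planted fold label."""

    fold_label: FoldClassLabel
    ctd_length: int = 53
    ntd_length: int = 40
    marker_pair_distance: float = 9.6  # Å, planted Cβ–Cβ distance
    seed: int = 0
    plddt: float = 90.0

    def __post_init__(self) -> None:
        if self.ctd_length < 8 or self.ntd_length < 8:
            raise ValueError("domain lengths must be >= 8 residues")
        if self.marker_pair_distance <= 0:
            raise ValueError("marker distance must be positive")


@dataclass
class DecoyMetadata:
    """Planted truth returned with every two-domain decoy."""

    fold_label: FoldClassLabel
    ctd_region: RegionSpec
    marker_pos_a: int
    marker_pos_b: int
    marker_distance: float


def _ctd_atoms(label: FoldClassLabel, n: int) -> List[Dict[str, np.ndarray]]:
    if label == FoldClassLabel.ALPHA:
        return _helix_hairpin_atoms(n)
    if label == FoldClassLabel.BETA:
        per = (n - 2) // 2
        atoms = _hairpin_atoms(per)
        while len(atoms) < n:  # pad with extended tail residues
            tail = _chain_atoms([STRAND_PHI_PSI] * (n - len(atoms) + 1))
            anchor = atoms[-1]["C"]
            shift = anchor + np.array([25.0, 25.0, 0.0]) - tail[1]["N"]
            atoms += _transform_atoms(tail[1:], np.eye(3), shift)
        return atoms[:n]
    if label == FoldClassLabel.MIXED:
        n_helix = max(8, int(round(0.30 * n)))
        per = (n - n_helix - 4) // 2
        helix = _chain_atoms([HELIX_PHI_PSI] * n_helix)
        hairpin = _hairpin_atoms(max(4, per))
        # keep the strand pair well apart from the helix
        shift = helix[-1]["C"] + np.array([20.0, 20.0, 0.0]) - hairpin[0]["N"]
        hairpin = _transform_atoms(hairpin, np.eye(3), shift)
        turn = _turn_atoms(helix[-1]["C"], hairpin[0]["N"])
        atoms = helix + turn + hairpin
        while len(atoms) < n:
            atoms.append(
                {k: v + np.array([3.5, 0.0, 0.0]) for k, v in atoms[-1].items()}
            )
        return atoms[:n]
    # NONE: extended coil, a single strand with no partner
    return _chain_atoms([STRAND_PHI_PSI] * n)


def build_two_domain_decoy(
    recipe: StructureRecipe,
) -> Tuple[ProteinStructure, DecoyMetadata]:
    """NTD stub + linker + CTD with the planted fold and marker distance.

    The marker residues (GLU in the NTD, ARG in the CTD) are placed so
    their Cβ–Cβ distance equals ``marker_pair_distance`` exactly, with
    the CTD body oriented away from the NTD to avoid spurious contacts.
    """
    rng = np.random.default_rng(recipe.seed)
    n_helix_ntd = max(8, int(round(0.6 * recipe.ntd_length)))
    ntd = _chain_atoms(
        [HELIX_PHI_PSI] * n_helix_ntd
        + [STRAND_PHI_PSI] * (recipe.ntd_length - n_helix_ntd)
    )
    linker_len = 4
    ctd = _ctd_atoms(recipe.fold_label, recipe.ctd_length)

    marker_a = n_helix_ntd // 2  # 0-based index into the NTD
    marker_b_local = min(len(ctd) - 1, recipe.ctd_length // 2)

    # orient the CTD randomly, then point its body away from the NTD
    R, _ = _random_rigid(rng)
    ctd = _transform_atoms(ctd, R, np.zeros(3))
    ntd_centroid = np.mean([a["CA"] for a in ntd], axis=0)
    cb_a = ntd[marker_a]["CB"]
    direction = cb_a - ntd_centroid
    direction /= np.linalg.norm(direction)
    ctd_centroid = np.mean([a["CA"] for a in ctd], axis=0)
    cb_b = ctd[marker_b_local]["CB"]
    body = ctd_centroid - cb_b
    if np.linalg.norm(body) > 1e-9:
        R_align = _rotation_between(body / np.linalg.norm(body), direction)
        pivot = cb_b
        ctd = [
            {k: R_align @ (v - pivot) + pivot for k, v in a.items()} for a in ctd
        ]
    target_cb_b = cb_a + recipe.marker_pair_distance * direction
    ctd = _transform_atoms(ctd, np.eye(3), target_cb_b - ctd[marker_b_local]["CB"])

    linker = _turn_atoms(ntd[-1]["C"], ctd[0]["N"], n_res=linker_len)
    atoms = ntd + linker + ctd

    names3 = ["ALA"] * len(atoms)
    pos_a = marker_a + 1
    pos_b = recipe.ntd_length + linker_len + marker_b_local + 1
    names3[pos_a - 1] = "GLU"
    names3[pos_b - 1] = "ARG"
    structure = _to_structure(
        atoms, names3, recipe.plddt, model_id=f"decoy_{recipe.fold_label.value}"
    )
    R_glob, t_glob = _random_rigid(rng)
    structure = structure.transformed(R_glob, t_glob)
    meta = DecoyMetadata(
        fold_label=recipe.fold_label,
        ctd_region=RegionSpec(
            recipe.ntd_length + linker_len + 1,
            recipe.ntd_length + linker_len + recipe.ctd_length,
        ),
        marker_pos_a=pos_a,
        marker_pos_b=pos_b,
        marker_distance=recipe.marker_pair_distance,
    )
    return structure, meta


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite vectors: rotate π about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        K = _skew(axis)
        return np.eye(3) + 2.0 * K @ K
    axis /= s
    K = _skew(axis)
    theta = math.atan2(s, c)
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * K @ K


def _skew(a: np.ndarray) -> np.ndarray:
    return np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])


# ---------------------------------------------------------------------------
# trajectories


def structure_atoms_flat(structure: ProteinStructure):
    """(coords, residue indices, atom names) in a canonical atom order."""
    coords, resi, names = [], [], []
    for res in structure.residues:
        for name in sorted(res.atoms):
            coords.append(res.atoms[name].coords)
            resi.append(res.index)
            names.append(name)
    return np.array(coords), np.array(resi), names


def simulate_transition_trajectory(
    start: ProteinStructure,
    end: ProteinStructure,
    n_frames: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    direction: str = "alpha_to_beta",
    force_constant: float = 0.01,
    traj_id: str = "traj",
) -> Trajectory:
    """Linear interpolation start → end with isotropic Gaussian noise.

    Frame 1 is the start conformation (plus noise), frame n the end.
    Both structures must share the same residue/atom layout.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    c0, resi0, names0 = structure_atoms_flat(start)
    c1, resi1, names1 = structure_atoms_flat(end)
    if c0.shape != c1.shape or names0 != names1 or not np.array_equal(resi0, resi1):
        raise ValueError("start and end structures have different atom layouts")
    rng = np.random.default_rng(seed)
    ts = np.linspace(0.0, 1.0, n_frames)
    frames = np.array([(1 - t) * c0 + t * c1 for t in ts])
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return Trajectory(
        frames=frames, atom_residues=resi0, atom_names=names0,
        direction=direction, force_constant=force_constant, traj_id=traj_id,
    )


# ---------------------------------------------------------------------------
# gene neighborhoods


@dataclass(frozen=True)
class PlantedOperon:
    n_members: int = 3
    member_length: int = 2000
    gap: int = 50
    strand: str = "+"
    offset: int = 500  # bp between the focal gene and the operon promoter end
    focal_inside: bool = False


@dataclass(frozen=True)
class NeighborhoodRecipe:
    """A focal gene, background genes, and an optional planted operon."""

    n_genes: int = 10  # background genes (up to 15 on each side in real data)
    planted_operon: Optional[PlantedOperon] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")


@dataclass
class NeighborhoodTruth:
    operon_gene_ids: List[str]  # empty if no qualifying operon planted
    expected_category: Optional[ProximityCategory]
    expected_distance: Optional[int]


_BG_GAP = (250, 800)  # background gaps always exceed max_intergenic=200
_BG_LEN = (300, 1500)


def simulate_gene_neighborhood(
    recipe: NeighborhoodRecipe,
    criteria: OperonCriteria = OperonCriteria(),
) -> Tuple[List[GeneRecord], GeneRecord, NeighborhoodTruth]:
    """Genes sorted by coordinate, the focal gene, and the planted truth.

    Background genes are separated by gaps larger than the intergenic
    cutoff, so no background run can qualify as an operon; the planted
    operon (if any) is the only candidate.
    """
    rng = np.random.default_rng(recipe.seed)
    op = recipe.planted_operon
    focal_len = int(rng.integers(400, 701))
    genes: List[GeneRecord] = []

    n_left = recipe.n_genes // 2
    n_right = recipe.n_genes - n_left

    cursor = 10_000
    for i in range(n_left):
        length = int(rng.integers(*_BG_LEN))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"bg_l{i}", cursor, cursor + length - 1, strand))
        cursor += length + int(rng.integers(*_BG_GAP))

    truth_ids: List[str] = []
    expected_cat: Optional[ProximityCategory] = None
    expected_dist: Optional[int] = None

    if op is None:
        focal = GeneRecord("focal", cursor, cursor + focal_len - 1, "+")
        genes.append(focal)
        cursor = focal.end + 1 + int(rng.integers(*_BG_GAP))
    else:
        members: List[Tuple[str, int]] = [
            (f"op{i}", op.member_length) for i in range(op.n_members)
        ]
        if op.focal_inside:
            insert_at = op.n_members // 2
            members.insert(insert_at, ("focal", focal_len))
        focal_strand = op.strand if op.focal_inside else "+"

        if op.focal_inside:
            block_start = cursor
            focal = _lay_block(genes, members, block_start, op, focal_strand)
            cursor = max(g.end for g in genes) + 1 + int(rng.integers(*_BG_GAP))
        elif op.strand == "+":
            # operon downstream of the focal gene; distance |focal.end - span_start|
            focal = GeneRecord("focal", cursor, cursor + focal_len - 1, "+")
            genes.append(focal)
            block_start = focal.end + op.offset
            _lay_block(genes, members, block_start, op, None)
            cursor = max(g.end for g in genes) + 1 + int(rng.integers(*_BG_GAP))
        else:
            # '-' operon upstream: its last gene's end is the promoter side
            block_start = cursor
            _lay_block(genes, members, block_start, op, None)
            span_end = max(g.end for g in genes if g.gene_id.startswith("op"))
            focal_start = span_end + op.offset
            focal = GeneRecord("focal", focal_start, focal_start + focal_len - 1, "+")
            genes.append(focal)
            cursor = focal.end + 1 + int(rng.integers(*_BG_GAP))

        span = op.n_members * op.member_length + (op.n_members - 1) * op.gap
        if op.focal_inside:
            span += focal_len + op.gap
        # a same-strand '+' operon laid within the intergenic cutoff of the
        # focal gene absorbs it into the run: the planted truth is INSIDE
        absorbed = (
            not op.focal_inside
            and op.strand == "+"
            and op.offset - 1 <= criteria.max_intergenic
        )
        if absorbed:
            span += focal_len + op.offset - 1
        qualifies = (
            op.n_members + (1 if op.focal_inside or absorbed else 0)
            >= criteria.min_genes
            and span > criteria.min_operon_length
            and op.gap <= criteria.max_intergenic
        )
        if qualifies:
            truth_ids = [m[0] for m in members]
            if absorbed:
                truth_ids = ["focal"] + truth_ids
            if op.focal_inside or absorbed:
                expected_cat = ProximityCategory.INSIDE
                expected_dist = None
            else:
                expected_dist = op.offset
                if op.offset < criteria.proximity_cutoff:
                    expected_cat = (
                        ProximityCategory.NEAR_SAME_DIRECTION
                        if focal.strand == op.strand
                        else ProximityCategory.NEAR_OPPOSITE_DIRECTION
                    )
                else:
                    expected_cat = ProximityCategory.DISTANT

    for i in range(n_right):
        length = int(rng.integers(*_BG_LEN))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"bg_r{i}", cursor, cursor + length - 1, strand))
        cursor += length + int(rng.integers(*_BG_GAP))

    genes.sort(key=lambda g: (g.start, g.end))
    truth = NeighborhoodTruth(truth_ids, expected_cat, expected_dist)
    return genes, focal, truth


def _lay_block(genes, members, block_start, op: PlantedOperon, focal_strand):
    """Lay consecutive same-strand genes with the recipe gap; returns the
    focal record if it is among the members."""
    pos = block_start
    focal = None
    for gid, length in members:
        strand = op.strand if focal_strand is None or gid != "focal" else focal_strand
        rec = GeneRecord(gid, pos, pos + length - 1, strand)
        genes.append(rec)
        if gid == "focal":
            focal = rec
        pos = rec.end + 1 + op.gap
    return focal
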