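"""Restraint energy, PCA maps and k-means clustering of trajectories.

The targeted-MD restraint energy for steering a structure toward a
target conformation is the quadratic form

    E_TMD = 1/2 * k * N * (RMSD(t) - RMSD_target)^2

with k the force constant (kcal/(mol·Å²)) and N the number of
collective-variable atoms.  Trajectories are embedded in a universal
PCA map built from the Cα coordinate covariance of the fold-switching
region after rigid-body alignment on the N-terminal domain, clustered
by k-means in the PC1/PC2 plane, and reduced to representative
pathways (the trajectory owning each cluster's centroid frame) or to
medoid structures in RMSD feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from metamorphscan.structures import ProteinStructure, RegionSpec
from metamorphscan.superpose import kabsch_superpose, region_rmsd_to_references


@dataclass(frozen=True)
class TMDParams:
    """Restraint parameters: force constant k, atom count N, target RMSD."""

    k: float  # kcal/(mol·Å²)
    n_atoms: int
    rmsd_target: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("force constant must be positive")
        if self.n_atoms < 1:
            raise ValueError("need at least one collective-variable atom")
        if self.rmsd_target < 0:
            raise ValueError("target RMSD cannot be negative")


def tmd_energy(rmsd_t: float, params: TMDParams) -> float:
    """½·k·N·(RMSD(t) − RMSD_target)² in kcal/mol."""
    if rmsd_t < 0:
        raise ValueError("RMSD cannot be negative")
    return 0.5 * params.k * params.n_atoms * (rmsd_t - params.rmsd_target) ** 2


@dataclass
class Trajectory:
    """Multi-frame coordinates with per-atom residue/name bookkeeping."""

    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    atom_residues: np.ndarray  # (n_atoms,), 1-based residue index per atom
    atom_names: List[str]
    direction: str = "alpha_to_beta"
    force_constant: float = 0.0
    traj_id: str = "traj"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.atom_residues = np.asarray(self.atom_residues, dtype=int)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.frames.shape[1] != len(self.atom_residues) or len(
            self.atom_names
        ) != len(self.atom_residues):
            raise ValueError("atom bookkeeping length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def ca_mask(self, region: Optional[RegionSpec] = None) -> np.ndarray:
        mask = np.array([name == "CA" for name in self.atom_names])
        if region is not None:
            mask &= (self.atom_residues >= region.start) & (
                self.atom_residues <= region.end
            )
        if not mask.any():
            raise ValueError("no Cα atoms in the requested region")
        return mask


@dataclass
class PCAMap:
    """Universal PCA basis over aligned region coordinates."""

    mean: np.ndarray  # flattened analysis-region coordinates
    eigenvectors: np.ndarray  # rows, descending variance, orthonormal
    eigenvalues: np.ndarray  # descending, non-negative
    fit_region: RegionSpec
    analysis_region: RegionSpec
    ref_fit_coords: np.ndarray  # fit-region Cα of the reference frame

    @property
    def total_variance(self) -> float:
        return float(np.sum(self.eigenvalues))


@dataclass
class ClusterAssignment:
    """k-means labels, centers, and per-cluster representative items."""

    labels: np.ndarray
    centers: np.ndarray
    representative: Dict[int, int] = field(default_factory=dict)
    features: Optional[np.ndarray] = None

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


def _aligned_region_frames(
    trajectories: Sequence[Trajectory],
    fit_region: RegionSpec,
    analysis_region: RegionSpec,
    ref_fit: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Superpose every frame on the reference fit-region Cα and return the
    flattened analysis-region Cα coordinates, one row per frame."""
    rows, traj_ids = [], []
    ref = ref_fit
    for traj in trajectories:
        fit_mask = traj.ca_mask(fit_region)
        ana_mask = traj.ca_mask(analysis_region)
        for frame in traj.frames:
            if ref is None:
                ref = frame[fit_mask]
            sup = kabsch_superpose(frame[fit_mask], ref)
            rows.append(sup.apply(frame[ana_mask]).ravel())
            traj_ids.append(traj.traj_id)
    return np.array(rows), ref, traj_ids


def build_pca_map(
    trajectories: Sequence[Trajectory],
    fit_region: RegionSpec,
    analysis_region: RegionSpec,
) -> PCAMap:
    """Coordinate-covariance PCA of the analysis region Cα atoms.

    Every frame is first superposed (fit_region Cα) onto the first
    frame of the first trajectory to remove rigid-body motion, then the
    covariance matrix of the flattened coordinates is diagonalised.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    X, ref_fit, _ = _aligned_region_frames(trajectories, fit_region, analysis_region)
    if X.shape[0] < 2:
        raise ValueError("need at least two frames in total")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows
    if evals[0] <= 1e-12:
        warnings.warn("degenerate covariance: all frames identical", RuntimeWarning)
    return PCAMap(mean, evecs, evals, fit_region, analysis_region, ref_fit)


def project(
    trajectory: Trajectory, pca_map: PCAMap, n_components: int = 2
) -> np.ndarray:
    """Per-frame coordinates of a trajectory in the leading PC plane."""
    X, _, _ = _aligned_region_frames(
        [trajectory], pca_map.fit_region, pca_map.analysis_region,
        ref_fit=pca_map.ref_fit_coords,
    )
    if X.shape[1] != pca_map.mean.shape[0]:
        raise ValueError(
            f"atom-count mismatch: trajectory gives {X.shape[1]} features, "
            f"map expects {pca_map.mean.shape[0]}"
        )
    return (X - pca_map.mean) @ pca_map.eigenvectors[:n_components].T


def project_all(
    trajectories: Sequence[Trajectory], pca_map: PCAMap, n_components: int = 2
):
    """Project many trajectories; returns (points, frame-wise traj ids)."""
    points, ids = [], []
    for traj in trajectories:
        p = project(traj, pca_map, n_components)
        points.append(p)
        ids.extend([traj.traj_id] * p.shape[0])
    return np.vstack(points), ids


def kmeans_cluster(points: np.ndarray, k: int, seed: int) -> ClusterAssignment:
    """Seeded Lloyd's k-means with k-means++ initialisation."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {pts.shape[0]} points")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=300, tol=1e-6,
        random_state=seed,
    ).fit(pts)
    return ClusterAssignment(
        labels=km.labels_.astype(int), centers=km.cluster_centers_, features=pts
    )


def select_representative_trajectories(
    points: np.ndarray,
    traj_ids: Sequence[str],
    assignment: ClusterAssignment,
) -> List[str]:
    """Per cluster, the trajectory owning the frame nearest the center.

    Duplicate selections collapse, so the returned set may be smaller
    than the number of clusters.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] != len(traj_ids):
        raise ValueError("every frame needs a trajectory id")
    selected = []
    for c in range(assignment.centers.shape[0]):
        members = assignment.members(c)
        if members.size == 0:
            warnings.warn(f"cluster {c} is empty; skipped", RuntimeWarning)
            continue
        d = np.linalg.norm(pts[members] - assignment.centers[c], axis=1)
        centroid_frame = members[int(np.argmin(d))]
        assignment.representative[c] = int(centroid_frame)
        tid = traj_ids[centroid_frame]
        if tid not in selected:
            selected.append(tid)
    return selected


def _medoid(features: np.ndarray, members: np.ndarray) -> int:
    sub = features[members]
    dists = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
    return int(members[int(np.argmin(dists.sum(axis=1)))])


def cluster_structures_by_rmsd(
    structures: Sequence[ProteinStructure],
    ref_alpha: ProteinStructure,
    ref_beta: ProteinStructure,
    region: RegionSpec,
    k: int,
    seed: int,
    fit_region: Optional[RegionSpec] = None,
) -> ClusterAssignment:
    """k-means over the (RMSD-to-α, RMSD-to-β) feature plane with medoids.

    The representative of each cluster is the medoid: the member
    minimising the summed in-cluster feature distance (ties break to
    the lowest structure index).
    """
    features = np.array(
        [
            region_rmsd_to_references(s, ref_alpha, ref_beta, region, fit_region)
            for s in structures
        ]
    )
    assignment = kmeans_cluster(features, k, seed)
    for c in range(k):
        members = assignment.members(c)
        if members.size == 0:
            warnings.warn(f"cluster {c} is empty; skipped", RuntimeWarning)
            continue
        assignment.representative[c] = _medoid(features, members)
    return assignment


def trajectory_from_structures(
    structures: Sequence[ProteinStructure],
    direction: str = "alpha_to_beta",
    force_constant: float = 0.0,
    traj_id: str = "traj",
) -> Trajectory:
    """Stack the models of a multi-model file into one Trajectory.

    All models must share the same residue/atom layout; atoms are taken
    in a canonical per-residue order.
    """
    if len(structures) < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    layouts = []
    frames = []
    for st in structures:
        coords, resi, names = [], [], []
        for res in st.residues:
            for name in sorted(res.atoms):
                coords.append(res.atoms[name].coords)
                resi.append(res.index)
                names.append(name)
        layouts.append((tuple(resi), tuple(names)))
        frames.append(np.array(coords))
    if len(set(layouts)) != 1:
        raise ValueError("models differ in residue/atom layout")
    resi, names = layouts[0]
    return Trajectory(
        frames=np.array(frames),
        atom_residues=np.array(resi),
        atom_names=list(names),
        direction=direction,
        force_constant=force_constant,
        traj_id=traj_id,
    )


def frame_rmsd(
    trajectory: Trajectory,
    target_coords: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Best-fit RMSD of each frame's (masked) atoms to target coordinates."""
    target = np.asarray(target_coords, dtype=float)
    out = []
    for frame in trajectory.frames:
        sel = frame if mask is None else frame[mask]
        out.append(kabsch_superpose(sel, target).rmsd)
    return np.array(out)
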