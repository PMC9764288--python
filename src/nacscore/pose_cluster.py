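"""RMSD-based grouping of ligand poses.

Two jobs share one distance: separating docking solutions into binding-mode
clusters (threshold 5 Angstrom) and removing redundant rotamers from a
conformer library (threshold 0.2 Angstrom).  The RMSD is computed in the
shared receptor frame with *no* superposition — docking poses and rotamers
live in one fixed active site, and superposing them would erase exactly the
binding-mode differences being measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LigandPose:
    """An ordered heavy-atom coordinate set with a docking/rotamer energy."""

    pose_id: str
    atom_names: tuple
    coords: np.ndarray          # shape (n_atoms, 3)
    energy: float               # lower is better

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        if len(self.atom_names) < 3:
            raise ValueError("a pose needs at least 3 atoms")
        if coords.shape != (len(self.atom_names), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.atom_names)} atom names")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite pose coordinates")


@dataclass
class Cluster:
    representative: LigandPose
    members: list               # pose_ids
    best_energy: float


def pose_rmsd(a: LigandPose, b: LigandPose) -> float:
    """Coordinate RMSD over matched atoms, no superposition."""
    if a.atom_names != b.atom_names:
        raise ValueError(
            f"atom order mismatch: {a.atom_names} vs {b.atom_names}")
    diff = a.coords - b.coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def greedy_cluster(poses: Sequence[LigandPose], threshold: float) -> list[Cluster]:
    """Leader clustering of poses at an RMSD threshold.

    Poses are visited in ascending energy (ties by pose_id).  A pose joins
    the first existing cluster whose representative lies strictly within
    the threshold; otherwise it founds a new cluster with itself as
    representative.  Because visiting order is energy-ascending, each
    representative is the lowest-energy member of its cluster.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("greedy_cluster needs at least one pose")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ordered = sorted(poses, key=lambda p: (p.energy, p.pose_id))
    clusters: list[Cluster] = []
    for pose in ordered:
        for cluster in clusters:
            if pose_rmsd(pose, cluster.representative) < threshold:
                cluster.members.append(pose.pose_id)
                cluster.best_energy = min(cluster.best_energy, pose.energy)
                break
        else:
            clusters.append(Cluster(representative=pose,
                                    members=[pose.pose_id],
                                    best_energy=pose.energy))
    return clusters


def select_lowest_energy_cluster(clusters: Sequence[Cluster]) -> Cluster:
    """The cluster with minimal best energy; ties resolved by representative id."""
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters to select from")
    best = min(clusters, key=lambda c: (c.best_energy, c.representative.pose_id))
    ties = [c for c in clusters
            if c.best_energy == best.best_energy and c is not best]
    if ties:
        warnings.warn(
            f"lowest-energy tie at {best.best_energy}; picked representative "
            f"{best.representative.pose_id} by pose_id order")
    return best


def dedupe_rotamers(poses: Sequence[LigandPose], threshold: float = 0.2,
                    max_keep: Optional[int] = None) -> list[LigandPose]:
    """Remove overlapping rotamers in a single greedy pass over input order.

    A pose is kept iff its RMSD to every already-kept pose is >= threshold
    (overlap means strictly closer than the threshold).  Keeping stops at
    ``max_keep`` survivors when given.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if max_keep is not None and max_keep < 1:
        raise ValueError("max_keep must be >= 1")
    kept: list[LigandPose] = []
    for pose in poses:
        if all(pose_rmsd(pose, k) >= threshold for k in kept):
            kept.append(pose)
            if max_keep is not None and len(kept) >= max_keep:
                break
    return kept


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_poses_csv(path) -> list[LigandPose]:
    """Read poses from CSV: pose_id, energy, then <name>_x, <name>_y, <name>_z."""
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c.endswith(("_x", "_y", "_z"))]
    names = []
    for c in coord_cols:
        base = c[:-2]
        if base not in names:
            names.append(base)
    poses = []
    for _, row in df.iterrows():
        coords = np.array([[row[f"{n}_x"], row[f"{n}_y"], row[f"{n}_z"]]
                           for n in names], dtype=float)
        poses.append(LigandPose(pose_id=str(row["pose_id"]),
                                atom_names=tuple(names), coords=coords,
                                energy=float(row["energy"])))
    return poses


def write_poses_csv(poses: Sequence[LigandPose], path) -> None:
    rows = []
    for p in poses:
        row = {"pose_id": p.pose_id, "energy": p.energy}
        for name, xyz in zip(p.atom_names, p.coords):
            row[f"{name}_x"], row[f"{name}_y"], row[f"{name}_z"] = xyz
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def clusters_to_dataframe(clusters: Sequence[Cluster]) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters):
        for pid in c.members:
            rows.append({"pose_id": pid, "cluster_id": i,
                         "is_representative": pid == c.representative.pose_id,
                         "cluster_best_energy": c.best_energy})
    return pd.DataFrame(rows, columns=["pose_id", "cluster_id",
                                       "is_representative",
                                       "cluster_best_energy"])
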