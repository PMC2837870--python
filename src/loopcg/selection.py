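"""Model selection from replica-exchange trajectories.

The blind top model is the *medoid* of the collated trajectory snapshots —
the snapshot minimizing the summed pairwise distance to all others.  In
well-converged annealed runs the whole-trajectory medoid tends to sit at
least as close to the truth as the largest cluster's medoid, so the global
medoid is the default selector; K-means clusters and their medoids are
reported for diagnostics.

By default distances are measured over loop-region Cα coordinates after
superposing each snapshot's scaffold onto a common frame: the scaffold is
nearly identical across snapshots, and whole-chain distances would wash
out the loop diversity that actually distinguishes models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .evaluation import kabsch_superpose, loop_crmsd_coords
from .lattice import LatticeConformation
from .remc import Trajectory

__all__ = [
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "kmeans_cluster",
    "global_medoid",
    "select_top_model",
    "select_best_model",
]


@dataclass
class ClusterResult:
    labels: np.ndarray
    medoid_per_cluster: list[int]
    global_medoid: int
    rmsd_matrix: np.ndarray
    inertia: float


def pairwise_rmsd_matrix(snapshots: list[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of Kabsch-superposed Cα RMSDs (Å)."""
    n = len(snapshots)
    coords = [np.asarray(s, float) for s in snapshots]
    if any(c.shape != coords[0].shape for c in coords):
        raise ValueError("snapshots must have equal lengths")
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            _, _, rmsd = kabsch_superpose(coords[a], coords[b])
            m[a, b] = m[b, a] = rmsd
    return m


def _superposed_frames(snapshots: list[np.ndarray],
                       scaffold_indices: np.ndarray) -> np.ndarray:
    """Snapshots rigidly moved so their scaffolds overlay snapshot 0's."""
    ref = snapshots[0]
    out = np.empty((len(snapshots),) + ref.shape)
    out[0] = ref
    for k in range(1, len(snapshots)):
        R, t, _ = kabsch_superpose(snapshots[k][scaffold_indices], ref[scaffold_indices])
        out[k] = snapshots[k] @ R.T + t
    return out


def _loop_distance_matrix(snapshots: list[np.ndarray], loop_indices: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise loop-region RMSD after common-frame scaffold superposition.

    Returns (matrix, per-snapshot flattened loop features).
    """
    n_res = len(snapshots[0])
    loop = np.asarray(loop_indices, int)
    scaffold = np.setdiff1d(np.arange(n_res), loop)
    frames = _superposed_frames(snapshots, scaffold)
    feats = frames[:, loop, :].reshape(len(snapshots), -1)
    diff = feats[:, None, :] - feats[None, :, :]
    m = np.sqrt((diff ** 2).sum(axis=2) / len(loop))
    return m, feats


def _distance_and_features(snapshots, loop_indices):
    if loop_indices is not None:
        return _loop_distance_matrix(snapshots, loop_indices)
    m = pairwise_rmsd_matrix(snapshots)
    # common frame for features: superpose everything onto the row-sum medoid
    med = int(np.argmin(m.sum(axis=1)))
    feats = np.empty((len(snapshots), snapshots[0].size))
    for k, s in enumerate(snapshots):
        R, t, _ = kabsch_superpose(s, snapshots[med])
        feats[k] = (s @ R.T + t).ravel()
    return m, feats


def global_medoid(snapshots: list[np.ndarray], loop_indices=None) -> int:
    """Index minimizing the row-sum of the pairwise RMSD matrix (ties: lowest)."""
    if len(snapshots) == 0:
        raise ValueError("no snapshots")
    m, _ = _distance_and_features(snapshots, loop_indices)
    return int(np.argmin(m.sum(axis=1)))


def kmeans_cluster(snapshots: list[np.ndarray], k: int, seed: int = 0,
                   loop_indices=None) -> ClusterResult:
    """K-means over superposed coordinate vectors, with per-cluster medoids."""
    n = len(snapshots)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} snapshots")
    m, feats = _distance_and_features(snapshots, loop_indices)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(feats)
    medoids = []
    for c in range(k):
        members = np.where(labels == c)[0]
        sub = m[np.ix_(members, members)]
        medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
    gmed = int(np.argmin(m.sum(axis=1)))
    return ClusterResult(labels, medoids, gmed, m, float(km.inertia_))


def _collate(trajectories: list[Trajectory]) -> list[LatticeConformation]:
    snaps = [s.conf for traj in trajectories for s in traj.snapshots]
    if not snaps:
        raise ValueError("no snapshots in trajectories")
    return snaps


def select_top_model(trajectories: list[Trajectory], loop_indices=None
                     ) -> LatticeConformation:
    """Blind top model: the global medoid of the collated snapshots.

    Never consults native coordinates.  ``loop_indices`` selects the
    loop-region metric (default full-chain Kabsch when None).
    """
    confs = _collate(trajectories)
    coords = [c.ca_xyz() for c in confs]
    return confs[global_medoid(coords, loop_indices)]


def select_best_model(trajectories: list[Trajectory], case
                      ) -> tuple[LatticeConformation, float]:
    """Benchmark oracle: the snapshot closest (loop cRMSD) to the native loop."""
    confs = _collate(trajectories)
    native_full = _native_full_coords(case)
    loop = np.asarray(case.loop_indices, int)
    best_i, best_v = 0, np.inf
    for i, c in enumerate(confs):
        v = loop_crmsd_coords(c.ca_xyz(), native_full, loop)
        if v < best_v:
            best_i, best_v = i, v
    return confs[best_i], float(best_v)


def _native_full_coords(case) -> np.ndarray:
    coords = np.empty((len(case.scaffold), 3))
    it = iter(case.native_loop)
    loop = set(case.loop_indices)
    for i, r in enumerate(case.scaffold.residues):
        coords[i] = next(it)[1] if i in loop else r.ca
    return coords
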