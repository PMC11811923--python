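"""Pairwise-RMSD conformational clustering of trajectory frames.

The classic greedy largest-neighborhood scheme: repeatedly take the frame
with the most neighbors within the RMSD cutoff, found a cluster from it and
its neighbors, remove them, and continue.  Cluster prevalences (percent of
all frames) and the founding (centroid) frame of each cluster are reported;
ties break to the lowest frame index, so the partition is deterministic.

The O(n²) matrix limits desk-scale runs: above ``cap`` frames a uniform
subsampling stride must be supplied, and the stride/cap used are recorded
on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, _batch_fit_rmsd
from .structio import Selection, Trajectory, select_atoms

__all__ = ["ClusterResult", "pairwise_rmsd_matrix", "greedy_neighbor_cluster"]


@dataclass(frozen=True)
class ClusterResult:
    assignment: np.ndarray        # frame -> cluster id (0 = largest)
    prevalence: np.ndarray        # percent of frames per cluster
    representative: np.ndarray    # founding frame index per cluster
    cutoff: float
    selection: str = ""
    frame_indices: np.ndarray | None = None   # original indices if strided

    @property
    def n_clusters(self) -> int:
        return len(self.prevalence)

    def __post_init__(self) -> None:
        if len(self.prevalence) and abs(self.prevalence.sum() - 100.0) > 1e-6:
            raise ValueError("prevalences must sum to 100")


def pairwise_rmsd_matrix(
    traj: Trajectory,
    sel: Selection | None = None,
    cap: int = 5000,
    stride: int | None = None,
    _chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix of best-fit RMSDs between all frame pairs.

    Returns ``(matrix, frame_indices)`` where ``frame_indices`` maps matrix
    rows back to trajectory frames (identity unless a stride was applied).
    Raises when more than ``cap`` frames would be used without a stride.
    """
    idx = select_atoms(traj.topology, sel) if sel is not None else list(range(traj.n_atoms))
    if len(idx) < 3:
        raise GeometryError("selection must contain >= 3 atoms")
    frame_idx = np.arange(traj.n_frames)
    if stride is not None and stride > 1:
        frame_idx = frame_idx[::stride]
    if len(frame_idx) > cap:
        raise ValueError(
            f"{len(frame_idx)} frames exceed the cap of {cap}; supply a subsampling stride"
        )
    X = traj.frames[np.ix_(frame_idx, idx)]
    n = len(frame_idx)
    M = np.zeros((n, n))
    for start in range(0, n, _chunk):
        stop = min(start + _chunk, n)
        for j in range(start, stop):        # fill rows j against frames > j
            if j + 1 < n:
                M[j, j + 1:] = _batch_fit_rmsd(X[j + 1:], X[j])
    M = M + M.T
    return M, frame_idx


def greedy_neighbor_cluster(matrix: np.ndarray, cutoff: float = 1.5, selection: str = "",
                            frame_indices: np.ndarray | None = None) -> ClusterResult:
    """Greedy largest-neighborhood clustering of a pairwise RMSD matrix.

    Each round, the unassigned frame with the most unassigned neighbors
    within ``cutoff`` (ties → lowest index) founds a cluster containing
    those neighbors.  Clusters are numbered by decreasing size.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n):
        raise ValueError("matrix must be square")
    adj = M <= cutoff
    np.fill_diagonal(adj, True)
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    reps: list[int] = []
    sizes: list[int] = []
    cid = 0
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))     # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & remaining)
        assignment[members] = cid
        reps.append(center)
        sizes.append(len(members))
        remaining[members] = False
        cid += 1
    order = np.argsort(np.array(sizes) * -1, kind="stable")   # by size desc, stable
    remap = np.empty(cid, dtype=int)
    remap[order] = np.arange(cid)
    assignment = remap[assignment]
    sizes_sorted = np.array(sizes)[order]
    reps_sorted = np.array(reps)[order]
    prevalence = 100.0 * sizes_sorted / n
    return ClusterResult(
        assignment=assignment,
        prevalence=prevalence,
        representative=reps_sorted,
        cutoff=cutoff,
        selection=selection,
        frame_indices=frame_indices,
    )
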