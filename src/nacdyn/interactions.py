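"""Hydrogen-bond series, conformer-state classification and contact spheres.

Covers the interaction analyses around the catalytic triad of an evolved
aniline-enzyme: donor–acceptor distance series and their occupancy-based
persistent/transient classification; forward/backward states of the mobile
Arg92 side chain in each monomer (and the derived cis-forward / trans /
cis-backward dimer states); cation-π stacking geometry between the aniline
ring and the guanidinium group; and radius-based residue-sphere selection
used to carve out quantum-cluster models around the catalytic nitrogen.

The H-bond criterion is a plain donor-heavy-atom↔acceptor distance cutoff
(default 3.5 Å, no angle term); persistent/transient are occupancy classes
(≥ 0.5 persistent, (0.05, 0.5) transient, ≤ 0.05 absent).  All thresholds
are parameters and are echoed in every summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nac_stats import AtomID, _resolve
from .structio import Structure, Trajectory

__all__ = [
    "DistanceSeries",
    "HbondSummary",
    "ConformerStateSeries",
    "CationPiResult",
    "distance_series",
    "hbond_occupancy",
    "conformer_states",
    "cation_pi_geometry",
    "residues_within",
]


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame distance between one atom pair, with the frame interval."""

    pair: tuple[AtomID, AtomID]
    values: np.ndarray  # Å, length n_frames
    dt: float           # ps

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.values)


def distance_series(traj: Trajectory, a: AtomID, b: AtomID) -> DistanceSeries:
    """Per-frame Euclidean distance between two atoms of the topology."""
    ia = _resolve(traj.topology, a)
    ib = _resolve(traj.topology, b)
    vals = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
    return DistanceSeries(pair=(a, b), values=vals, dt=traj.dt)


@dataclass(frozen=True)
class HbondSummary:
    occupancy: float
    classification: str          # persistent | transient | absent
    longest_bound_ps: float
    cutoff: float
    persistent_threshold: float
    transient_threshold: float


def hbond_occupancy(
    s: DistanceSeries,
    cutoff: float = 3.5,
    persistent_threshold: float = 0.5,
    transient_threshold: float = 0.05,
) -> HbondSummary:
    """Occupancy of a distance-defined H-bond and its persistence class.

    Occupancy is the fraction of frames with distance ≤ cutoff; the class is
    persistent (≥ persistent_threshold), transient (in
    (transient_threshold, persistent_threshold)) or absent.  Also reports
    the longest unbroken bound stretch in ps.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    bound = s.values <= cutoff
    occ = float(bound.mean()) if len(bound) else 0.0
    if occ >= persistent_threshold:
        klass = "persistent"
    elif occ > transient_threshold:
        klass = "transient"
    else:
        klass = "absent"
    longest = _longest_run(bound) * s.dt
    return HbondSummary(
        occupancy=occ, classification=klass, longest_bound_ps=float(longest),
        cutoff=cutoff, persistent_threshold=persistent_threshold,
        transient_threshold=transient_threshold,
    )


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return int(np.max(edges[1::2] - edges[0::2]))


@dataclass(frozen=True)
class ConformerStateSeries:
    """Per-monomer forward/backward state series and the derived dimer state.

    forward = the guanidinium faces its monomer's catalytic residue
    (distance ≤ threshold); dimer states: both forward → cis-forward, both
    backward → cis-backward, otherwise trans.
    """

    monomer_forward: tuple[np.ndarray, np.ndarray]   # bool per frame
    dimer_state: np.ndarray                          # str per frame
    threshold: float
    dt: float

    @property
    def monomer_prevalence(self) -> tuple[dict, dict]:
        out = []
        for fw in self.monomer_forward:
            n = len(fw)
            f = float(fw.mean()) if n else 0.0
            out.append({"forward": f, "backward": 1.0 - f})
        return tuple(out)

    @property
    def dimer_prevalence(self) -> dict:
        n = len(self.dimer_state)
        return {
            state: float((self.dimer_state == state).sum()) / n if n else 0.0
            for state in ("cis-forward", "trans", "cis-backward")
        }


def conformer_states(
    traj: Trajectory,
    pAF_N: tuple[AtomID, AtomID],
    R92_CZ: tuple[AtomID, AtomID],
    threshold: float = 6.0,
) -> ConformerStateSeries:
    """Classify the mobile side chain of each monomer as forward/backward.

    ``pAF_N`` and ``R92_CZ`` give, per monomer, the catalytic side-chain
    nitrogen and the guanidinium central carbon; forward means their
    distance is at or below ``threshold``.
    """
    fw = []
    for n_id, cz_id in zip(pAF_N, R92_CZ):
        d = distance_series(traj, n_id, cz_id).values
        fw.append(d <= threshold)
    a, b = fw
    dimer = np.where(a & b, "cis-forward", np.where(~a & ~b, "cis-backward", "trans"))
    return ConformerStateSeries(
        monomer_forward=(a, b), dimer_state=dimer, threshold=threshold, dt=traj.dt
    )


@dataclass(frozen=True)
class CationPiResult:
    centroid_distance: float     # ring centroid ↔ CZ, Å
    offset_angle: float          # ring normal vs centroid→CZ, degrees in [0, 90]
    stacked: bool
    nonplanar_warning: bool


def cation_pi_geometry(
    ring_atoms: np.ndarray,
    cz: np.ndarray,
    guanidinium_n: np.ndarray | None = None,
    max_distance: float = 6.0,
    max_offset: float = 30.0,
    planarity_tol: float = 0.1,
) -> CationPiResult:
    """Cation-π stacking geometry between an aromatic ring and a guanidinium.

    Stacked iff the centroid↔CZ distance is ≤ ``max_distance`` and the angle
    between the ring normal and the centroid→CZ vector is ≤ ``max_offset``.
    An axial cation (on the ring normal) has offset 0°; an in-plane cation
    90°, which is the geometry of an in-plane H-bond approach — hence
    stacking and H-bonding to the same face are mutually exclusive.
    """
    ring = np.asarray(ring_atoms, dtype=float)
    if ring.shape != (6, 3):
        raise ValueError("expected 6 ring atom coordinates")
    cz = np.asarray(cz, dtype=float)
    centroid = ring.mean(axis=0)
    # plane fit: normal = least singular vector of the centered ring
    _, svals, Vt = np.linalg.svd(ring - centroid)
    normal = Vt[2]
    rms_out = float(np.sqrt(np.mean(((ring - centroid) @ normal) ** 2)))
    v = cz - centroid
    dist = float(np.linalg.norm(v))
    if dist < 1e-9:
        raise ValueError("cation coincides with the ring centroid")
    cosang = abs(float(normal @ (v / dist)))   # fold to [0, 90]
    offset = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return CationPiResult(
        centroid_distance=dist,
        offset_angle=offset,
        stacked=bool(dist <= max_distance and offset <= max_offset),
        nonplanar_warning=bool(rms_out > planarity_tol),
    )


def residues_within(s: Structure, center: AtomID, radius: float) -> set[tuple[str, int, str]]:
    """Residues with at least one atom within ``radius`` Å of the center atom.

    The center's own residue is always included (its distance to itself is
    zero).  This is the selection rule used to carve a first-shell cluster
    around the catalytic side-chain nitrogen.
    """
    ic = _resolve(s.topology if isinstance(s, Trajectory) else s, center)
    struct = s.topology if isinstance(s, Trajectory) else s
    c = struct.atoms[ic].coord
    out: set[tuple[str, int, str]] = set()
    for a in struct.atoms:
        if np.linalg.norm(a.coord - c) <= radius:
            out.add(a.residue_id)
    return out
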