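"""Seeded synthetic-data generators with known ground truth.

Every analysis in this package is exercised against data whose true answer
is known by construction: ideal helices at controlled inter-axis angles,
hollow shells enclosing cavities of analytic volume, reactive-fragment
trajectories whose dihedral/distance values follow prescribed mixtures,
two-state Markov donor–acceptor distance series with prescribed occupancy,
and two-state conformational trajectories with prescribed prevalences.

All generators are pure functions of their configuration including the
seed (bit-reproducible) and return their ground truth alongside the data,
so parameter recovery can be asserted quantitatively downstream.

Default sizes mirror the production setting they emulate: six replicates
of 500 ns sampled every 10 ps (50,000 frames each, 3 × 10⁵ total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import HelixSegment, wrap_angle
from .interactions import DistanceSeries
from .nac_stats import NACAtomSpec, NACWindows, _label_arrays
from .structio import AtomRecord, Structure, Trajectory

__all__ = [
    "MixtureComponent",
    "NacMixtureConfig",
    "HbondSeriesConfig",
    "NacSample",
    "HbondSample",
    "TwoStateSample",
    "make_ideal_helix",
    "make_helix_pair",
    "make_hollow_shell",
    "make_nac_trajectory",
    "make_hbond_series",
    "make_two_state_trajectory",
    "default_nac_spec",
]


# ---------------------------------------------------------------------------
# helices


def make_ideal_helix(
    n_res: int = 15,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    chain: str = "A",
    start_resseq: int = 1,
) -> HelixSegment:
    """Cα trace of an ideal α-helix along +z.

    Defaults (rise 1.5 Å, twist 100°/residue, radius 2.3 Å) give the
    canonical ~3.8 Å consecutive Cα–Cα distance.
    """
    if n_res < 4:
        raise ValueError("a helix segment needs at least 4 residues")
    k = np.arange(n_res)
    theta = np.radians(twist) * k
    coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * k])
    return HelixSegment(
        chain=chain, resseq_start=start_resseq, resseq_end=start_resseq + n_res - 1,
        ca_coords=coords,
    )


def _ca_atoms(coords: np.ndarray, chain: str, start_resseq: int, serial0: int) -> list[AtomRecord]:
    return [
        AtomRecord(
            serial=serial0 + i, name="CA", altloc="", resname="ALA", chain=chain,
            resseq=start_resseq + i, icode="", element="C", coord=c,
        )
        for i, c in enumerate(coords)
    ]


def make_helix_pair(angle: float, separation: float = 12.0, n_res: int = 15) -> Structure:
    """Two ideal helices whose oriented (N→C) axes subtend ``angle`` degrees.

    Chain A runs along +z at the origin; chain B is chain A rotated by the
    requested angle about x and displaced by ``separation`` along x.
    """
    if not 0.0 <= angle <= 180.0:
        raise ValueError("angle must be in [0, 180] degrees")
    h = make_ideal_helix(n_res=n_res)
    a = np.radians(angle)
    rot = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    coords_b = h.ca_coords @ rot.T + np.array([separation, 0.0, 0.0])
    atoms = _ca_atoms(h.ca_coords, "A", 1, 1) + _ca_atoms(coords_b, "B", 1, n_res + 1)
    return Structure(atoms=atoms, metadata={"requested_angle": angle})


# ---------------------------------------------------------------------------
# hollow shell


def make_hollow_shell(
    cavity_radius: float,
    shell_thickness: float = 2.0,
    atom_spacing: float = 0.9,
    probe: float = 1.4,
    center: np.ndarray | None = None,
) -> Structure:
    """Spherical shell of pseudo-atoms enclosing a cavity of known volume.

    Pseudo-atom centers sit at ``cavity_radius + r_vdw(C) + probe`` from the
    center so that, probed with the given small-probe radius, the accessible
    cavity is a sphere of exactly ``cavity_radius`` (volume 4/3·π·r³) up to
    the scalloping between atoms, which is < 0.05 Å for spacing ≤ 1 Å.
    """
    if atom_spacing > 1.0:
        warnings.warn("atom_spacing > 1.0 A may let the probe leak through the shell")
    c0 = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    r_vdw = 1.70  # carbon pseudo-atoms
    r_inner = cavity_radius + r_vdw + probe
    n_layers = max(1, int(np.ceil(shell_thickness / atom_spacing)))
    atoms: list[AtomRecord] = []
    serial = 1
    for layer in range(n_layers):
        R = r_inner + layer * atom_spacing
        n_pts = int(np.ceil(16.0 * R * R / (atom_spacing * atom_spacing)))
        pts = _fibonacci_sphere(n_pts) * R + c0
        for p in pts:
            atoms.append(
                AtomRecord(
                    serial=serial, name="C", altloc="", resname="SPH", chain="S",
                    resseq=serial, icode="", element="C", coord=p, het=True,
                )
            )
            serial += 1
    return Structure(atoms=atoms, metadata={"cavity_radius": cavity_radius, "probe": probe})


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + np.sqrt(5))
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


# ---------------------------------------------------------------------------
# reactive-fragment (NAC) trajectories


@dataclass(frozen=True)
class MixtureComponent:
    """One mixture component in (dihedral, distance) space.

    ``constraint`` pins the component to a region of the NAC windows:
    "pro-S"/"pro-R" components are resampled until they fall inside their
    box, "background" components until they fall outside both, so the
    component label is the exact classification ground truth.
    """

    weight: float
    dihedral_mean: float     # degrees
    dihedral_sigma: float    # degrees (wrapped-normal; adequate for sigma <= 60)
    distance_mean: float     # Å
    distance_sigma: float    # Å (truncated at 0)
    constraint: str = "background"     # "pro-S" | "pro-R" | "background" | "free"


@dataclass(frozen=True)
class NacMixtureConfig:
    """Mixture + replication settings for reactive-geometry trajectories."""

    n_frames: int = 50_000           # per replicate (500 ns at 10 ps)
    n_replicates: int = 6
    components: tuple = (
        MixtureComponent(0.95, 0.0, 103.0, 9.0, 3.0, "background"),
        MixtureComponent(0.05, 90.0, 12.0, 3.4, 0.3, "pro-S"),
    )
    windows: NACWindows = field(default_factory=NACWindows)
    dt: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array([c.weight for c in self.components])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be non-negative and sum to 1")
        for c in self.components:
            if c.dihedral_sigma <= 0 or c.distance_sigma <= 0:
                raise ValueError("component sigmas must be positive")


@dataclass(frozen=True)
class NacSample:
    trajectories: list
    truth: pd.DataFrame          # replicate, frame, component, dihedral, distance
    spec: NACAtomSpec
    windows: NACWindows
    config: NacMixtureConfig


#: internal geometry of the 6-atom reactive fragment (Å / degrees)
_BOND_P1P2 = 1.40        # iminium C — enal Cα
_BOND_P2P3 = 1.50        # enal Cα — enal Cβ
_ANGLE_123 = 120.0       # p1-p2-p3
_ANGLE_234 = 109.5       # p2-p3-p4 (approach angle of the indole carbon)


def default_nac_spec(chain: str = "L", resseq: int = 1) -> NACAtomSpec:
    """Atom identities matching the topology built by make_nac_trajectory."""
    return NACAtomSpec(
        dihedral_atoms=(
            (chain, resseq, "CM"), (chain, resseq, "CA"),
            (chain, resseq, "CB"), (chain, resseq, "C3"),
        ),
        distance_atoms=((chain, resseq, "CB"), (chain, resseq, "C3")),
    )


def _nac_topology() -> Structure:
    names = ["CM", "CA", "CB", "C3", "D1", "D2"]
    coords = np.zeros((6, 3))
    atoms = [
        AtomRecord(serial=i + 1, name=n, altloc="", resname="NAC", chain="L",
                   resseq=1, icode="", element="C", coord=coords[i])
        for i, n in enumerate(names)
    ]
    return Structure(atoms=atoms)


def _place_fragment(dihedrals: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Coordinates of the 6-atom fragment realizing each (dihedral, distance).

    Atoms p1..p3 are fixed; p4 is placed by an explicit internal-coordinate
    construction (rotation about the p2→p3 axis), so the measured torsion
    and p3–p4 distance equal the sampled values exactly.  Two fixed
    spectator atoms complete the fragment.
    """
    n = len(dihedrals)
    p2 = np.zeros(3)
    p3 = np.array([_BOND_P2P3, 0.0, 0.0])
    a1 = np.radians(_ANGLE_123)
    p1 = p2 + _BOND_P1P2 * np.array([np.cos(a1), np.sin(a1), 0.0])
    bc = (p3 - p2) / np.linalg.norm(p3 - p2)
    nvec = np.cross(p2 - p1, bc)
    nvec = nvec / np.linalg.norm(nvec)
    mvec = np.cross(nvec, bc)
    theta = np.radians(_ANGLE_234)
    phi = np.radians(dihedrals)
    d = distances
    p4 = (
        p3[None, :]
        + (-d * np.cos(theta))[:, None] * bc[None, :]
        + (d * np.sin(theta) * np.cos(phi))[:, None] * mvec[None, :]
        + (d * np.sin(theta) * np.sin(phi))[:, None] * nvec[None, :]
    )
    frames = np.empty((n, 6, 3))
    frames[:, 0] = p1
    frames[:, 1] = p2
    frames[:, 2] = p3
    frames[:, 3] = p4
    frames[:, 4] = np.array([0.0, -2.5, 1.0])
    frames[:, 5] = np.array([3.0, -2.0, -1.5])
    return frames


def _sample_component(rng: np.random.Generator, c: MixtureComponent, n: int,
                      w: NACWindows) -> tuple[np.ndarray, np.ndarray]:
    """Sample n (dihedral, distance) pairs from one component, honoring its
    window constraint by resampling the rejected draws."""
    dih = np.empty(n)
    dist = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        m = len(todo)
        d = wrap_angle(rng.normal(c.dihedral_mean, c.dihedral_sigma, size=m))
        r = rng.normal(c.distance_mean, c.distance_sigma, size=m)
        r = np.where(r <= 0.05, np.abs(r) + 0.05, r)
        labels = _label_arrays(d, r, w)
        if c.constraint == "free":
            ok = np.ones(m, dtype=bool)
        elif c.constraint == "background":
            ok = labels == "none"
        else:
            ok = labels == c.constraint
        dih[todo[ok]] = d[ok]
        dist[todo[ok]] = r[ok]
        todo = todo[~ok]
        if len(todo) == 0:
            return dih, dist
    raise ValueError(
        f"infeasible geometry request: component {c.constraint!r} with mean "
        f"({c.dihedral_mean} deg, {c.distance_mean} A) almost never satisfies its window"
    )


def make_nac_trajectory(cfg: NacMixtureConfig | None = None) -> NacSample:
    """Replicated trajectories of a reactive fragment with mixture-drawn
    (dihedral, distance) values and exact component ground truth."""
    cfg = cfg or NacMixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    top = _nac_topology()
    weights = np.array([c.weight for c in cfg.components])
    trajectories = []
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        comp_idx = rng.choice(len(cfg.components), size=cfg.n_frames, p=weights)
        dih = np.empty(cfg.n_frames)
        dist = np.empty(cfg.n_frames)
        for ci, c in enumerate(cfg.components):
            sel = comp_idx == ci
            n_sel = int(sel.sum())
            if n_sel:
                dih[sel], dist[sel] = _sample_component(rng, c, n_sel, cfg.windows)
        frames = _place_fragment(dih, dist)
        trajectories.append(Trajectory(topology=top, frames=frames, dt=cfg.dt))
        rows.append(pd.DataFrame({
            "replicate": rep,
            "frame": np.arange(cfg.n_frames, dtype=int),
            "component": [cfg.components[i].constraint for i in comp_idx],
            "dihedral": dih,
            "distance": dist,
        }))
    truth = pd.concat(rows, ignore_index=True)
    return NacSample(trajectories=trajectories, truth=truth,
                     spec=default_nac_spec(), windows=cfg.windows, config=cfg)


# ---------------------------------------------------------------------------
# H-bond distance series


@dataclass(frozen=True)
class HbondSeriesConfig:
    """Two-state Markov dwell process emulating an H-bond distance trace."""

    n_frames: int = 10_000
    target_occupancy: float = 0.62
    bound_mean: float = 2.9      # Å
    bound_sigma: float = 0.15
    unbound_mean: float = 6.0    # Å
    unbound_sigma: float = 0.8
    mean_dwell: float = 50.0     # frames spent bound per visit, on average
    dt: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must be in [0, 1]")
        if not self.bound_mean < self.unbound_mean:
            raise ValueError("bound_mean must be below unbound_mean")


@dataclass(frozen=True)
class HbondSample:
    series: DistanceSeries
    states: np.ndarray           # bool, True = bound
    realized_occupancy: float
    config: HbondSeriesConfig


def make_hbond_series(cfg: HbondSeriesConfig | None = None) -> HbondSample:
    """Distance series from a bound/unbound Markov chain.

    Dwell times are geometric with mean ``mean_dwell`` in the bound state
    and ``mean_dwell·(1−p)/p`` unbound, giving stationary occupancy p.
    """
    cfg = cfg or HbondSeriesConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    p = cfg.target_occupancy
    if p >= 1.0:
        states = np.ones(n, dtype=bool)
    elif p <= 0.0:
        states = np.zeros(n, dtype=bool)
    else:
        leave_b = min(1.0, 1.0 / cfg.mean_dwell)
        leave_u = min(1.0, 1.0 / (cfg.mean_dwell * (1.0 - p) / p))
        states = np.empty(n, dtype=bool)
        state = bool(rng.random() < p)
        i = 0
        while i < n:
            leave = leave_b if state else leave_u
            run = int(rng.geometric(leave))
            states[i:i + run] = state
            i += run
            state = not state
    d = np.where(
        states,
        rng.normal(cfg.bound_mean, cfg.bound_sigma, size=n),
        rng.normal(cfg.unbound_mean, cfg.unbound_sigma, size=n),
    )
    d = np.abs(d)
    series = DistanceSeries(pair=(("L", 1, "O1"), ("A", 93, "ND1")), values=d, dt=cfg.dt)
    return HbondSample(series=series, states=states,
                       realized_occupancy=float(states.mean()), config=cfg)


# ---------------------------------------------------------------------------
# two-state conformational trajectories


@dataclass(frozen=True)
class TwoStateSample:
    trajectory: Trajectory
    states: np.ndarray           # int per frame
    conformers: list
    prevalences: tuple


def make_two_state_trajectory(
    prevalences=(0.7, 0.3),
    conformers: list | None = None,
    jitter_sigma: float = 0.2,
    n_frames: int = 1000,
    n_atoms: int = 10,
    seed: int = 0,
    dt: float = 10.0,
) -> TwoStateSample:
    """Frames drawn from jittered reference conformers in stated proportions.

    Default conformers are independent random point clouds (std 3 Å), whose
    mutual best-fit RMSD of several Å dwarfs the per-atom jitter, so RMSD
    clustering can recover the prevalences.
    """
    prev = np.asarray(prevalences, dtype=float)
    if np.any(prev < 0) or abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError("prevalences must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    if conformers is None:
        conformers = [rng.normal(scale=3.0, size=(n_atoms, 3)) for _ in prev]
    m = conformers[0].shape[0]
    states = rng.choice(len(prev), size=n_frames, p=prev)
    frames = np.stack([conformers[s] for s in states])
    frames += rng.normal(scale=jitter_sigma, size=frames.shape)
    atoms = _ca_atoms(np.zeros((m, 3)), "A", 1, 1)
    top = Structure(atoms=atoms)
    traj = Trajectory(topology=top, frames=frames, dt=dt)
    return TwoStateSample(trajectory=traj, states=states, conformers=list(conformers),
                          prevalences=tuple(prev))
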