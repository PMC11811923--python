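"""Core geometric measurements on structures and trajectories.

Distances, torsions, least-squares superposition (Kabsch), per-frame RMSD
and per-atom RMSF, principal component analysis of coordinate fluctuations,
and helix-axis / inter-helix-angle measurements used to quantify changes in
quaternary structure (e.g. the α1/α4 packing angle of a homodimeric
transcription-factor scaffold).

Conventions
-----------
* Torsions follow the IUPAC sign convention: looking down the p2→p3 bond,
  a clockwise rotation of the far bond relative to the near bond is
  positive; values lie in (−180°, 180°].
* Helix axes are oriented N→C (sign fixed by the first-to-last Cα vector),
  so inter-helix angles are defined on [0°, 180°] without the usual
  line-direction ambiguity.
* All superpositions are proper rotations (det = +1); reflections are never
  returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Selection, Structure, Trajectory, select_atoms

__all__ = [
    "GeometryError",
    "HelixSegment",
    "SuperpositionResult",
    "HelixAxis",
    "distance",
    "min_pairwise_distance",
    "dihedral",
    "dihedral_batch",
    "kabsch_superpose",
    "superpose_frames",
    "rmsd_series",
    "rmsf",
    "helix_axis",
    "interhelix_angle",
    "pca_modes",
]


class GeometryError(ValueError):
    """Degenerate geometry (coincident points, collinear sets, …)."""


@dataclass(frozen=True)
class HelixSegment:
    """A contiguous stretch of helix represented by its Cα trace.

    Invariants are enforced at construction: at least four Cα positions and
    consecutive Cα–Cα distances within [2.5, 4.5] Å (a loose band around the
    ideal ~3.8 Å virtual bond).
    """

    chain: str
    resseq_start: int
    resseq_end: int
    ca_coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        object.__setattr__(self, "ca_coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
            raise ValueError("helix segment needs >= 4 Calpha positions")
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if np.any(steps < 2.5) or np.any(steps > 4.5):
            raise ValueError(
                "consecutive Calpha-Calpha distances outside [2.5, 4.5] A: "
                f"range [{steps.min():.2f}, {steps.max():.2f}]"
            )


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation mapping X onto Y, with the RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class HelixAxis:
    """Oriented (N→C) unit axis and centroid of a helix; ``ill_defined`` is
    set when the Cα cloud is too isotropic for a meaningful axis."""

    axis: np.ndarray
    centroid: np.ndarray
    ill_defined: bool = False


def distance(a, b) -> float:
    """Euclidean distance |a − b| in Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise GeometryError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


def min_pairwise_distance(A: np.ndarray, B: np.ndarray) -> tuple[float, tuple[int, int]]:
    """Global minimum distance over A×B and the achieving index pair.

    Ties resolve to the lexicographically lowest (i, j).  Used e.g. for the
    closest-atom separation of the two Trp96 side chains across the dimer
    interface.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("min_pairwise_distance: empty coordinate set")
    d2 = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=-1)
    flat = int(np.argmin(d2))  # argmin is row-major -> lowest (i, j) on ties
    i, j = divmod(flat, d2.shape[1])
    return float(np.sqrt(d2[i, j])), (int(i), int(j))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1–p2–p3–p4 in degrees, IUPAC convention, in (−180, 180]."""
    out = dihedral_batch(
        np.asarray(p1, float)[None], np.asarray(p2, float)[None],
        np.asarray(p3, float)[None], np.asarray(p4, float)[None],
    )
    return float(out[0])


def dihedral_batch(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Vectorized torsion over (n, 3) point arrays.

    Raises :class:`GeometryError` when consecutive points coincide or three
    consecutive points are collinear (the torsion is then undefined).
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.any(np.linalg.norm(b1, axis=-1) < 1e-10) or \
       np.any(np.linalg.norm(b2, axis=-1) < 1e-10) or \
       np.any(np.linalg.norm(b3, axis=-1) < 1e-10):
        raise GeometryError("undefined dihedral: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-10) or np.any(np.linalg.norm(n2, axis=-1) < 1e-10):
        raise GeometryError("undefined dihedral: collinear consecutive points")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2u, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 to +180 so the range is the half-open interval (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang


def wrap_angle(a) -> np.ndarray:
    """Wrap angles in degrees to (−180, 180]."""
    a = np.asarray(a, dtype=float)
    w = (a + 180.0) % 360.0 - 180.0
    return np.where(w == -180.0, 180.0, w)


def kabsch_superpose(X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares optimal superposition of X onto Y (Kabsch, via SVD).

    Returns the proper rotation R and translation t minimising
    Σ wᵢ |R xᵢ + t − yᵢ|², together with the minimised (weighted) RMSD.
    Requires ≥3 non-collinear points.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both be (n, 3) with equal n")
    n = X.shape[0]
    if n < 3:
        raise GeometryError("superposition needs >= 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    xc = w @ X
    yc = w @ Y
    Xc = X - xc
    Yc = Y - yc
    H = (Xc * w[:, None]).T @ Yc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:  # rank < 2: points effectively collinear
        raise GeometryError("degenerate point set: rotation not uniquely defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    # residual-based rmsd: immune to the cancellation the trace formula
    # suffers when the fit is near-exact
    resid = Xc @ R.T - Yc
    rmsd = float(np.sqrt(np.sum(w * np.sum(resid**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _batch_fit_rmsd(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Best-fit RMSD of each frame (n_frames, n, 3) against ref (n, 3)."""
    n = ref.shape[0]
    Fc = frames - frames.mean(axis=1, keepdims=True)
    Rc = ref - ref.mean(axis=0)
    H = np.einsum("fni,nj->fij", Fc, Rc) / n
    S = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    sgn = np.where(det < 0, -1.0, 1.0)
    gx = np.mean(np.sum(Fc**2, axis=2), axis=1)
    gy = np.mean(np.sum(Rc**2, axis=1))
    msd = gx + gy - 2.0 * (S[:, 0] + S[:, 1] + sgn * S[:, 2])
    return np.sqrt(np.clip(msd, 0.0, None))


def rmsd_series(traj: Trajectory, ref: Structure | np.ndarray, sel: Selection | None = None) -> np.ndarray:
    """Per-frame best-fit RMSD (Å) of the selected atoms against a reference.

    Each frame is independently superposed onto the reference selection
    before the deviation is measured, so rigid-body motion does not
    contribute.
    """
    idx = _selection_indices(traj.topology, sel)
    if len(idx) < 3:
        raise GeometryError("selection must contain >= 3 atoms")
    ref_coords = ref.coords if isinstance(ref, Structure) else np.asarray(ref, dtype=float)
    return _batch_fit_rmsd(traj.frames[:, idx, :], ref_coords[idx])


def superpose_frames(traj: Trajectory, sel: Selection | None = None, ref: np.ndarray | None = None) -> Trajectory:
    """Return a copy of the trajectory with every frame superposed on the
    reference (default: frame 0) over the selection."""
    idx = _selection_indices(traj.topology, sel)
    if len(idx) < 3:
        raise GeometryError("selection must contain >= 3 atoms")
    ref_coords = traj.frames[0] if ref is None else np.asarray(ref, dtype=float)
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        fit = kabsch_superpose(traj.frames[f, idx], ref_coords[idx])
        out[f] = fit.apply(traj.frames[f])
    return Trajectory(topology=traj.topology, frames=out, dt=traj.dt)


def rmsf(traj: Trajectory, sel: Selection | None = None, presuperposed: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean position (Å).

    Frames are assumed already superposed on the selection; pass
    ``presuperposed=False`` to run a two-pass mean-structure superposition
    first (superpose on frame 0, then on the resulting mean).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _selection_indices(traj.topology, sel)
    if not presuperposed:
        t1 = superpose_frames(traj, sel)
        mean = t1.frames.mean(axis=0)
        traj = superpose_frames(t1, sel, ref=mean)
    coords = traj.frames[:, idx, :]
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def _selection_indices(top: Structure, sel: Selection | None) -> list[int]:
    if sel is None:
        return list(range(len(top)))
    return select_atoms(top, sel)


def helix_axis(h: HelixSegment | np.ndarray) -> HelixAxis:
    """Helix axis as the first principal component of the Cα coordinates.

    The sign is chosen so the axis points N→C (positive projection of the
    first-to-last Cα vector).  When the Cα cloud is nearly isotropic
    (λ₁ < 2 λ₂), the axis direction is unstable and the result is flagged
    ``ill_defined`` rather than raising.
    """
    coords = h.ca_coords if isinstance(h, HelixSegment) else np.asarray(h, dtype=float)
    # a one-turn moving average removes most of the helical wobble that
    # otherwise tilts the principal axis when the trace spans a non-integer
    # number of turns; short segments fall back to the raw trace
    smooth = coords
    if len(coords) >= 8:
        kernel = 4  # ~one turn at 100 deg/residue
        smooth = np.stack([coords[i:len(coords) - kernel + 1 + i] for i in range(kernel)]).mean(axis=0)
    centroid = smooth.mean(axis=0)
    X = smooth - centroid
    cov = X.T @ X / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    ill = bool(evals[-1] < 2.0 * evals[-2])
    span = coords[-1] - coords[0]
    if float(axis @ span) < 0:
        axis = -axis
    return HelixAxis(axis=axis / np.linalg.norm(axis), centroid=centroid, ill_defined=ill)


def interhelix_angle(a1: np.ndarray | HelixAxis, a2: np.ndarray | HelixAxis) -> float:
    """Angle in degrees between two oriented helix axes, in [0, 180]."""
    v1 = a1.axis if isinstance(a1, HelixAxis) else np.asarray(a1, dtype=float)
    v2 = a2.axis if isinstance(a2, HelixAxis) else np.asarray(a2, dtype=float)
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 / np.linalg.norm(v2)
    return float(np.degrees(np.arccos(np.clip(v1 @ v2, -1.0, 1.0))))


@dataclass(frozen=True)
class PCAModes:
    eigenvalues: np.ndarray      # Å², non-increasing
    modes: np.ndarray            # (k, 3*n_sel), orthonormal rows
    projections: np.ndarray      # (n_frames, k), centered


def pca_modes(traj: Trajectory, sel: Selection | None = None, k: int = 2) -> PCAModes:
    """Principal components of coordinate fluctuations over the selection.

    Frames are assumed superposed.  Eigenvalues are the variances (Å²) along
    each mode, non-increasing; mode vectors are orthonormal; per-frame
    projections are mean-centered.
    """
    idx = _selection_indices(traj.topology, sel)
    X = traj.frames[:, idx, :].reshape(traj.n_frames, -1)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds 3*n_sel={X.shape[1]}")
    Xc = X - X.mean(axis=0)
    # SVD of the centered data matrix: eigenvalues of the covariance are s^2/n
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evals = (s**2) / X.shape[0]
    modes = Vt[:k]
    projections = Xc @ modes.T
    return PCAModes(eigenvalues=evals[:k], modes=modes, projections=projections)
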