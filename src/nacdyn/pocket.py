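"""Grid-based cavity volume estimation with a two-probe flood fill.

Voxels on a cubic grid count toward a cavity when they are (a) outside every
atom van-der-Waals sphere inflated by the small (solvent) probe, (b)
flood-fill connected to a user-supplied seed point, and (c) not reachable
from the bulk solvent, where "bulk" is the region a large probe can reach
from outside the structure.  The two-probe construction closes pocket mouths
that a water-sized probe alone would leak through, the standard trick in
grid cavity detectors.

For the dimer-interface pocket of an LmrR-type scaffold the natural seed is
the midpoint of the two Trp96 CZ2 atoms; :func:`w96_seed_point` computes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .structio import Selection, Structure, select_atoms

__all__ = ["GridSpec", "CavityResult", "SeedError", "cavity_volume", "w96_seed_point", "VDW_RADII"]

#: Fixed van-der-Waals radii (Å); unknown elements fall back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "D": 1.20, "P": 1.80}
_DEFAULT_RADIUS = 1.70


class SeedError(ValueError):
    """Seed point unusable: inside an atom or in probe-excluded space."""


@dataclass(frozen=True)
class GridSpec:
    """Grid and probe parameters.

    spacing ≤ small_probe keeps the flood fill leak-tight; the large probe
    must exceed the small one so the bulk region is a strict subset of
    solvent-accessible space.
    """

    spacing: float = 0.5
    small_probe: float = 1.4
    large_probe: float = 3.4
    seed_point: np.ndarray | None = None
    padding: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.spacing <= self.small_probe:
            raise ValueError("require 0 < spacing <= small_probe")
        if not self.small_probe < self.large_probe:
            raise ValueError("require small_probe < large_probe")
        if self.seed_point is not None:
            object.__setattr__(self, "seed_point", np.asarray(self.seed_point, dtype=float))


@dataclass(frozen=True)
class CavityResult:
    volume: float                 # Å³
    n_voxels: int
    voxel_coords: np.ndarray      # (n_voxels, 3) Å
    open_cavity: bool             # True when the cavity touches bulk solvent
    spacing: float


def _occupancy_mask(shape, origin, spacing, coords, radii) -> np.ndarray:
    """Boolean grid: voxel center within ``radii[i]`` of atom i for some i."""
    mask = np.zeros(shape, dtype=bool)
    for c, r in zip(coords, radii):
        lo = np.maximum(np.floor((c - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r - origin) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ax = [origin[d] + spacing * np.arange(lo[d], hi[d]) - c[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= d2 <= r * r
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return mask


def _boundary_mask(shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


def cavity_volume(s: Structure, sel: Selection | None = None, g: GridSpec | None = None) -> CavityResult:
    """Estimate the volume of the cavity containing ``g.seed_point``.

    Returns the voxel count times the voxel volume, the voxel coordinates,
    and an ``open_cavity`` flag set when the seed's probe-excluded region
    touches bulk solvent (the volume is still reported in that case).

    Raises :class:`SeedError` when the seed lies inside an atom's
    van-der-Waals sphere, or in space the small probe cannot occupy.
    """
    g = g or GridSpec()
    if g.seed_point is None:
        raise ValueError("GridSpec.seed_point is required")
    idx = select_atoms(s, sel) if sel is not None else range(len(s))
    atoms = [s.atoms[i] for i in idx]
    if not atoms:
        raise ValueError("empty atom selection")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS) for a in atoms])

    d_seed = np.linalg.norm(coords - g.seed_point, axis=1)
    if np.any(d_seed < radii):
        raise SeedError("seed point lies inside an atom van-der-Waals sphere")

    origin = coords.min(axis=0) - radii.max() - g.padding
    top = coords.max(axis=0) + radii.max() + g.padding
    shape = tuple(np.ceil((top - origin) / g.spacing).astype(int) + 1)

    blocked_small = _occupancy_mask(shape, origin, g.spacing, coords, radii + g.small_probe)
    free_small = ~blocked_small

    seed_idx = tuple(np.round((g.seed_point - origin) / g.spacing).astype(int))
    if not all(0 <= seed_idx[d] < shape[d] for d in range(3)):
        raise SeedError("seed point outside the analysis grid")
    if not free_small[seed_idx]:
        raise SeedError("seed point lies in probe-excluded space (no cavity at seed)")

    # bulk: region the large probe reaches from outside, then geodesically
    # grown back within small-probe-free space by the probe radius difference
    blocked_large = _occupancy_mask(shape, origin, g.spacing, coords, radii + g.large_probe)
    free_large = ~blocked_large
    labels, _ = ndimage.label(free_large)
    edge_labels = np.unique(labels[_boundary_mask(shape) & free_large])
    bulk_core = np.isin(labels, edge_labels[edge_labels > 0])
    grow = int(np.ceil((g.large_probe - g.small_probe) / g.spacing))
    bulk = ndimage.binary_dilation(bulk_core, iterations=grow, mask=free_small) if grow else bulk_core

    interior = free_small & ~bulk
    labels_i, _ = ndimage.label(interior)
    seed_label = labels_i[seed_idx]
    if seed_label == 0:
        # seed voxel itself was claimed by bulk: cavity is wide open
        cavity = np.zeros(shape, dtype=bool)
        cavity[seed_idx] = True
        open_cavity = True
    else:
        cavity = labels_i == seed_label
        open_cavity = bool(np.any(ndimage.binary_dilation(cavity) & bulk))

    vox = np.argwhere(cavity)
    vol = float(vox.shape[0]) * g.spacing**3
    return CavityResult(
        volume=vol,
        n_voxels=int(vox.shape[0]),
        voxel_coords=origin + vox * g.spacing,
        open_cavity=open_cavity,
        spacing=g.spacing,
    )


def w96_seed_point(s: Structure, resseq: int = 96, atom_name: str = "CZ2") -> np.ndarray:
    """Midpoint of the two Trp-96 CZ2 atoms across the dimer — the default
    seed for the interface pocket of LmrR-family structures."""
    pts = [a.coord for a in s.atoms if a.resseq == resseq and a.name == atom_name]
    if len(pts) < 2:
        raise ValueError(f"need the {atom_name} atom of residue {resseq} in both chains")
    return (pts[0] + pts[1]) / 2.0
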