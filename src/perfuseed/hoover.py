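"""Hoover (Robin-Hood) homogeneity index and its two reactor applications.

The index of a nonnegative quantity v over bins with reference weights w is

    H = 1/2 * sum_i | v_i w_i / sum(v w) - w_i / sum(w) |,

i.e. half the L1 distance between the quantity's shares and the reference
shares: 0 means perfectly even, values toward 1 mean the quantity is
concentrated in few bins (the attainable maximum on n equal-weight bins is
1 - 1/n).

Two distinct applications share the name in perfusion work, and they are
deliberately kept apart here:

* **flow homogeneity** - the index of the velocity-magnitude distribution
  *within* each cross-sectional plane, averaged over a stack of planes
  (reported as the mean coefficient of a reactor design);
* **axial distribution homogeneity** - a single index of how a deposited
  quantity (cells, activity) is shared *across* the planes, weighted by
  each plane's fluid volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import WALL, SimulationDomain

DEFAULT_PLANE_COUNT = 24
DEFAULT_PLANE_SPACING_MM = 1.0


def hoover_index(values, weights=None) -> float:
    """Hoover/Robin-Hood inequality index of ``values`` over the bins.

    ``weights`` are strictly positive reference masses (bin volumes,
    populations); equal weights by default.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("hoover_index needs at least one bin")
    if (v < 0).any():
        raise ValueError("hoover_index requires nonnegative values")
    total = v.sum()
    if total == 0:
        raise ValueError("hoover_index undefined for all-zero values")
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != v.shape:
            raise ValueError("weights must match values in length")
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
    q = v * w
    return float(0.5 * np.abs(q / q.sum() - w / w.sum()).sum())


@dataclass(frozen=True)
class PlaneSet:
    """Uniformly spaced cross-sectional evaluation planes along an axis."""

    axis: int
    positions_mm: tuple
    spacing_mm: float

    def __post_init__(self):
        pos = np.asarray(self.positions_mm)
        if pos.size == 0:
            raise ValueError("PlaneSet needs at least one plane")
        d = np.diff(pos)
        if pos.size > 1 and (not (d > 0).all()
                             or np.abs(d - self.spacing_mm).max() > 1e-6):
            raise ValueError("plane positions must increase uniformly")

    @property
    def count(self) -> int:
        return len(self.positions_mm)

    def layer_indices(self, voxel_mm: float) -> np.ndarray:
        """Voxel-layer index of each plane (positions snap to voxel centers)."""
        return np.asarray(
            [int(np.floor(p / voxel_mm)) for p in self.positions_mm], dtype=int
        )


def default_planes(domain: SimulationDomain, count: int = DEFAULT_PLANE_COUNT,
                   spacing_mm: float = DEFAULT_PLANE_SPACING_MM) -> PlaneSet:
    """Evaluation planes centered on the scaffold along the flow axis.

    For the default 24 planes at 1 mm on a 20 mm block the stack spans the
    scaffold plus ~1.5 mm into each connector.  Positions snap to voxel
    centers of the domain grid.
    """
    h = domain.voxel_mm
    z0, z1 = domain.scaffold_zrange
    nz = domain.shape[domain.flow_axis]
    # snap the stack center to a voxel-center coordinate, then lay the
    # planes out at exact spacing (spacing must be a voxel multiple)
    if abs(spacing_mm / h - round(spacing_mm / h)) > 1e-9:
        raise ValueError(
            f"plane spacing {spacing_mm} mm must be a multiple of the "
            f"voxel size {h} mm"
        )
    center = 0.5 * (z0 + z1) * h
    first = center - (count - 1) / 2.0 * spacing_mm
    fsnap = (np.clip(np.floor(first / h), 0, nz - 1) + 0.5) * h
    pos = fsnap + np.arange(count) * spacing_mm
    # half-voxel leeway at the ends, then shift fully inside if possible
    if pos[-1] - pos[0] > (nz - 1) * h + 1e-9:
        raise ValueError(
            f"domain ({nz * h} mm) shorter than the requested plane span "
            f"({pos[-1] - pos[0]:.1f} mm)"
        )
    if pos[0] < h / 2:
        pos = pos + h * np.ceil((h / 2 - pos[0]) / h)
    if pos[-1] > (nz - 0.5) * h:
        pos = pos - h * np.ceil((pos[-1] - (nz - 0.5) * h) / h)
    return PlaneSet(axis=domain.flow_axis, positions_mm=tuple(pos),
                    spacing_mm=spacing_mm)


@dataclass
class HooverResult:
    per_plane: np.ndarray          # within-plane index per evaluation plane
    mean: float                    # mean coefficient over planes
    positions_mm: tuple
    excluded_planes: tuple = ()    # plane positions with no fluid voxels


def flow_homogeneity(flow, domain: SimulationDomain | None = None,
                     planes: PlaneSet | None = None) -> HooverResult:
    """Within-plane Hoover index of velocity magnitude, averaged over planes.

    Each plane's index is computed over that plane's flow-carrying voxels
    with equal weights; planes without fluid voxels are excluded and
    reported.
    """
    domain = domain or flow.domain
    if planes is None:
        planes = default_planes(domain)
    speed = flow.speed()
    mask = flow.fluid_mask
    per, pos, excluded = [], [], []
    for kpos, k in zip(planes.positions_mm, planes.layer_indices(domain.voxel_mm)):
        m = np.take(mask, k, axis=planes.axis)
        s = np.take(speed, k, axis=planes.axis)[m]
        if m.sum() == 0 or s.sum() == 0:
            excluded.append(kpos)
            continue
        per.append(hoover_index(s))
        pos.append(kpos)
    if not per:
        raise ValueError("no evaluation plane contained fluid voxels")
    per = np.asarray(per)
    return HooverResult(per_plane=per, mean=float(per.mean()),
                        positions_mm=tuple(pos), excluded_planes=tuple(excluded))


def axial_distribution_hoover(density_field: np.ndarray,
                              domain: SimulationDomain,
                              planes: PlaneSet | None = None,
                              homogenized: bool = True) -> float:
    """Across-plane Hoover index of a deposited quantity in the scaffold.

    Each plane contributes its integrated quantity over scaffold voxels,
    weighted by the plane's scaffold fluid volume; planes not intersecting
    the scaffold are dropped.
    """
    density = np.asarray(density_field, dtype=float)
    if (density < 0).any():
        raise ValueError("density must be nonnegative")
    if planes is None:
        planes = default_planes(domain)
    smask = domain.scaffold_mask(homogenized=homogenized)
    q, w = [], []
    for k in planes.layer_indices(domain.voxel_mm):
        m = np.take(smask, k, axis=planes.axis)
        nvox = int(m.sum())
        if nvox == 0:
            continue
        q.append(np.take(density, k, axis=planes.axis)[m].sum())
        w.append(nvox)
    if not q:
        raise ValueError("no plane intersects the scaffold")
    if sum(q) == 0:
        raise ValueError("axial Hoover undefined: zero total quantity")
    # per-volume density as the value, plane fluid volume as reference mass
    q = np.asarray(q)
    w = np.asarray(w, dtype=float)
    return hoover_index(q / w, w)
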