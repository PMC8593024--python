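"""Synthetic voxelized porous scaffolds.

The wet-lab reference object is a cancellous-bone xenograft block
(10 mm x 10 mm x 20 mm, 69% porous, macropore scale ~0.1 mm) scanned by
micro-CT.  At desk scale we replace the scan by a Gaussian-random-field
surrogate: seeded white noise is smoothed with a kernel whose width sets
the pore correlation length, thresholded at the porosity quantile, and
repaired so the fluid phase percolates along the longitudinal axis.
The surrogate matches the block's dimensions and porosity, not its exact
micro-architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

SOLID = 0
FLUID = 1

#: face-adjacency (6-neighbour) connectivity structure
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)

# defaults mirroring the xenograft block used in every simulation
DEFAULT_DIMS_MM = (10.0, 10.0, 20.0)
DEFAULT_VOXEL_MM = 0.25
DEFAULT_POROSITY = 0.69
DEFAULT_PORE_SCALE_MM = 0.5


class PorosityError(ValueError):
    """Raised when the generator cannot reach the requested porosity."""


@dataclass
class ScaffoldVolume:
    """Labeled voxel volume of a porous scaffold.

    Attributes
    ----------
    dims_mm : tuple of float
        Physical extent (x, y, z) in mm; z is the longitudinal axis.
    voxel_mm : float
        Isotropic voxel edge length in mm.
    occupancy : ndarray of uint8
        3D label array over {SOLID, FLUID}.
    porosity : float
        Fluid volume fraction, exactly FLUID count / total count.
    pore_scale_mm : float
        Target correlation length of the fluid phase.
    seed : int or None
        RNG seed used for generation (None for imported volumes).
    provenance : str
        ``"synthetic"`` or ``"imported"``.
    """

    dims_mm: tuple
    voxel_mm: float
    occupancy: np.ndarray
    porosity: float
    pore_scale_mm: float = DEFAULT_PORE_SCALE_MM
    seed: int | None = None
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.occupancy.shape

    def fluid_mask(self) -> np.ndarray:
        return self.occupancy == FLUID


def measure_porosity(vol) -> float:
    """Fluid volume fraction: FLUID voxel count / total voxel count."""
    occ = vol.occupancy if isinstance(vol, ScaffoldVolume) else np.asarray(vol)
    return float(np.count_nonzero(occ == FLUID) / occ.size)


def percolates(mask: np.ndarray, axis: int = 2) -> bool:
    """True if one face-connected fluid component spans ``axis`` end to end."""
    labels, n = ndimage.label(mask, structure=_FACE_STRUCT)
    if n == 0:
        return False
    first = np.take(labels, 0, axis=axis)
    last = np.take(labels, -1, axis=axis)
    return bool(np.intersect1d(first[first > 0], last[last > 0]).size)


def _spanning_union(mask: np.ndarray, axis: int = 2) -> np.ndarray | None:
    """Union of fluid components that span ``axis``; None if there is none."""
    labels, n = ndimage.label(mask, structure=_FACE_STRUCT)
    if n == 0:
        return None
    first = np.take(labels, 0, axis=axis)
    last = np.take(labels, -1, axis=axis)
    spanning = np.intersect1d(first[first > 0], last[last > 0])
    if spanning.size == 0:
        return None
    return np.isin(labels, spanning)


def generate_scaffold(
    dims_mm=DEFAULT_DIMS_MM,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    target_porosity: float = DEFAULT_POROSITY,
    pore_scale_mm: float = DEFAULT_PORE_SCALE_MM,
    seed: int = 0,
    max_drift: float = 0.02,
) -> ScaffoldVolume:
    """Generate a percolating Gaussian-random-field scaffold.

    White noise seeded by ``seed`` is smoothed with a Gaussian kernel of
    sigma = pore_scale_mm / (2 * voxel_mm), thresholded so that exactly the
    ``target_porosity`` fraction of voxels (lowest field values) is fluid,
    and non-spanning fluid pockets are solidified.  If that prunes away too
    much fluid, or no component spans, the threshold is relaxed stepwise
    (admitting more fluid) until a spanning phase at the target porosity
    (+-0.01) exists.  Deterministic given (seed, parameters).

    Raises
    ------
    PorosityError
        If the requested porosity is out of (0, 1) or the achieved
        porosity after percolation repair drifts more than ``max_drift``
        from the target.
    """
    if not 0.0 < target_porosity < 1.0:
        raise PorosityError(f"target porosity must be in (0,1), got {target_porosity}")
    if pore_scale_mm < 2.0 * voxel_mm:
        raise ValueError(
            f"pore_scale_mm={pore_scale_mm} under-resolved at voxel_mm={voxel_mm}; "
            "need pore_scale >= 2 voxels"
        )
    dims_mm = tuple(float(d) for d in dims_mm)
    if min(dims_mm) <= 0:
        raise ValueError(f"dims must be positive, got {dims_mm}")

    shape = tuple(max(1, int(round(d / voxel_mm))) for d in dims_mm)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    sigma = pore_scale_mm / (2.0 * voxel_mm)
    fld = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")

    order = np.argsort(fld, axis=None, kind="stable")
    n = fld.size
    occ = None
    frac = target_porosity
    while frac <= min(1.0, target_porosity + max_drift + 1e-12):
        k = min(n, int(round(frac * n)))
        mask = np.zeros(n, dtype=bool)
        mask[order[:k]] = True
        mask = mask.reshape(shape)
        if k == n:
            occ = mask
            break
        span = _spanning_union(mask, axis=2)
        if span is not None and measure_porosity(
            span.astype(np.uint8)
        ) >= target_porosity - 0.01:
            occ = span
            break
        frac += 0.005
    if occ is None:
        k = min(n, int(round(frac * n)))
        achieved = k / n
        raise PorosityError(
            f"percolation repair failed: no spanning fluid phase within "
            f"porosity drift {max_drift} of target {target_porosity} "
            f"(last tried {achieved:.4f})"
        )

    occupancy = occ.astype(np.uint8)
    porosity = measure_porosity(occupancy)
    if abs(porosity - target_porosity) > max_drift:
        raise PorosityError(
            f"achieved porosity {porosity:.4f} drifted more than {max_drift} "
            f"from target {target_porosity}"
        )
    return ScaffoldVolume(
        dims_mm=dims_mm,
        voxel_mm=float(voxel_mm),
        occupancy=occupancy,
        porosity=porosity,
        pore_scale_mm=float(pore_scale_mm),
        seed=int(seed),
        provenance="synthetic",
    )


# ---------------------------------------------------------------------------
# IO: NIfTI for interchange, npz + JSON sidecar string as internal format
# ---------------------------------------------------------------------------

def save_volume(vol: ScaffoldVolume, path) -> None:
    """Write a volume to ``.nii``/``.nii.gz`` (isotropic affine) or ``.npz``."""
    path = str(path)
    meta = {
        "dims_mm": list(vol.dims_mm),
        "voxel_mm": vol.voxel_mm,
        "pore_scale_mm": vol.pore_scale_mm,
        "seed": vol.seed,
        "provenance": vol.provenance,
        "labels": {"SOLID": SOLID, "FLUID": FLUID},
    }
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([vol.voxel_mm] * 3 + [1.0])
        img = nib.Nifti1Image(vol.occupancy.astype(np.uint8), affine)
        img.header.set_zooms((vol.voxel_mm,) * 3)
        img.header["descrip"] = b"perfuseed scaffold"
        nib.save(img, path)
    elif path.endswith(".npz"):
        np.savez_compressed(path, occupancy=vol.occupancy, sidecar=json.dumps(meta))
    else:
        raise ValueError(f"unsupported volume format: {path}")


def load_volume(path, spacing_atol: float = 1e-5) -> ScaffoldVolume:
    """Load a volume written by :func:`save_volume`.

    Rejects files with non-isotropic spacing; the flow grid is isotropic
    by construction.
    """
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        zooms = img.header.get_zooms()[:3]
        if max(zooms) - min(zooms) > spacing_atol:
            raise ValueError(f"non-isotropic spacing {zooms} not supported")
        occ = np.asarray(img.dataobj).astype(np.uint8)
        voxel = float(zooms[0])
        dims = tuple(s * voxel for s in occ.shape)
        pore_scale = DEFAULT_PORE_SCALE_MM
        seed = None
    elif path.endswith(".npz"):
        data = np.load(path, allow_pickle=False)
        occ = data["occupancy"].astype(np.uint8)
        meta = json.loads(str(data["sidecar"]))
        voxel = float(meta["voxel_mm"])
        dims = tuple(meta["dims_mm"])
        if any(abs(d - s * voxel) > voxel for d, s in zip(dims, occ.shape)):
            raise ValueError(
                f"sidecar dims {dims} inconsistent with shape {occ.shape} "
                f"at voxel {voxel}"
            )
        pore_scale = float(meta.get("pore_scale_mm", DEFAULT_PORE_SCALE_MM))
        seed = meta.get("seed")
    else:
        raise ValueError(f"unsupported volume format: {path}")
    return ScaffoldVolume(
        dims_mm=tuple(dims),
        voxel_mm=voxel,
        occupancy=occ,
        porosity=measure_porosity(occ),
        pore_scale_mm=pore_scale,
        seed=seed,
        provenance="imported",
    )
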