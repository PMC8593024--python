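"""Dynamic PET-like activity synthesis and ROI quantification.

The forward model turns a seeding simulation into the kind of data a
small-animal PET scanner produces after reconstruction: cells carry a
fixed fluorine-18 label, so each 5-minute frame is (deposited + suspended
cells per voxel) x activity per cell x the physical-decay factor, plus a
circulating free-tracer background in the fluid while cell suspension is
being perfused, blurred with an isotropic Gaussian point-spread function
and optionally degraded with Poisson counting noise.  Scanner physics
(sinograms, attenuation, randoms, dead time) is outside the model: the
quantification here operates on reconstructed images, as the ROI analysis
it emulates did.

Quantification mirrors the experimental readout: ROI time-activity curves
over the whole scaffold block, its axial thirds and the outflow tract;
physical decay correction; and the per-frame axial Hoover coefficient of
the activity distribution in the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import F18_HALF_LIFE_MIN
from .geometry import (CHAMBER_FLUID, CONNECTOR, OPEN_FLUID_LABELS,
                       OUTLET_PORT, SimulationDomain)
from .hoover import PlaneSet, axial_distribution_hoover, default_planes
from .seeding import SeedingResult

MBQ_PER_BQ = 1e-6

#: default label activity: 1 MBq offered to 2e5 cells with a 50% retained
#: uptake fraction (the uptake fraction is a free model parameter)
DEFAULT_ACTIVITY_PER_CELL_BQ = 1e6 / 2e5 * 0.5


@dataclass
class ActivitySeries4D:
    frames: np.ndarray              # (n_frames, nx, ny, nz), MBq per voxel
    frame_min: float
    frame_times_min: np.ndarray     # frame end times
    decay_corrected: bool = False
    isotope_half_life_min: float = F18_HALF_LIFE_MIN
    psf_mm: float = 0.0
    noise_model: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.frames < 0).any():
            raise ValueError("activity frames must be nonnegative")
        if len(self.frames) != len(self.frame_times_min):
            raise ValueError("frame count and frame times disagree")

    def mid_times_min(self) -> np.ndarray:
        return self.frame_times_min - self.frame_min / 2.0


class RoiTable(pd.DataFrame):
    """Per-frame ROI activities (MBq); columns whole/upper/middle/lower/outflow."""

    _metadata = ["frame_min"]

    @property
    def _constructor(self):
        return RoiTable


def synthesize_pet(seeding: SeedingResult, domain: SimulationDomain,
                   activity_per_cell_Bq: float = DEFAULT_ACTIVITY_PER_CELL_BQ,
                   free_tracer_fraction: float = 0.05,
                   psf_mm: float = 1.2, noise: str = "none", seed: int = 0,
                   efflux_rate_per_min: float = 0.002,
                   counts_per_MBq: float = 2e4) -> ActivitySeries4D:
    """Forward-model a dynamic activity series from a seeding simulation.

    ``free_tracer_fraction`` is the fraction of the injected activity
    circulating unbound during the perfusion phase (spread over the fluid
    volume); ``efflux_rate_per_min`` is a single-exponential label leak
    from cells during washout, producing the observed slight decline to a
    plateau.  Decay uses the physical fluorine-18 half-life from the
    labeling reference time t0 = start of perfusion.
    """
    if activity_per_cell_Bq < 0 or free_tracer_fraction < 0 or psf_mm < 0:
        raise ValueError("PET model parameters must be nonnegative")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    lam = np.log(2.0) / F18_HALF_LIFE_MIN
    prot = seeding.meta.get("protocol")
    t_seed = prot.seeding_duration_min if prot is not None else 60.0
    rng = np.random.default_rng(seed)
    h = domain.voxel_mm
    fluid = np.isin(domain.labels, OPEN_FLUID_LABELS)
    n_fluid = max(int(fluid.sum()), 1)

    frames = []
    times = np.asarray(seeding.frame_times_min, dtype=float)
    for k, t in enumerate(times):
        tm = t - 2.5  # frame mid-time
        cells = seeding.deposited_frames[k].astype(np.float64)
        # washout label leak from already-bound cells
        if tm > t_seed:
            cells = cells * np.exp(-efflux_rate_per_min * (tm - t_seed))
        cells = cells + seeding.suspended_frames[k]
        act = cells * activity_per_cell_Bq * MBQ_PER_BQ
        if tm <= t_seed and free_tracer_fraction > 0:
            injected = seeding.retention_series["injected_cells"].iloc[k]
            bg = injected * activity_per_cell_Bq * MBQ_PER_BQ \
                * free_tracer_fraction / n_fluid
            act = act + np.where(fluid, bg, 0.0)
        act = act * np.exp(-lam * tm)
        if psf_mm > 0:
            act = ndimage.gaussian_filter(act, sigma=psf_mm / 2.355 / h)
        if noise == "poisson":
            act = rng.poisson(np.maximum(act, 0) * counts_per_MBq) \
                / counts_per_MBq
        frames.append(act)
    return ActivitySeries4D(
        frames=np.asarray(frames), frame_min=float(times[1] - times[0])
        if len(times) > 1 else 5.0,
        frame_times_min=times, decay_corrected=False, psf_mm=psf_mm,
        noise_model=noise,
        meta={"activity_per_cell_Bq": activity_per_cell_Bq,
              "free_tracer_fraction": free_tracer_fraction,
              "efflux_rate_per_min": efflux_rate_per_min,
              "seed": seed},
    )


def decay_correct(series: ActivitySeries4D) -> ActivitySeries4D:
    """Scale each frame by exp(+lambda t_mid); refuses double correction."""
    if series.decay_corrected:
        raise ValueError("series is already decay-corrected")
    lam = np.log(2.0) / series.isotope_half_life_min
    fac = np.exp(lam * series.mid_times_min())
    return ActivitySeries4D(
        frames=series.frames * fac[:, None, None, None],
        frame_min=series.frame_min, frame_times_min=series.frame_times_min,
        decay_corrected=True,
        isotope_half_life_min=series.isotope_half_life_min,
        psf_mm=series.psf_mm, noise_model=series.noise_model,
        meta=dict(series.meta),
    )


def decay_uncorrect(series: ActivitySeries4D) -> ActivitySeries4D:
    if not series.decay_corrected:
        raise ValueError("series is not decay-corrected")
    lam = np.log(2.0) / series.isotope_half_life_min
    fac = np.exp(-lam * series.mid_times_min())
    out = ActivitySeries4D(
        frames=series.frames * fac[:, None, None, None],
        frame_min=series.frame_min, frame_times_min=series.frame_times_min,
        decay_corrected=False,
        isotope_half_life_min=series.isotope_half_life_min,
        psf_mm=series.psf_mm, noise_model=series.noise_model,
        meta=dict(series.meta),
    )
    return out


def _scaffold_bbox(domain: SimulationDomain):
    m = domain.scaffold_mask(homogenized=True)
    idx = np.argwhere(m)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def roi_timecourses(series: ActivitySeries4D,
                    domain: SimulationDomain) -> RoiTable:
    """ROI sums per frame: whole block, axial thirds, outflow tract."""
    if series.frames.shape[1:] != domain.shape:
        raise ValueError("activity series grid does not match the domain")
    bbox = _scaffold_bbox(domain)
    zsl = bbox[2]
    z_edges = np.linspace(zsl.start, zsl.stop, 4).round().astype(int)
    lab = domain.labels
    tract = np.zeros(domain.shape, dtype=bool)
    tract[:, :, zsl.stop:] = np.isin(
        lab[:, :, zsl.stop:], (CONNECTOR, OUTLET_PORT, CHAMBER_FLUID))
    rows = []
    for act in series.frames:
        blk = act[bbox[0], bbox[1], :]
        whole = blk[:, :, zsl.start:zsl.stop].sum()
        thirds = [blk[:, :, a:b].sum() for a, b in zip(z_edges[:-1], z_edges[1:])]
        rows.append((whole, *thirds, act[tract].sum()))
    tab = RoiTable(rows, columns=["whole", "upper", "middle", "lower",
                                  "outflow"],
                   index=pd.Index(series.frame_times_min, name="t_min"))
    tab.frame_min = series.frame_min
    return tab


def enrichment_and_hoover_timecourse(
        series: ActivitySeries4D, domain: SimulationDomain,
        planes: PlaneSet | None = None,
        table: RoiTable | None = None) -> pd.DataFrame:
    """Per-frame whole-block activity (MBq) and axial Hoover coefficient."""
    if table is None:
        table = roi_timecourses(series, domain)
    if planes is None:
        planes = default_planes(domain)
    hoov = []
    for act in series.frames:
        try:
            hoov.append(axial_distribution_hoover(act, domain, planes))
        except ValueError:
            hoov.append(np.nan)
    return pd.DataFrame(
        {"activity_MBq": table["whole"].to_numpy(), "axial_hoover": hoov},
        index=table.index,
    )
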