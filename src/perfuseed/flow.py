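"""Steady creeping flow through the reactor on a staggered (MAC) grid.

The momentum balance solved is Stokes flow with an optional Brinkman drag
term representing unresolved porous micro-structure:

    mu lap(u) - (mu / K) u - grad p = 0,      div u = 0,

with no-slip walls, a uniform prescribed velocity over the inlet port,
a mass-matched uniform velocity over the outlet port, and the pressure
referenced to zero at the outlet.  At the studied flow rates (order
1 ml/min through mm-scale ports) the Reynolds number is small, so inertia
is neglected and the whole problem is a single sparse linear solve; all
fields are exactly linear in the flow rate.

In RESOLVED mode scaffold solid voxels are no-slip obstacles.  In
HOMOGENIZED mode the scaffold block is treated as an isotropic Brinkman
medium whose permeability follows the Kozeny-Carman relation evaluated at
the block's porosity and pore scale.

Units: mm / s / mPa·s, so pressure is in mPa and 1 ml/min = 16.667 mm^3/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .constants import (DEFAULT_DENSITY_KG_M3, DEFAULT_VISCOSITY_MPAS,
                        KOZENY_CARMAN_CONST, ML_PER_MIN_TO_MM3_S)
from .geometry import (INLET_PORT, OUTLET_PORT, SCAFFOLD_FLUID, SCAFFOLD_SOLID,
                       SimulationDomain)

RESOLVED = "resolved"
HOMOGENIZED = "homogenized"


@dataclass(frozen=True)
class FluidProps:
    viscosity_mPas: float = DEFAULT_VISCOSITY_MPAS
    density_kg_m3: float = DEFAULT_DENSITY_KG_M3

    def __post_init__(self):
        if self.viscosity_mPas <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("viscosity and density must be strictly positive")


def kozeny_carman_permeability(porosity: float, pore_scale_mm: float,
                               constant: float = KOZENY_CARMAN_CONST) -> float:
    """Isotropic permeability (mm^2) of a granular medium."""
    phi = porosity
    return phi**3 * pore_scale_mm**2 / (constant * (1.0 - phi) ** 2)


class FlowSolveError(RuntimeError):
    pass


@dataclass
class FlowField:
    """Solved velocity/pressure on the MAC grid.

    ``u, v, w`` are face-normal velocities (mm/s) on x/y/z faces with
    shapes (nx+1,ny,nz), (nx,ny+1,nz), (nx,ny,nz+1); ``pressure`` is
    cell-centered (mPa, outlet-referenced, NaN outside the fluid).
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    pressure: np.ndarray
    domain: SimulationDomain
    mode: str
    inlet_flow_ml_min: float
    props: FluidProps
    fluid_mask: np.ndarray
    residuals: dict = field(default_factory=dict)
    _shear: np.ndarray | None = None

    def cell_velocity(self) -> np.ndarray:
        """Collocated velocity, shape (3, nx, ny, nz); zero outside fluid."""
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        out = np.stack([uc, vc, wc])
        out[:, ~self.fluid_mask] = 0.0
        return out

    def speed(self) -> np.ndarray:
        return np.sqrt((self.cell_velocity() ** 2).sum(axis=0))

    @property
    def shear_rate(self) -> np.ndarray:
        if self._shear is None:
            self._shear = shear_rate_field(self)
        return self._shear

    def plane_flux_mm3_s(self, k: int) -> float:
        """Volumetric flux through the z-face plane at index k."""
        h = self.domain.voxel_mm
        return float(self.w[:, :, k].sum() * h * h)

    def negated(self) -> "FlowField":
        """Reversed-perfusion field (Stokes flow is reversible)."""
        return FlowField(
            u=-self.u, v=-self.v, w=-self.w, pressure=-self.pressure,
            domain=self.domain, mode=self.mode,
            inlet_flow_ml_min=-self.inlet_flow_ml_min, props=self.props,
            fluid_mask=self.fluid_mask, residuals=dict(self.residuals),
        )


def _face_dirichlet(domain: SimulationDomain, q_mm3_s: float, reverse: bool):
    """Prescribed z-face velocities at the two port patches."""
    nx, ny, nz = domain.shape
    h = domain.voxel_mm
    dw = np.zeros((nx, ny, nz + 1))
    m_in = domain.labels[:, :, 0] == INLET_PORT
    m_out = domain.labels[:, :, -1] == OUTLET_PORT
    win = q_mm3_s / (m_in.sum() * h * h)
    wout = q_mm3_s / (m_out.sum() * h * h)
    sgn = -1.0 if reverse else 1.0
    dw[:, :, 0][m_in] = sgn * win
    dw[:, :, nz][m_out] = sgn * wout
    return dw


def solve_flow(domain: SimulationDomain, props: FluidProps | None = None,
               inlet_flow_ml_min: float = 1.0, mode: str = HOMOGENIZED,
               reverse: bool = False,
               pore_scale_mm: float | None = None) -> FlowField:
    """Solve the Stokes-Brinkman system on the reactor domain.

    The sparse saddle-point system (momentum on active faces, continuity
    per fluid cell, one pressure pinned at the outlet) is factorized
    directly, so the solution is exact to machine/LU precision; the
    recorded residuals report the worst cell divergence and the worst
    cross-sectional flux error against the prescribed rate.
    """
    if props is None:
        props = FluidProps()
    if inlet_flow_ml_min <= 0:
        raise ValueError("inlet flow rate must be positive")
    if mode not in (RESOLVED, HOMOGENIZED):
        raise ValueError(f"unknown mode {mode!r}")

    lab = domain.labels
    nx, ny, nz = lab.shape
    h = domain.voxel_mm
    mu = props.viscosity_mPas
    q = inlet_flow_ml_min * ML_PER_MIN_TO_MM3_S

    fluid = domain.fluid_mask(homogenized=(mode == HOMOGENIZED))
    if not fluid.any():
        raise FlowSolveError("domain has no fluid cells")

    # Brinkman drag sigma = mu/K in porous scaffold cells (homogenized mode)
    sigma = np.zeros(lab.shape)
    if mode == HOMOGENIZED:
        # permeability uses the true micro-structure pore scale, which may
        # be finer than the coarse surrogate's correlation length
        K = kozeny_carman_permeability(
            domain.porosity, pore_scale_mm or domain.pore_scale_mm)
        sigma[np.isin(lab, (SCAFFOLD_FLUID, SCAFFOLD_SOLID))] = mu / K

    # active (unknown) faces: both adjacent cells fluid
    act_u = np.zeros((nx + 1, ny, nz), dtype=bool)
    act_v = np.zeros((nx, ny + 1, nz), dtype=bool)
    act_w = np.zeros((nx, ny, nz + 1), dtype=bool)
    act_u[1:nx] = fluid[:-1] & fluid[1:]
    act_v[:, 1:ny] = fluid[:, :-1] & fluid[:, 1:]
    act_w[:, :, 1:nz] = fluid[:, :, :-1] & fluid[:, :, 1:]

    dw = _face_dirichlet(domain, q, reverse)
    du = np.zeros((nx + 1, ny, nz))
    dv = np.zeros((nx, ny + 1, nz))

    iu = np.full(act_u.shape, -1, dtype=np.int64)
    iv = np.full(act_v.shape, -1, dtype=np.int64)
    iw = np.full(act_w.shape, -1, dtype=np.int64)
    nu, nv, nw = int(act_u.sum()), int(act_v.sum()), int(act_w.sum())
    iu[act_u] = np.arange(nu)
    iv[act_v] = nu + np.arange(nv)
    iw[act_w] = nu + nv + np.arange(nw)
    ip = np.full(lab.shape, -1, dtype=np.int64)
    npr = int(fluid.sum())
    ip[fluid] = nu + nv + nw + np.arange(npr)
    ntot = nu + nv + nw + npr

    rows, cols, vals = [], [], []
    rhs = np.zeros(ntot)
    inv_h = 1.0 / h
    mu_h2 = mu / (h * h)

    def momentum(idx_map, act, dval, axis, sig_face):
        coords = np.argwhere(act)
        ai, aj, ak = coords[:, 0], coords[:, 1], coords[:, 2]
        row = idx_map[ai, aj, ak]
        diag = np.full(row.shape, -6.0 * mu_h2) - sig_face
        shape = act.shape
        for d in range(3):
            for sgn in (-1, 1):
                ni = ai + (sgn if d == 0 else 0)
                nj = aj + (sgn if d == 1 else 0)
                nk = ak + (sgn if d == 2 else 0)
                if d == axis:
                    # normal direction: neighbor always in bounds
                    nb = idx_map[ni, nj, nk]
                    m = nb >= 0
                    rows.append(row[m]); cols.append(nb[m])
                    vals.append(np.full(m.sum(), mu_h2))
                    if (~m).any():
                        np.add.at(rhs, row[~m],
                                  -mu_h2 * dval[ni[~m], nj[~m], nk[~m]])
                else:
                    inb = ((ni >= 0) & (ni < shape[0]) & (nj >= 0)
                           & (nj < shape[1]) & (nk >= 0) & (nk < shape[2]))
                    nb = np.full(row.shape, -1, dtype=np.int64)
                    nb[inb] = idx_map[ni[inb], nj[inb], nk[inb]]
                    m = nb >= 0
                    rows.append(row[m]); cols.append(nb[m])
                    vals.append(np.full(m.sum(), mu_h2))
                    # wall half a cell away: ghost value -u (no-slip mirror)
                    diag[~m] += -1.0 * mu_h2
        rows.append(row); cols.append(row); vals.append(diag)
        return ai, aj, ak, row

    # u-momentum: face i sits between cells (i-1,j,k) and (i,j,k)
    coords = np.argwhere(act_u)
    sfu = 0.5 * (sigma[coords[:, 0] - 1, coords[:, 1], coords[:, 2]]
                 + sigma[coords[:, 0], coords[:, 1], coords[:, 2]])
    ai, aj, ak, row_u = momentum(iu, act_u, du, 0, sfu)
    # pressure gradient: -(p_R - p_L)/h
    pl = ip[ai - 1, aj, ak]; pr = ip[ai, aj, ak]
    rows.append(row_u); cols.append(pl); vals.append(np.full(pl.shape, inv_h))
    rows.append(row_u); cols.append(pr); vals.append(np.full(pr.shape, -inv_h))

    coords = np.argwhere(act_v)
    sfv = 0.5 * (sigma[coords[:, 0], coords[:, 1] - 1, coords[:, 2]]
                 + sigma[coords[:, 0], coords[:, 1], coords[:, 2]])
    ai, aj, ak, row_v = momentum(iv, act_v, dv, 1, sfv)
    pl = ip[ai, aj - 1, ak]; pr = ip[ai, aj, ak]
    rows.append(row_v); cols.append(pl); vals.append(np.full(pl.shape, inv_h))
    rows.append(row_v); cols.append(pr); vals.append(np.full(pr.shape, -inv_h))

    coords = np.argwhere(act_w)
    sfw = 0.5 * (sigma[coords[:, 0], coords[:, 1], coords[:, 2] - 1]
                 + sigma[coords[:, 0], coords[:, 1], coords[:, 2]])
    ai, aj, ak, row_w = momentum(iw, act_w, dw, 2, sfw)
    pl = ip[ai, aj, ak - 1]; pr = ip[ai, aj, ak]
    rows.append(row_w); cols.append(pl); vals.append(np.full(pl.shape, inv_h))
    rows.append(row_w); cols.append(pr); vals.append(np.full(pr.shape, -inv_h))

    # continuity per fluid cell
    coords = np.argwhere(fluid)
    ci, cj, ck = coords[:, 0], coords[:, 1], coords[:, 2]
    row_p = ip[ci, cj, ck]
    for idx_map, dval, off in (
        (iu, du, (1, 0, 0)), (iv, dv, (0, 1, 0)), (iw, dw, (0, 0, 1)),
    ):
        for sgn, shift in ((1.0, off), (-1.0, (0, 0, 0))):
            fi, fj, fk = ci + shift[0], cj + shift[1], ck + shift[2]
            nb = idx_map[fi, fj, fk]
            m = nb >= 0
            rows.append(row_p[m]); cols.append(nb[m])
            vals.append(np.full(m.sum(), sgn * inv_h))
            if (~m).any():
                np.add.at(rhs, row_p[~m],
                          -sgn * inv_h * dval[fi[~m], fj[~m], fk[~m]])

    rows = np.concatenate(rows); cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    # pin one outlet-cell pressure (constant-pressure nullspace)
    out_cells = np.argwhere(lab == OUTLET_PORT)
    pin_cell = out_cells[0] if len(out_cells) else coords[-1]
    pin_row = ip[tuple(pin_cell)]
    keep = rows != pin_row
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    rows = np.append(rows, pin_row)
    cols = np.append(cols, pin_row)
    vals = np.append(vals, 1.0)
    rhs[pin_row] = 0.0

    A = sparse.csc_matrix((vals, (rows, cols)), shape=(ntot, ntot))
    try:
        # MMD_ATA keeps LU fill low on this saddle-point sparsity pattern
        sol = splu(A, permc_spec="MMD_ATA").solve(rhs)
    except Exception as exc:  # pragma: no cover - solver backend failure
        raise FlowSolveError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise FlowSolveError("sparse solve returned non-finite values "
                             "(singular system; check port connectivity)")

    u = du.copy(); v = dv.copy(); w = dw.copy()
    u[act_u] = sol[iu[act_u]]
    v[act_v] = sol[iv[act_v]]
    w[act_w] = sol[iw[act_w]]
    p = np.full(lab.shape, np.nan)
    p[fluid] = sol[ip[fluid]]
    p[fluid] -= np.nanmean(p[lab == OUTLET_PORT])

    div = (u[1:] - u[:-1] + v[:, 1:] - v[:, :-1]
           + w[:, :, 1:] - w[:, :, :-1]) * inv_h
    max_div = float(np.abs(div[fluid]).max())
    fluxes = np.abs(w.sum(axis=(0, 1)) * h * h)
    flux_err = float(np.abs(fluxes - q).max() / q)

    ff = FlowField(u=u, v=v, w=w, pressure=p, domain=domain, mode=mode,
                   inlet_flow_ml_min=(-inlet_flow_ml_min if reverse
                                      else inlet_flow_ml_min),
                   props=props, fluid_mask=fluid,
                   residuals={"max_divergence_s1": max_div,
                              "max_plane_flux_rel_err": flux_err,
                              "n_unknowns": ntot})
    if flux_err > 0.01:
        raise FlowSolveError(
            f"cross-sectional flux deviates {flux_err:.2%} from the "
            f"prescribed rate (residuals: {ff.residuals})"
        )
    return ff


def shear_rate_field(flow: FlowField) -> np.ndarray:
    """Scalar shear rate gamma-dot = sqrt(2 D:D), 1/s, cell-centered.

    D is the symmetric part of the velocity-gradient tensor computed by
    central differences (one-sided at the array boundaries).
    """
    h = flow.domain.voxel_mm
    vel = flow.cell_velocity()
    g = np.empty((3, 3) + vel.shape[1:])
    for i in range(3):
        for j in range(3):
            g[i, j] = np.gradient(vel[i], h, axis=j)
    d = 0.5 * (g + g.transpose(1, 0, 2, 3, 4))
    return np.sqrt(2.0 * (d**2).sum(axis=(0, 1)))


def max_shear_in_scaffold(flow: FlowField, domain: SimulationDomain | None = None
                          ) -> float:
    """Maximum shear rate over the scaffold's flow-carrying voxels."""
    domain = domain or flow.domain
    mask = domain.scaffold_mask(homogenized=(flow.mode == HOMOGENIZED))
    if not mask.any():
        raise ValueError("domain has no scaffold flow region")
    return float(flow.shear_rate[mask].max())
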