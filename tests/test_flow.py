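import numpy as np
import pytest

from perfuseed import flow as fl
from perfuseed import geometry as geo
from perfuseed.constants import ML_PER_MIN_TO_MM3_S
from perfuseed.scaffold import generate_scaffold
from conftest import make_connector_domain


def rect_duct_profile(points_y, points_z, half_w, half_d, n_terms=199):
    """Series solution for pressure-driven flow in a rectangular duct."""
    u = np.zeros((len(points_y), len(points_z)))
    Y, Z = np.meshgrid(points_y, points_z, indexing="ij")
    for n in range(1, n_terms + 1, 2):
        a = n * np.pi / (2 * half_w)
        u += ((-1) ** ((n - 1) // 2) / n**3
              * (1 - np.cosh(a * Z) / np.cosh(a * half_d))
              * np.cos(a * Y))
    return u


@pytest.fixture(scope="module")
def duct_flow():
    dom = geo.duct_domain(6.0, 6.0, 18.0, 0.5)
    return dom, fl.solve_flow(dom, inlet_flow_ml_min=1.0, mode=fl.RESOLVED)


class TestStokesSolver:
    def test_duct_profile_matches_series_solution(self, duct_flow):
        dom, ff = duct_flow
        k = dom.shape[2] // 2  # mid-length: fully developed at Re << 1
        w = ff.cell_velocity()[2][1:-1, 1:-1, k]
        centers = (np.arange(12) + 0.5) * 0.5 - 3.0
        ana = rect_duct_profile(centers, centers, 3.0, 3.0)
        ratio_num = w[5:7, 5:7].mean() / w.mean()
        ratio_ana = ana[5:7, 5:7].mean() / ana.mean()
        assert ratio_num == pytest.approx(ratio_ana, rel=0.02)

    def test_mass_conservation_through_every_plane(self, duct_flow):
        dom, ff = duct_flow
        q = ff.inlet_flow_ml_min * ML_PER_MIN_TO_MM3_S
        for k in range(dom.shape[2] + 1):
            assert ff.plane_flux_mm3_s(k) == pytest.approx(q, rel=0.01)

    def test_field_is_linear_in_flow_rate(self, duct_flow):
        dom, ff = duct_flow
        ff2 = fl.solve_flow(dom, inlet_flow_ml_min=2.0, mode=fl.RESOLVED)
        scale = np.abs(ff2.w[ff.w != 0] / ff.w[ff.w != 0] - 2.0)
        assert scale.max() < 1e-6

    def test_reversed_boundary_conditions_negate_the_field(self, duct_flow):
        dom, ff = duct_flow
        fr = fl.solve_flow(dom, inlet_flow_ml_min=1.0, mode=fl.RESOLVED,
                           reverse=True)
        assert np.allclose(fr.w, -ff.w, atol=1e-10)
        assert np.allclose(fr.u, -ff.u, atol=1e-10)

    def test_mirror_symmetric_domain_gives_symmetric_field(self, duct_flow):
        dom, ff = duct_flow
        w = ff.cell_velocity()[2]
        assert np.allclose(w, w[::-1, :, :], atol=1e-9 * np.abs(w).max())

    def test_no_slip_in_walls(self, duct_flow):
        dom, ff = duct_flow
        vel = ff.cell_velocity()
        assert np.abs(vel[:, dom.labels == geo.WALL]).max() == 0.0

    def test_rejects_nonpositive_rate_and_bad_mode(self, duct_flow):
        dom, _ = duct_flow
        with pytest.raises(ValueError):
            fl.solve_flow(dom, inlet_flow_ml_min=0.0)
        with pytest.raises(ValueError):
            fl.solve_flow(dom, mode="spectral")


class TestHomogenizedMode:
    def test_plug_flow_plane_mean_is_q_over_a(self, coarse_scaffold):
        dom = make_connector_domain(coarse_scaffold, geo.CYLINDRICAL, 4.0,
                                    diameter_mm=10.0)
        ff = fl.solve_flow(dom, inlet_flow_ml_min=1.0, mode=fl.HOMOGENIZED,
                           pore_scale_mm=0.5)
        q = ML_PER_MIN_TO_MM3_S
        h = dom.voxel_mm
        z0, z1 = dom.scaffold_zrange
        for k in range(z0, z1 + 1):
            assert ff.plane_flux_mm3_s(k) == pytest.approx(q, rel=0.01)

    def test_kozeny_carman_value(self):
        # phi^3 d^2 / (180 (1-phi)^2) by hand for phi=0.69, d=0.5
        k = fl.kozeny_carman_permeability(0.69, 0.5)
        assert k == pytest.approx(0.69**3 * 0.25 / (180 * 0.31**2), rel=1e-12)

    def test_wider_inlet_lowers_scaffold_shear(self, coarse_scaffold):
        shear = {}
        for d in (1.0, 10.0):
            dom = make_connector_domain(coarse_scaffold, geo.CYLINDRICAL,
                                        10.0, diameter_mm=d)
            ff = fl.solve_flow(dom, inlet_flow_ml_min=1.0,
                               mode=fl.HOMOGENIZED, pore_scale_mm=0.5)
            shear[d] = fl.max_shear_in_scaffold(ff)
        assert shear[10.0] < shear[1.0]


def _field_from_velocity(u_fn, shape=(8, 8, 8), h=0.5):
    """FlowField carrying a prescribed collocated velocity (via faces)."""
    nx, ny, nz = shape
    lab = np.full(shape, geo.SCAFFOLD_FLUID, dtype=np.uint8)
    dom = geo.SimulationDomain(labels=lab, voxel_mm=h,
                               scaffold_zrange=(0, nz))
    # face-center coordinate grids
    def face_coords(axis):
        coords = [np.arange(nx), np.arange(ny), np.arange(nz)]
        coords[axis] = np.arange(shape[axis] + 1) - 0.5
        g = np.meshgrid(*coords, indexing="ij")
        return [(c + 0.5) * h for c in g]

    u = u_fn(*face_coords(0))[0]
    v = u_fn(*face_coords(1))[1]
    w = u_fn(*face_coords(2))[2]
    return fl.FlowField(u=u, v=v, w=w, pressure=np.zeros(shape), domain=dom,
                        mode=fl.RESOLVED, inlet_flow_ml_min=1.0,
                        props=fl.FluidProps(),
                        fluid_mask=np.ones(shape, dtype=bool))


class TestShearRate:
    def test_uniform_translation_has_zero_shear(self):
        ff = _field_from_velocity(lambda x, y, z: (np.full_like(x, 2.0),
                                                   np.full_like(x, -1.0),
                                                   np.full_like(x, 0.5)))
        assert np.abs(ff.shear_rate).max() < 1e-12

    def test_couette_profile_recovers_rate(self):
        k = 3.0
        ff = _field_from_velocity(lambda x, y, z: (k * y, 0 * x, 0 * x))
        assert np.allclose(ff.shear_rate, k, atol=1e-9)
        assert fl.max_shear_in_scaffold(ff) == pytest.approx(k)

    def test_matches_brute_force_gradient_tensor(self):
        rng = np.random.default_rng(11)
        shape, h = (6, 6, 6), 0.5
        lab = np.full(shape, geo.SCAFFOLD_FLUID, dtype=np.uint8)
        dom = geo.SimulationDomain(labels=lab, voxel_mm=h,
                                   scaffold_zrange=(0, 6))
        ff = fl.FlowField(u=rng.random((7, 6, 6)), v=rng.random((6, 7, 6)),
                          w=rng.random((6, 6, 7)), pressure=np.zeros(shape),
                          domain=dom, mode=fl.RESOLVED, inlet_flow_ml_min=1.0,
                          props=fl.FluidProps(),
                          fluid_mask=np.ones(shape, dtype=bool))
        vel = ff.cell_velocity()
        expected = np.zeros(shape)
        for i in range(6):
            for j in range(6):
                for kk in range(6):
                    g = np.zeros((3, 3))
                    for a in range(3):
                        for b in range(3):
                            idx = [i, j, kk]
                            if idx[b] == 0:
                                lo, hi, dx = 0, 1, h
                            elif idx[b] == 5:
                                lo, hi, dx = 4, 5, h
                            else:
                                lo, hi, dx = idx[b] - 1, idx[b] + 1, 2 * h
                            ilo, ihi = list(idx), list(idx)
                            ilo[b], ihi[b] = lo, hi
                            g[a, b] = (vel[a][tuple(ihi)]
                                       - vel[a][tuple(ilo)]) / dx
                    d = 0.5 * (g + g.T)
                    expected[i, j, kk] = np.sqrt(2 * (d**2).sum())
        assert np.allclose(ff.shear_rate, expected, atol=1e-12)

    def test_zero_flow_means_zero_max_shear(self):
        ff = _field_from_velocity(lambda x, y, z: (0 * x, 0 * x, 0 * x))
        assert fl.max_shear_in_scaffold(ff) == 0.0
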