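import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfuseed import geometry as geo
from perfuseed.hoover import (PlaneSet, axial_distribution_hoover,
                              default_planes, flow_homogeneity, hoover_index)

positive_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=2,
    max_size=12).filter(lambda v: sum(v) > 0)


class TestHooverIndex:
    def test_uniform_distribution_is_zero(self):
        assert hoover_index([3.0] * 7) == pytest.approx(0.0)

    def test_single_occupied_bin_attains_maximum(self):
        # all quantity in one of n equal bins: H = 1 - 1/n
        assert hoover_index([0, 0, 5, 0]) == pytest.approx(0.75)

    def test_matches_brute_force_share_computation(self):
        v = np.array([1.0, 2.0, 3.0, 6.0])
        expected = 0.5 * sum(abs(x / v.sum() - 0.25) for x in v)
        assert hoover_index(v) == pytest.approx(expected, abs=1e-15)
        # by hand: shares (1,2,3,6)/12 vs 1/4 -> (2+1+0+3)/12 / 2 = 1/4
        assert expected == pytest.approx(0.25)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(positive_vectors, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, v, c):
        assert hoover_index(np.array(v) * c) == pytest.approx(
            hoover_index(v), abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(positive_vectors, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, v, rnd):
        p = list(v)
        rnd.shuffle(p)
        assert hoover_index(p) == pytest.approx(hoover_index(v), abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(positive_vectors)
    def test_bounded_below_maximal_inequality(self, v):
        h = hoover_index(v)
        assert -1e-12 <= h <= 1 - 1 / len(v) + 1e-12

    def test_merging_equal_share_bins_never_increases(self):
        # coarsening property checked by brute force on small vectors
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.random(6)
            # merged bin carries the mean per-capita value over weight 2
            merged = np.concatenate([[(v[0] + v[1]) / 2], v[2:]])
            h_fine = hoover_index(v, np.ones(6))
            h_coarse = hoover_index(merged, np.array([2.0] + [1.0] * 4))
            assert h_coarse <= h_fine + 1e-12

    def test_weighted_form_reduces_to_population_shares(self):
        # equal per-capita values over unequal weights -> perfectly even
        assert hoover_index([2.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)
        # concentrating the per-capita value in the small bin is unequal
        assert hoover_index([4.0, 1.0], [1.0, 4.0]) > 0.3

    def test_error_cases(self):
        with pytest.raises(ValueError):
            hoover_index([0.0, 0.0])
        with pytest.raises(ValueError):
            hoover_index([1.0, -0.5])
        with pytest.raises(ValueError):
            hoover_index([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            hoover_index([1.0, 2.0], [1.0, 0.0])


class TestPlaneSet:
    def test_default_stack_is_24_planes_at_1mm(self, type2_domain):
        ps = default_planes(type2_domain)
        assert ps.count == 24
        assert ps.spacing_mm == 1.0
        d = np.diff(ps.positions_mm)
        assert np.allclose(d, 1.0)

    def test_positions_fall_on_voxel_centers(self, type2_domain):
        h = type2_domain.voxel_mm
        for p in default_planes(type2_domain).positions_mm:
            assert (p / h - 0.5) == pytest.approx(round(p / h - 0.5), abs=1e-9)

    def test_custom_count_and_spacing_stay_uniform(self, type2_domain):
        ps = default_planes(type2_domain, count=12, spacing_mm=2.0)
        assert ps.count == 12
        assert np.allclose(np.diff(ps.positions_mm), 2.0)

    def test_domain_too_short_is_rejected(self, type2_domain):
        with pytest.raises(ValueError, match="shorter"):
            default_planes(type2_domain, count=200)

    def test_nonuniform_positions_rejected(self):
        with pytest.raises(ValueError):
            PlaneSet(axis=2, positions_mm=(0.5, 1.5, 3.5), spacing_mm=1.0)


class TestFlowHomogeneity:
    def test_uniform_plug_flow_scores_zero(self):
        lab = np.full((6, 6, 30), geo.SCAFFOLD_FLUID, dtype=np.uint8)
        dom = geo.SimulationDomain(labels=lab, voxel_mm=1.0,
                                   scaffold_zrange=(5, 25))
        from perfuseed import flow as fl

        ff = fl.FlowField(u=np.zeros((7, 6, 30)), v=np.zeros((6, 7, 30)),
                          w=np.ones((6, 6, 31)), pressure=np.zeros(lab.shape),
                          domain=dom, mode=fl.RESOLVED, inlet_flow_ml_min=1.0,
                          props=fl.FluidProps(),
                          fluid_mask=np.ones(lab.shape, dtype=bool))
        res = flow_homogeneity(ff, dom)
        assert res.mean == pytest.approx(0.0, abs=1e-12)

    def test_single_plane_reduces_to_scalar_index(self):
        lab = np.full((2, 2, 3), geo.SCAFFOLD_FLUID, dtype=np.uint8)
        dom = geo.SimulationDomain(labels=lab, voxel_mm=1.0,
                                   scaffold_zrange=(0, 3))
        from perfuseed import flow as fl

        w = np.zeros((2, 2, 4))
        w[:, :, 1] = np.array([[1.0, 1.0], [1.0, 5.0]])
        w[:, :, 2] = w[:, :, 1]
        ff = fl.FlowField(u=np.zeros((3, 2, 3)), v=np.zeros((2, 3, 3)),
                          w=w, pressure=np.zeros(lab.shape), domain=dom,
                          mode=fl.RESOLVED, inlet_flow_ml_min=1.0,
                          props=fl.FluidProps(),
                          fluid_mask=np.ones(lab.shape, dtype=bool))
        planes = PlaneSet(axis=2, positions_mm=(1.5,), spacing_mm=1.0)
        res = flow_homogeneity(ff, dom, planes)
        assert res.per_plane[0] == pytest.approx(hoover_index([1, 1, 1, 5]))


class TestAxialDistribution:
    def test_uniform_per_volume_deposition_scores_zero(self, type2_domain):
        dom = type2_domain
        density = dom.scaffold_mask(homogenized=True).astype(float)
        assert axial_distribution_hoover(density, dom) == pytest.approx(
            0.0, abs=1e-12)

    def test_top_third_concentration_matches_plane_sum_oracle(self,
                                                              type2_domain):
        dom = type2_domain
        z0, z1 = dom.scaffold_zrange
        cut = z0 + (z1 - z0) // 3
        density = np.zeros(dom.shape)
        smask = dom.scaffold_mask(homogenized=True)
        density[:, :, :cut][smask[:, :, :cut]] = 2.0
        planes = default_planes(dom)
        # independent oracle: per-plane sums and volumes by hand
        q, w = [], []
        for k in planes.layer_indices(dom.voxel_mm):
            m = smask[:, :, k]
            if m.sum() == 0:
                continue
            q.append(density[:, :, k][m].sum())
            w.append(m.sum())
        q, w = np.array(q), np.array(w, dtype=float)
        shares = (q / q.sum())
        ref = w / w.sum()
        expected = 0.5 * np.abs(shares - ref).sum()
        got = axial_distribution_hoover(density, dom, planes)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_total_quantity_rejected(self, type2_domain):
        with pytest.raises(ValueError):
            axial_distribution_hoover(np.zeros(type2_domain.shape),
                                      type2_domain)
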