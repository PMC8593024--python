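import numpy as np
import pandas as pd
import pytest

from perfuseed.constants import F18_HALF_LIFE_MIN
from perfuseed.pet import (ActivitySeries4D, decay_correct, decay_uncorrect,
                           enrichment_and_hoover_timecourse, roi_timecourses,
                           synthesize_pet)
from perfuseed.seeding import (CellSuspension, DepositionParams,
                               PerfusionProtocol, simulate_seeding)
from perfuseed.study import TRUE_PORE_SCALE_MM


@pytest.fixture(scope="module")
def seeding_run(type2_domain, type2_flow):
    return simulate_seeding(
        type2_flow, None, type2_domain, PerfusionProtocol(rate_ml_min=0.5),
        CellSuspension(), DepositionParams(), seed=0, n_particles=1500,
        pore_scale_mm=TRUE_PORE_SCALE_MM)


def static_series(shape=(4, 4, 4), frame_times=(5.0, 10.0), value=1.0,
                  hot=None):
    frames = np.zeros((len(frame_times),) + shape)
    if hot is not None:
        frames[(slice(None),) + hot] = value
    else:
        frames[:] = value
    return ActivitySeries4D(frames=frames, frame_min=5.0,
                            frame_times_min=np.asarray(frame_times))


class TestSynthesis:
    def test_zero_cells_zero_background_is_all_zero(self, seeding_run,
                                                    type2_domain):
        import copy

        empty = copy.copy(seeding_run)
        empty.deposited_frames = [np.zeros(type2_domain.shape)
                                  for _ in seeding_run.deposited_frames]
        empty.suspended_frames = [np.zeros(type2_domain.shape)
                                  for _ in seeding_run.suspended_frames]
        ser = synthesize_pet(empty, type2_domain, free_tracer_fraction=0.0,
                             noise="none")
        assert np.abs(ser.frames).max() == 0.0

    def test_half_life_identity_for_static_source(self, seeding_run,
                                                  type2_domain):
        # frame mid-times one half-life apart -> activity halves exactly
        import copy

        run2 = copy.copy(seeding_run)
        const = [seeding_run.deposited_frames[-1]] * 2
        run2.deposited_frames = const
        run2.suspended_frames = [np.zeros(type2_domain.shape)] * 2
        run2.frame_times_min = np.array([2.5 + 2.5,
                                         2.5 + 2.5 + F18_HALF_LIFE_MIN])
        run2.retention_series = seeding_run.retention_series.iloc[:2]
        run2.meta = dict(seeding_run.meta)
        run2.meta["protocol"] = PerfusionProtocol(
            rate_ml_min=0.5, seeding_duration_min=1e-6 + 200,
            washout_duration_min=1.0)
        ser = synthesize_pet(run2, type2_domain, free_tracer_fraction=0.0,
                             psf_mm=0.0, noise="none")
        ratio = ser.frames[1].sum() / ser.frames[0].sum()
        assert ratio == pytest.approx(0.5, rel=1e-9)

    def test_total_activity_matches_per_voxel_summation(self, seeding_run,
                                                        type2_domain):
        ser = synthesize_pet(seeding_run, type2_domain,
                             free_tracer_fraction=0.0, psf_mm=0.0,
                             noise="none")
        lam = np.log(2) / F18_HALF_LIFE_MIN
        a_cell = ser.meta["activity_per_cell_Bq"]
        prot = seeding_run.meta["protocol"]
        for k, t in enumerate(seeding_run.frame_times_min):
            cells = (seeding_run.deposited_frames[k]
                     + seeding_run.suspended_frames[k])
            tm = t - 2.5
            if tm > prot.seeding_duration_min:
                leak = np.exp(-ser.meta["efflux_rate_per_min"]
                              * (tm - prot.seeding_duration_min))
                cells = (seeding_run.deposited_frames[k] * leak
                         + seeding_run.suspended_frames[k])
            expected = cells.sum() * a_cell * 1e-6 * np.exp(-lam * tm)
            # frame snapshots are stored in float32
            assert ser.frames[k].sum() == pytest.approx(expected, rel=1e-5)

    def test_poisson_noise_is_seeded(self, seeding_run, type2_domain):
        a = synthesize_pet(seeding_run, type2_domain, noise="poisson", seed=1)
        b = synthesize_pet(seeding_run, type2_domain, noise="poisson", seed=1)
        c = synthesize_pet(seeding_run, type2_domain, noise="poisson", seed=2)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_negative_parameters_rejected(self, seeding_run, type2_domain):
        with pytest.raises(ValueError):
            synthesize_pet(seeding_run, type2_domain,
                           activity_per_cell_Bq=-1.0)


class TestDecayCorrection:
    def test_flat_source_becomes_flat(self):
        lam = np.log(2) / F18_HALF_LIFE_MIN
        times = np.array([5.0, 10.0, 15.0, 20.0])
        frames = np.ones((4, 3, 3, 3)) * np.exp(
            -lam * (times - 2.5))[:, None, None, None]
        ser = ActivitySeries4D(frames=frames, frame_min=5.0,
                               frame_times_min=times)
        cor = decay_correct(ser)
        sums = cor.frames.sum(axis=(1, 2, 3))
        assert np.abs(sums / sums[0] - 1).max() < 1e-6

    def test_round_trip_identity(self):
        ser = static_series(value=2.0)
        back = decay_uncorrect(decay_correct(ser))
        assert np.allclose(back.frames, ser.frames, rtol=1e-12)
        assert not back.decay_corrected

    def test_correction_factor_at_one_half_life_is_two(self):
        times = np.array([2.5 + F18_HALF_LIFE_MIN])
        ser = ActivitySeries4D(frames=np.ones((1, 2, 2, 2)), frame_min=5.0,
                               frame_times_min=times)
        cor = decay_correct(ser)
        assert cor.frames[0, 0, 0, 0] == pytest.approx(2.0, rel=1e-12)

    def test_double_correction_guarded(self):
        ser = decay_correct(static_series())
        with pytest.raises(ValueError):
            decay_correct(ser)


class TestRoiAnalysis:
    def test_uniform_activity_thirds_are_equal(self, type2_domain):
        n_frames = 2
        frames = np.zeros((n_frames,) + type2_domain.shape)
        z0, z1 = type2_domain.scaffold_zrange
        frames[:, :, :, z0:z1] = 1.0
        ser = ActivitySeries4D(frames=frames, frame_min=5.0,
                               frame_times_min=np.array([5.0, 10.0]))
        tab = roi_timecourses(ser, type2_domain)
        assert np.allclose(tab["upper"], tab["whole"] / 3, rtol=0.05)
        assert np.allclose(tab[["upper", "middle", "lower"]].sum(axis=1),
                           tab["whole"], rtol=1e-12)

    def test_activity_below_scaffold_lands_in_outflow_roi(self,
                                                          type2_domain):
        frames = np.zeros((1,) + type2_domain.shape)
        z1 = type2_domain.scaffold_zrange[1]
        lab = type2_domain.labels
        sel = np.zeros_like(lab, dtype=bool)
        sel[:, :, z1:] = lab[:, :, z1:] > 0
        frames[0][sel] = 1.0
        ser = ActivitySeries4D(frames=frames, frame_min=5.0,
                               frame_times_min=np.array([5.0]))
        tab = roi_timecourses(ser, type2_domain)
        assert tab["whole"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert tab["outflow"].iloc[0] > 0

    def test_thirds_sum_within_psf_tolerance(self, seeding_run,
                                             type2_domain):
        ser = synthesize_pet(seeding_run, type2_domain, psf_mm=1.2,
                             noise="none")
        tab = roi_timecourses(ser, type2_domain)
        thirds = tab[["upper", "middle", "lower"]].sum(axis=1)
        assert (np.abs(thirds / tab["whole"] - 1) < 0.02).all()

    def test_unidirectional_upper_curve_dominates_at_60min(self,
                                                           seeding_run,
                                                           type2_domain):
        ser = synthesize_pet(seeding_run, type2_domain, noise="none")
        tab = roi_timecourses(ser, type2_domain)
        k = np.argmin(np.abs(tab.index.to_numpy() - 60.0))
        assert tab["upper"].iloc[k] >= tab["lower"].iloc[k]

    def test_grid_mismatch_rejected(self, type2_domain):
        ser = static_series()
        with pytest.raises(ValueError):
            roi_timecourses(ser, type2_domain)


class TestEnrichmentTimecourse:
    def test_activity_nondecreasing_during_seeding(self, seeding_run,
                                                   type2_domain):
        ser = synthesize_pet(seeding_run, type2_domain, noise="none")
        tc = enrichment_and_hoover_timecourse(ser, type2_domain)
        seeding_part = tc[tc.index <= 60.0]["activity_MBq"].to_numpy()
        assert (np.diff(seeding_part) > -1e-9).all()

    def test_constant_uniform_frames_have_zero_hoover(self, type2_domain):
        frames = np.zeros((2,) + type2_domain.shape)
        frames[:, type2_domain.scaffold_mask(homogenized=True)] = 1.0
        ser = ActivitySeries4D(frames=frames, frame_min=5.0,
                               frame_times_min=np.array([5.0, 10.0]))
        tc = enrichment_and_hoover_timecourse(ser, type2_domain)
        assert np.allclose(tc["axial_hoover"], 0.0, atol=1e-12)
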