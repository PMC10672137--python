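"""Hard-threshold shrinkage, Wiener filtering, aggregation and stage runs."""

import dataclasses

import numpy as np
import pytest

from bm4dpar import (
    Accumulators,
    CubeCoord,
    FilteredGroup,
    Group,
    StageParams,
    Transform4D,
    Volume,
    accumulate_group,
    filter_group_ht,
    filter_group_wiener,
    finalize_estimate,
    forward_4d,
    hard_threshold_coeffs,
    inverse_4d,
    run_bm4d,
    run_stage,
    wiener_gains,
)

T4 = Transform4D()


def make_group(cubes, coords=None):
    cubes = np.asarray(cubes, dtype=float)
    if coords is None:
        coords = [CubeCoord(i, 0, 0) for i in range(cubes.shape[0])]
    return Group(cubes=cubes, coords=coords, reference=coords[0])


class TestHardThreshold:
    def test_table_threshold_example(self):
        coeffs = np.array([4.0, 1.0, -3.0, 0.5])
        out, n = hard_threshold_coeffs(coeffs, lambda4d=2.8, sigma=1.0)
        np.testing.assert_array_equal(out, [4.0, 0.0, -3.0, 0.0])
        assert n == 2

    def test_zero_lambda_is_noop(self, rng):
        coeffs = rng.standard_normal((2, 2, 2, 2))
        out, n = hard_threshold_coeffs(coeffs, lambda4d=0.0, sigma=0.3)
        np.testing.assert_array_equal(out, coeffs)
        assert n == np.count_nonzero(coeffs)

    def test_only_dc_survives_heavy_threshold(self):
        coeffs = np.full((2, 2, 2, 2), 0.1)
        coeffs[0, 0, 0, 0] = 5.0
        out, n = hard_threshold_coeffs(coeffs, lambda4d=2.8, sigma=1.0)
        assert n == 1
        assert out[0, 0, 0, 0] == 5.0
        assert np.count_nonzero(out) == 1

    def test_dc_retained_even_below_threshold(self):
        coeffs = np.zeros((2, 2, 2, 2))
        coeffs[0, 0, 0, 0] = 0.01
        out, n = hard_threshold_coeffs(coeffs, lambda4d=2.8, sigma=1.0)
        assert out[0, 0, 0, 0] == 0.01
        assert n == 1


class TestFilterGroupHT:
    PARAMS = StageParams(L=2, M=32, Nstep=3, NS=11, tau_match=24.6,
                         lambda4d=2.8)

    def test_constant_group_unchanged_with_dc_weight(self):
        group = make_group(np.full((2, 2, 2, 2), 0.6))
        fg = filter_group_ht(group, sigma=0.2, params=self.PARAMS,
                             transforms=T4)
        np.testing.assert_allclose(fg.cubes, 0.6, atol=1e-12)
        assert fg.weight == pytest.approx(1.0 / 0.2 ** 2)  # n_retained = 1

    def test_zero_lambda_round_trips(self, rng):
        params = dataclasses.replace(self.PARAMS, lambda4d=0.0)
        group = make_group(rng.uniform(0, 1, (4, 2, 2, 2)))
        fg = filter_group_ht(group, sigma=0.2, params=params, transforms=T4)
        np.testing.assert_allclose(fg.cubes, group.cubes, atol=1e-10)

    def test_subthreshold_perturbation_snaps_to_constant(self, rng):
        # perturbation built in coefficient space with all non-DC below
        # lambda * sigma, so thresholding must recover the exact constant
        sigma, lam = 0.1, 2.8
        coeffs = rng.uniform(-0.3, 0.3, (2, 2, 2, 2)) * lam * sigma
        coeffs[0, 0, 0, 0] = 0.0
        group = make_group(0.5 + inverse_4d(coeffs))
        fg = filter_group_ht(group, sigma=sigma, params=self.PARAMS,
                             transforms=T4)
        np.testing.assert_allclose(fg.cubes, 0.5, atol=1e-10)

    def test_sigma_zero_weight_finite(self):
        group = make_group(np.full((2, 2, 2, 2), 0.5))
        fg = filter_group_ht(group, sigma=0.0, params=self.PARAMS,
                             transforms=T4)
        assert np.isfinite(fg.weight) and fg.weight > 0


class TestWiener:
    def test_gain_limits(self):
        e = np.array([0.0, 1.0, 2.0])
        np.testing.assert_array_equal(wiener_gains(e, sigma=0.0), 1.0)
        assert wiener_gains(np.array([0.0]), sigma=0.5)[0] == 0.0
        assert wiener_gains(np.array([0.3]), sigma=0.3)[0] == \
            pytest.approx(0.5)

    def test_sigma_zero_passes_noisy_group_through(self, rng):
        noisy = make_group(rng.uniform(0, 1, (2, 2, 2, 2)))
        est = make_group(rng.uniform(0, 1, (2, 2, 2, 2)), noisy.coords)
        fg = filter_group_wiener(noisy, est, sigma=0.0, transforms=T4)
        np.testing.assert_allclose(fg.cubes, noisy.cubes, atol=1e-10)

    def test_zero_estimate_kills_output(self, rng):
        noisy = make_group(rng.uniform(0, 1, (2, 2, 2, 2)))
        est = make_group(np.zeros((2, 2, 2, 2)), noisy.coords)
        fg = filter_group_wiener(noisy, est, sigma=0.3, transforms=T4)
        np.testing.assert_allclose(fg.cubes, 0.0, atol=1e-12)

    def test_single_coefficient_halved_when_estimate_equals_sigma(self):
        # group whose 4D spectrum has one nonzero coefficient: E = sigma
        # gives gain 1/2, so the noisy coefficient c comes back as c/2
        sigma, c = 0.25, 0.8
        e_coeffs = np.zeros((2, 2, 2, 2))
        e_coeffs[0, 1, 0, 1] = sigma
        n_coeffs = np.zeros((2, 2, 2, 2))
        n_coeffs[0, 1, 0, 1] = c
        noisy = make_group(inverse_4d(n_coeffs))
        est = make_group(inverse_4d(e_coeffs), noisy.coords)
        fg = filter_group_wiener(noisy, est, sigma=sigma, transforms=T4)
        out_coeffs = forward_4d(fg.cubes)
        assert out_coeffs[0, 1, 0, 1] == pytest.approx(c / 2)
        assert fg.weight == pytest.approx(1.0 / (sigma ** 2 * 0.25))

    def test_coordinate_mismatch_rejected(self, rng):
        noisy = make_group(rng.uniform(0, 1, (2, 2, 2, 2)))
        est = make_group(rng.uniform(0, 1, (2, 2, 2, 2)),
                         [CubeCoord(9, 9, 9), CubeCoord(0, 0, 0)])
        with pytest.raises(ValueError, match="coordinate"):
            filter_group_wiener(noisy, est, sigma=0.3, transforms=T4)


class TestAggregation:
    def test_single_cube_finalizes_to_its_values(self, rng):
        acc = Accumulators.zeros((8, 8, 8))
        cube = rng.uniform(0, 1, (1, 2, 2, 2))
        fg = FilteredGroup(cubes=cube, coords=[CubeCoord(2, 2, 2)],
                           weight=0.7)
        accumulate_group(acc, fg)
        fallback = Volume(np.full((8, 8, 8), -1.0))
        est, n_fallback = finalize_estimate(acc, fallback)
        np.testing.assert_allclose(est.data[2:4, 2:4, 2:4], cube[0],
                                   atol=1e-12)
        assert est.data[0, 0, 0] == -1.0
        assert n_fallback == 8 ** 3 - 2 ** 3

    def test_equal_weight_overlap_averages(self):
        acc = Accumulators.zeros((8, 8, 8))
        for value, origin in ((0.0, CubeCoord(0, 0, 0)),
                              (1.0, CubeCoord(1, 0, 0))):
            accumulate_group(acc, FilteredGroup(
                cubes=np.full((1, 2, 2, 2), value), coords=[origin],
                weight=0.3))
        est, _ = finalize_estimate(acc, Volume(np.zeros((8, 8, 8))))
        np.testing.assert_allclose(est.data[1, 0:2, 0:2], 0.5, atol=1e-12)

    def test_zero_or_negative_weight_forbidden(self):
        with pytest.raises(ValueError, match="weight"):
            FilteredGroup(cubes=np.zeros((1, 2, 2, 2)),
                          coords=[CubeCoord(0, 0, 0)], weight=0.0)

    def test_empty_accumulators_fall_back_everywhere(self, random_volume):
        acc = Accumulators.zeros(random_volume.dims)
        est, n_fallback = finalize_estimate(acc, random_volume)
        np.testing.assert_array_equal(est.data, random_volume.data)
        assert n_fallback == random_volume.data.size

    def test_default_profile_covers_every_voxel(self, profile, rng):
        vol = Volume(rng.uniform(0, 1, (16, 16, 16)))
        from bm4dpar.collaborative_filter import (StageContext,
                                                  _default_schedule_refs)
        ctx = StageContext(volume=vol, matching_volume=vol, sigma=0.1,
                           params=profile.ht, mode="ht",
                           estimate_volume=None, transforms=T4)
        acc = Accumulators.zeros(vol.dims)
        for ref in _default_schedule_refs(vol.dims, profile.ht):
            ctx.process_reference(acc, ref)
        assert np.all(acc.denominator > 0)


class TestStageRuns:
    def test_constant_volume_fixed_point_of_ht_stage(self, profile):
        vol = Volume(np.full((16, 16, 16), 0.42))
        out = run_stage(vol, vol, 0.2, profile.ht, "ht")
        np.testing.assert_allclose(out.data, 0.42, atol=1e-10)

    def test_wiener_mode_requires_estimate(self, profile, random_volume):
        with pytest.raises(ValueError, match="estimate"):
            run_stage(random_volume, random_volume, 0.1, profile.wie,
                      "wiener")

    def test_output_within_noise_envelope(self, profile, noisy32):
        out = run_bm4d(noisy32, 0.1, profile)
        lo, hi = noisy32.data.min(), noisy32.data.max()
        assert out.data.min() >= lo - 0.3 and out.data.max() <= hi + 0.3

    def test_two_stage_run_returns_pilot_and_refined(self, profile,
                                                     phantom32, noisy32):
        from bm4dpar import evaluate
        final, pilot = run_bm4d(noisy32, 0.1, profile,
                                return_intermediate=True)
        clean = phantom32.volume
        psnr = {name: evaluate(clean, v).psnr_db
                for name, v in (("noisy", noisy32), ("pilot", pilot),
                                ("final", final))}
        assert psnr["pilot"] > psnr["noisy"]
        assert psnr["final"] >= psnr["pilot"]
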