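import numpy as np
import pytest

from sraiflux import (
    EmptyFieldError,
    IndexConfig,
    calibrate_threshold,
    index_sweep,
    probe_mask,
    quantify_field,
    ratio_map,
    tolles_ypet_index,
)
from sraiflux.flux_index import DEFAULT_THRESHOLDS, RatioMap
from sraiflux.synthetic import SimParams, generate_field

from conftest import make_prepared


def ratio_map_from_values(values, valid=None, r_cap=10.0):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, bool)
    return RatioMap(
        ratio=np.where(valid, values, -1.0),
        valid=valid,
        params={"epsilon": 1.0, "r_cap": r_cap, "b_T": 0.0, "b_Y": 0.0},
    )


def naive_index(rmap, t):
    """Per-pixel loop oracle for Index(t)."""
    above = total = 0
    h, w = rmap.ratio.shape
    for i in range(h):
        for j in range(w):
            if rmap.valid[i, j]:
                total += 1
                if rmap.ratio[i, j] > t:
                    above += 1
    return above / total


class TestProbeMask:
    def _noise_field(self, rng, shape=(96, 96), bg=100.0, sigma=5.0):
        return rng.normal(bg, sigma, shape)

    def test_all_background_field_flags_rejection(self, rng):
        prepared = make_prepared(
            self._noise_field(rng), self._noise_field(rng),
            background_stable=100.0, background_labile=100.0,
        )
        mask = probe_mask(prepared, IndexConfig(min_obj_px=9))
        assert not mask.any()
        assert prepared.rejected

    def test_bright_block_in_stable_channel_only_is_segmented(self, rng):
        stable = self._noise_field(rng)
        sigma = 5.0
        stable[30:50, 40:60] += 10 * sigma  # one 20x20 block at 10 sigma
        prepared = make_prepared(
            stable, self._noise_field(rng),
            background_stable=100.0, background_labile=100.0,
        )
        mask = probe_mask(prepared)
        block = np.zeros_like(mask)
        block[30:50, 40:60] = True
        # essentially the planted 400-px block, allowing noise at the rim
        assert mask[block].mean() > 0.95
        assert mask[~block].sum() <= 5

    def test_union_includes_labile_only_signal(self, rng):
        stable = self._noise_field(rng)
        labile = self._noise_field(rng)
        stable[10:30, 10:30] += 80
        labile[60:80, 60:80] += 80  # bright in labile only
        prepared = make_prepared(
            stable, labile, background_stable=100.0, background_labile=100.0
        )
        mask = probe_mask(prepared)
        assert mask[15:25, 15:25].all()
        assert mask[65:75, 65:75].all()

    def test_small_objects_removed(self, rng):
        stable = self._noise_field(rng)
        stable[5, 5] += 500  # isolated hot pixel, below min_obj_px
        prepared = make_prepared(
            stable, self._noise_field(rng),
            background_stable=100.0, background_labile=100.0,
        )
        mask = probe_mask(prepared, IndexConfig(min_obj_px=9))
        assert not mask[5, 5]

    def test_saturated_pixels_excluded(self, rng):
        stable = self._noise_field(rng)
        stable[20:40, 20:40] += 200
        sat = np.zeros(stable.shape, bool)
        sat[25, 25] = True
        prepared = make_prepared(
            stable, self._noise_field(rng),
            background_stable=100.0, background_labile=100.0, saturation=sat,
        )
        assert not probe_mask(prepared)[25, 25]


class TestRatioMap:
    def test_plain_arithmetic(self):
        prepared = make_prepared([[130.0]], [[115.0]], 100.0, 100.0)
        rmap = ratio_map(prepared, np.ones((1, 1), bool))
        assert rmap.ratio[0, 0] == pytest.approx(2.0)

    def test_quenched_pixel_rails_at_cap(self):
        # acceptor at/below background: denominator floored at epsilon
        prepared = make_prepared([[150.0]], [[95.0]], 100.0, 100.0)
        rmap = ratio_map(prepared, np.ones((1, 1), bool), epsilon=1.0, r_cap=10.0)
        assert rmap.ratio[0, 0] == 10.0

    def test_donor_below_background_clamps_to_zero(self):
        prepared = make_prepared([[90.0]], [[200.0]], 100.0, 100.0)
        rmap = ratio_map(prepared, np.ones((1, 1), bool))
        assert rmap.ratio[0, 0] == 0.0

    def test_invalid_pixels_carry_negative_sentinel(self):
        prepared = make_prepared(np.full((2, 2), 200.0), np.full((2, 2), 150.0), 100.0, 100.0)
        mask = np.array([[True, False], [True, True]])
        rmap = ratio_map(prepared, mask)
        assert rmap.ratio[0, 1] < 0
        assert rmap.valid.sum() == 3

    def test_parameter_guards(self):
        prepared = make_prepared([[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            ratio_map(prepared, np.ones((1, 1), bool), epsilon=0.0)


class TestIndex:
    def test_uniform_ratio_straddles_thresholds(self):
        rmap = ratio_map_from_values(np.full((4, 4), 2.0))
        assert tolles_ypet_index(rmap, 1.5) == 1.0
        assert tolles_ypet_index(rmap, 2.5) == 0.0
        # strict inequality: ties count only in the denominator
        assert tolles_ypet_index(rmap, 2.0) == 0.0

    def test_enumerated_ten_pixel_map(self):
        values = np.array([[3.0] * 3 + [0.8] * 7])
        rmap = ratio_map_from_values(values)
        assert tolles_ypet_index(rmap, 1.0) == pytest.approx(0.3)

    def test_index_at_cap_is_zero(self):
        rmap = ratio_map_from_values(np.full((3, 3), 10.0), r_cap=10.0)
        assert tolles_ypet_index(rmap, 10.0) == 0.0

    def test_no_valid_pixels_is_an_explicit_error(self):
        rmap = ratio_map_from_values(np.ones((2, 2)), valid=np.zeros((2, 2), bool))
        with pytest.raises(EmptyFieldError):
            tolles_ypet_index(rmap, 1.0)


class TestIndexSweep:
    def test_default_sweep_has_eight_thresholds(self, rng):
        rmap = ratio_map_from_values(rng.uniform(0, 5, (32, 32)))
        res = index_sweep(rmap)
        assert res.thresholds == DEFAULT_THRESHOLDS
        assert len(res.index) == 8

    def test_single_threshold_equals_pointwise_index(self, rng):
        rmap = ratio_map_from_values(rng.uniform(0, 5, (16, 16)))
        res = index_sweep(rmap, [1.5])
        assert res.index[0] == tolles_ypet_index(rmap, 1.5)

    def test_sweep_matches_naive_loop_on_synthetic_fields(self):
        for seed in range(3):
            stack, _ = generate_field(SimParams(shape=(64, 64), n_cells=3, seed=seed))
            _, rmap, res = quantify_field(stack)
            for t, v in zip(res.thresholds, res.index):
                assert v == naive_index(rmap, t)

    def test_monotone_non_increasing_in_threshold(self, rng):
        for _ in range(20):
            rmap = ratio_map_from_values(rng.uniform(0, 9.5, (24, 24)))
            res = index_sweep(rmap)
            assert all(b <= a for a, b in zip(res.index, res.index[1:]))

    def test_unsorted_thresholds_rejected(self, rng):
        rmap = ratio_map_from_values(rng.uniform(0, 5, (8, 8)))
        with pytest.raises(ValueError, match="ascending"):
            index_sweep(rmap, [2.0, 1.0])

    def test_threshold_at_or_above_cap_rejected(self, rng):
        rmap = ratio_map_from_values(rng.uniform(0, 5, (8, 8)), r_cap=10.0)
        with pytest.raises(ValueError, match="r_cap"):
            index_sweep(rmap, [1.0, 10.0])

    def test_invariant_under_common_gain(self, rng):
        """Multiplying both background-subtracted channels by one constant
        leaves every Index(t) unchanged."""
        base_s = rng.uniform(0, 300, (32, 32))
        base_y = rng.uniform(0, 300, (32, 32))
        mask = (base_s > 50) | (base_y > 50)
        for gain in (0.5, 3.0):
            p1 = make_prepared(100 + base_s, 100 + base_y, 100.0, 100.0)
            p2 = make_prepared(100 + gain * base_s, 100 + gain * base_y, 100.0, 100.0)
            r1 = index_sweep(ratio_map(p1, mask, epsilon=1e-9), DEFAULT_THRESHOLDS)
            r2 = index_sweep(ratio_map(p2, mask, epsilon=1e-9), DEFAULT_THRESHOLDS)
            assert r1.index == r2.index

    def test_small_noise_barely_moves_index(self):
        """i.i.d. noise below 2% of foreground leaves Index within 0.01 at
        calibrated thresholds (away from the neutral-ratio shoulder)."""
        stack, _ = generate_field(SimParams(seed=11, read_sigma=0.0))
        _, rmap0, res0 = quantify_field(stack)
        rng = np.random.default_rng(0)
        noisy = stack.pixels.astype(float) + rng.normal(0, 4.0, stack.pixels.shape)
        noisy_stack = type(stack)(
            pixels=np.clip(np.rint(noisy), 0, 4095).astype(np.uint16),
            channel_names=stack.channel_names,
        )
        _, rmap1, res1 = quantify_field(noisy_stack)
        for t in (1.0, 1.5, 2.5):
            assert abs(res1.at(t) - res0.at(t)) < 0.01


class TestQuantifyField:
    def test_rejected_field_yields_nan_row(self):
        stack, _ = generate_field(SimParams(seed=0))
        px = stack.pixels.copy()
        px[:] = 100  # constant -> no signal
        flat = type(stack)(pixels=px, channel_names=stack.channel_names)
        prepared, rmap, res = quantify_field(flat)
        assert prepared.rejected and rmap is None
        assert np.isnan(res.index).all()
        assert res.rejected

    def test_min_area_qc(self):
        stack, _ = generate_field(SimParams(seed=0))
        _, _, res = quantify_field(
            stack, index_config=IndexConfig(min_area_px=10**6)
        )
        assert res.rejected and "min_area" in res.qc["reason"]


class TestCalibrateThreshold:
    def test_picks_threshold_with_clean_negative_control(self):
        pos, neg = [], []
        for seed in range(4):
            s, _ = generate_field(SimParams(quenched_fraction=0.4, seed=100 + seed))
            pos.append(quantify_field(s)[2])
            s, _ = generate_field(SimParams(quenched_fraction=0.0, seed=200 + seed))
            neg.append(quantify_field(s)[2])
        t = calibrate_threshold(pos, neg)
        assert t in DEFAULT_THRESHOLDS
        neg_mean = np.mean([r.at(t) for r in neg])
        assert neg_mean <= 0.02
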