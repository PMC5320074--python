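"""Stripe-map construction, shadow segmentation and column removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octlumen.guidewire import (Interval, build_stripe_map, detect_guidewire,
                                fill_missing_intervals, remove_guidewire,
                                segment_guidewire_map, track_from_mask)


def _frame_with_dark_cols(n_radii, n_angles, dark, level=0.8):
    f = np.full((n_radii, n_angles), level)
    f[:, dark] = 0.0
    return f


class TestStripeMap:
    def test_dark_column_is_row_minimum(self):
        f = _frame_with_dark_cols(20, 36, [5])
        smap = build_stripe_map([f])
        assert smap[0, 5] == 0.0
        assert smap.min() >= 0 and smap.max() <= 1

    def test_constant_frame_degenerates_to_half(self):
        smap = build_stripe_map([np.full((20, 36), 0.3)])
        assert np.allclose(smap[0], 0.5)

    def test_rows_stack_in_pullback_order(self):
        frames = [_frame_with_dark_cols(20, 36, [i]) for i in (3, 7)]
        smap = build_stripe_map(frames)
        assert smap.shape == (2, 36)
        assert smap[0].argmin() == 3 and smap[1].argmin() == 7

    def test_empty_pullback_rejected(self):
        with pytest.raises(ValueError):
            build_stripe_map([])

    @given(scale=st.floats(0.1, 50), offset=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_normalization_affine_invariant(self, scale, offset):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.1, 1.0, (15, 24))
        a = build_stripe_map([f])
        b = build_stripe_map([scale * f + offset])
        assert np.allclose(a, b, atol=1e-9)


class TestSegmentMap:
    def test_bimodal_band_recovered_with_dilation_margin(self):
        smap = np.full((30, 120), 0.9)
        band = np.arange(50, 70)
        smap[:, band] = 0.1
        # exhaustive-search Otsu oracle: with two pure classes any threshold
        # strictly between them is optimal, so the raw mask is exactly the band
        mask = segment_guidewire_map(smap, min_area=5, closing_radius=0,
                                     dilation_radius=0)
        assert np.array_equal(np.nonzero(mask[0])[0], band)
        dil = segment_guidewire_map(smap, min_area=5, closing_radius=0,
                                    dilation_radius=2)
        on = np.nonzero(dil[0])[0]
        assert on.min() == 48 and on.max() == 71

    def test_small_speckle_removed(self):
        smap = np.full((20, 60), 0.9)
        smap[10, 30] = 0.0  # isolated dark pixel, area 1 < min_area
        mask = segment_guidewire_map(smap, min_area=5, closing_radius=0,
                                     dilation_radius=0)
        assert not mask.any()

    def test_closing_bridges_one_frame_interruption(self):
        # morphology oracle on a 10x36 toy map: the dark band vanishes in one
        # frame; closing with radius >= 1 must bridge it along the pullback
        smap = np.full((10, 36), 0.9)
        smap[:, 10:15] = 0.1
        smap[5, :] = 0.9  # interruption
        mask = segment_guidewire_map(smap, min_area=1, closing_radius=1,
                                     dilation_radius=0)
        assert mask[5, 11:14].any()

    def test_periodic_seam_not_split(self):
        smap = np.full((10, 60), 0.9)
        smap[:, [58, 59, 0, 1]] = 0.1
        mask = segment_guidewire_map(smap, min_area=4, closing_radius=1,
                                     dilation_radius=0)
        iv = track_from_mask(mask, 0)
        assert iv.contains(59) and iv.contains(0)

    def test_constant_map_yields_empty_mask(self):
        assert not segment_guidewire_map(np.full((5, 20), 0.5)).any()


class TestTrack:
    def test_wrapped_run(self):
        row = np.zeros(360, dtype=bool)
        row[350:] = True
        row[:10] = True
        iv = track_from_mask(row[None, :], 0)
        assert (iv.start, iv.end, iv.width()) == (350, 9, 20)

    def test_empty_row_absent_and_inherited(self):
        iv = track_from_mask(np.zeros((1, 36), dtype=bool), 0)
        assert iv is None
        filled = fill_missing_intervals([Interval(3, 5, 36), None, None])
        assert filled[1] == Interval(3, 5, 36)
        assert fill_missing_intervals([None, None]) == [None, None]

    def test_widest_run_wins_with_stripe_tiebreak(self):
        row = np.zeros(60, dtype=bool)
        row[5:10] = True   # width 5
        row[30:35] = True  # width 5, darker
        stripe = np.ones(60)
        stripe[30:35] = 0.0
        iv = track_from_mask(row[None, :], 0, stripe_row=stripe)
        assert iv.start == 30

    def test_overwide_run_is_non_detection(self):
        row = np.zeros(100, dtype=bool)
        row[:60] = True
        assert track_from_mask(row[None, :], 0, max_width=25) is None


class TestRemove:
    def test_plain_interval_bookkeeping(self):
        f = np.arange(5 * 360, dtype=float).reshape(5, 360)
        merged = remove_guidewire(f, Interval(100, 119, 360))
        assert merged.pixels.shape == (5, 340)
        assert merged.column_map[0] == 120
        assert np.array_equal(merged.pixels, f[:, merged.column_map])

    def test_wrapped_interval(self):
        f = np.arange(3 * 360, dtype=float).reshape(3, 360)
        merged = remove_guidewire(f, Interval(350, 9, 360))
        assert merged.pixels.shape == (3, 340)
        assert merged.column_map[0] == 10

    def test_remove_then_reinsert_restores_columns(self):
        f = np.random.default_rng(0).uniform(size=(4, 36))
        iv = Interval(30, 3, 36)
        merged = remove_guidewire(f, iv)
        restored = np.full_like(f, np.nan)
        restored[:, merged.column_map] = merged.pixels
        restored[:, iv.columns()] = f[:, iv.columns()]
        assert np.array_equal(restored, f)
        # column_map is a bijection onto the kept columns
        kept = set(range(36)) - set(iv.columns().tolist())
        assert set(merged.column_map.tolist()) == kept

    def test_full_cover_rejected(self):
        with pytest.raises(ValueError):
            remove_guidewire(np.zeros((4, 10)), Interval(0, 9, 10))

    def test_none_interval_passthrough(self):
        f = np.random.default_rng(1).uniform(size=(4, 12))
        merged = remove_guidewire(f, None)
        assert np.array_equal(merged.pixels, f)
        assert np.array_equal(merged.column_map, np.arange(12))


def test_interval_jaccard():
    a = Interval(0, 9, 36)
    assert a.jaccard(Interval(0, 9, 36)) == 1.0
    assert a.jaccard(Interval(5, 14, 36)) == pytest.approx(5 / 15)
    assert a.jaccard(Interval(20, 29, 36)) == 0.0


def test_detect_on_synthetic_pullback():
    rng = np.random.default_rng(2)
    frames = []
    for f in range(12):
        img = rng.uniform(0.5, 1.0, (40, 72))
        start = (10 + f) % 72
        cols = (start + np.arange(6)) % 72
        img[:, cols] *= 0.05
        frames.append(img)
    ivs = detect_guidewire(frames, min_area=10)
    for f, iv in enumerate(ivs):
        truth = Interval((10 + f) % 72, (15 + f) % 72, 72)
        assert iv is not None and iv.jaccard(truth) >= 0.5
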