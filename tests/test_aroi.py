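"""Adaptive-ROI margin, recentering, resizing and propagation logic."""

import math

import numpy as np
import pytest

from noduleseg.aroi import (
    AROIConfig,
    ContractViolation,
    SquareROI,
    compute_margins,
    extract_voi,
    propagate_axial,
    recenter,
    resize,
)
from noduleseg.metrics import dsc
from noduleseg.synthetic import oracle_segmenter
from noduleseg.volume_io import MaskVolume

from conftest import ellipse_stack

EXTENT = (512, 512)


def roi_at(x1, y1, side, z=0):
    return SquareROI(z, x1, x1 + side, y1, y1 + side)


class TestSquareROI:
    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            SquareROI(0, 0, 10, 0, 9)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            SquareROI(0, 5, 5, 5, 5)


class TestComputeMargins:
    def test_bounding_box_margins(self):
        mask = np.zeros((10, 10), np.uint8)
        mask[2:6, 2:6] = 1  # bbox x,y in [2,5] inclusive
        m = compute_margins(mask, roi_at(0, 0, 10))
        assert (m.d_left, m.d_right, m.d_top, m.d_bottom) == (2, 4, 2, 4)

    def test_full_mask_zero_margins(self):
        m = compute_margins(np.ones((7, 7), np.uint8), roi_at(0, 0, 7))
        assert (m.d_left, m.d_right, m.d_top, m.d_bottom) == (0, 0, 0, 0)

    def test_centre_pixel_symmetric(self):
        mask = np.zeros((9, 9), np.uint8)
        mask[4, 4] = 1
        m = compute_margins(mask, roi_at(0, 0, 9))
        assert m.d_left == m.d_right and m.d_top == m.d_bottom

    def test_empty_mask_signals_none(self):
        assert compute_margins(np.zeros((5, 5), np.uint8), roi_at(0, 0, 5)) is None

    def test_wrong_shape_is_contract_violation(self):
        with pytest.raises(ContractViolation):
            compute_margins(np.zeros((4, 5), np.uint8), roi_at(0, 0, 5))


class TestRecenter:
    def test_shift_toward_mask(self):
        from noduleseg.aroi import MaskMargins

        roi = roi_at(100, 100, 10)
        out = recenter(roi, MaskMargins(4, 2, 3, 3), EXTENT)
        assert (out.x1, out.x2) == (101, 111)  # shift_x = +1
        assert (out.y1, out.y2) == (100, 110)

    def test_equal_margins_identity(self):
        from noduleseg.aroi import MaskMargins

        roi = roi_at(50, 60, 11)
        assert recenter(roi, MaskMargins(3, 3, 2, 2), EXTENT) == roi

    def test_concentricity_property(self, rng):
        """After an unclamped recenter, opposing margins differ by <= 1."""
        for _ in range(300):
            side = int(rng.integers(6, 40))
            mask = np.zeros((side, side), np.uint8)
            h = int(rng.integers(1, side))
            w = int(rng.integers(1, side))
            y0 = int(rng.integers(0, side - h + 1))
            x0 = int(rng.integers(0, side - w + 1))
            mask[y0 : y0 + h, x0 : x0 + w] = 1
            roi = roi_at(200, 200, side)
            m = compute_margins(mask, roi)
            out = recenter(roi, m, EXTENT)
            # margins of the same mask (in volume coordinates) w.r.t. the new ROI
            gx0, gx1 = 200 + x0, 200 + x0 + w - 1
            gy0, gy1 = 200 + y0, 200 + y0 + h - 1
            dl, dr = gx0 - out.x1, out.x2 - 1 - gx1
            dt, db = gy0 - out.y1, out.y2 - 1 - gy1
            assert abs(dl - dr) <= 1 and abs(dt - db) <= 1

    def test_clamped_at_boundary_keeps_side(self):
        from noduleseg.aroi import MaskMargins

        roi = roi_at(0, 0, 10)
        out = recenter(roi, MaskMargins(0, 9, 0, 9), (64, 64))  # wants to move to -4
        assert out.side == 10 and out.x1 == 0 and out.y1 == 0


class TestResize:
    CFG = AROIConfig(ratio_threshold=0.6, min_side=1)

    def test_grows_to_required_area(self):
        out = resize(roi_at(100, 100, 10), 80, self.CFG, EXTENT)
        assert out.side == math.ceil(math.sqrt(80 / 0.6))  # = 12

    def test_grow_only_identity_when_ratio_ok(self):
        cfg = AROIConfig(ratio_threshold=0.6, min_side=1, resize_mode="grow_only")
        roi = roi_at(100, 100, 10)
        assert resize(roi, 50, cfg, EXTENT) == roi  # 50/100 <= 0.6

    def test_shrinks_in_always_mode(self):
        out = resize(roi_at(100, 100, 10), 9, self.CFG, EXTENT)
        assert out.side == 4  # ceil(sqrt(15))

    def test_min_side_clamp(self):
        cfg = AROIConfig(ratio_threshold=0.6, min_side=8)
        out = resize(roi_at(100, 100, 10), 9, cfg, EXTENT)
        assert out.side == 8

    def test_ratio_invariant_when_unclamped(self, rng):
        for _ in range(200):
            area = int(rng.integers(1, 2000))
            roi = roi_at(200, 200, int(rng.integers(2, 50)))
            out = resize(roi, area, self.CFG, EXTENT)
            assert area / out.area <= 0.6 + 1e-12

    def test_empty_area_signals_none(self):
        assert resize(roi_at(0, 0, 10), 0, self.CFG, EXTENT) is None


def _hand_simulate(truth, seed_roi, cfg):
    """Independent step-by-step replay of recenter+resize on the ground
    truth, collecting the ROI side sequence per direction."""
    nz, ny, nx = truth.shape
    sides = {}
    for direction in (+1, -1):
        roi = seed_roi
        z = seed_roi.slice_index
        prev = truth[z, roi.y1 : roi.y2, roi.x1 : roi.x2]
        seq = []
        while True:
            m = compute_margins(prev, roi)
            if m is not None:
                roi = recenter(roi, m, (ny, nx))
                r = resize(roi, int(prev.sum()), cfg, (ny, nx))
                if r is not None:
                    roi = r
            z += direction
            if not (0 <= z < nz):
                break
            prev = truth[z, roi.y1 : roi.y2, roi.x1 : roi.x2]
            seq.append((z, roi.side))
            if prev.sum() == 0:
                break
        sides[direction] = seq
    return sides


class TestPropagateAxial:
    def test_oracle_recovers_phantom_slices(self, ellipsoid_phantom):
        vol, truth = ellipsoid_phantom
        from noduleseg.pipeline import seed_roi_from_truth

        seg = oracle_segmenter(truth)
        out = propagate_axial(vol, seed_roi_from_truth(truth), seg, AROIConfig())
        for rec in out.report:
            z = rec["z"]
            if truth.data[z].sum() == 0:
                continue
            r = rec["roi"]
            pred = out.data[z, r["y1"] : r["y2"], r["x1"] : r["x2"]]
            ref = truth.data[z, r["y1"] : r["y2"], r["x1"] : r["x2"]]
            np.testing.assert_array_equal(pred, ref)

    def test_empty_seed_gives_empty_mask(self, ellipsoid_phantom):
        vol, truth = ellipsoid_phantom
        seg = oracle_segmenter(truth)
        out = propagate_axial(vol, SquareROI(0, 0, 12, 0, 12), seg, AROIConfig())
        assert out.data.sum() == 0
        assert len(out.report) == 1  # only the seed slice was visited

    def test_roi_sequence_matches_hand_simulation(self, rng):
        cfg = AROIConfig(ratio_threshold=0.6, min_side=8)
        for _ in range(10):
            vol, truth = ellipse_stack(rng)
            from noduleseg.pipeline import seed_roi_from_truth

            seed = seed_roi_from_truth(truth)
            out = propagate_axial(vol, seed, oracle_segmenter(truth), cfg)
            expected = _hand_simulate(truth.data, seed, cfg)
            got_up = [(r["z"], r["roi"]["side"]) for r in out.report if r["z"] > seed.slice_index]
            got_dn = [(r["z"], r["roi"]["side"]) for r in out.report if r["z"] < seed.slice_index]
            assert got_up == sorted(expected[+1])
            assert got_dn == sorted(expected[-1])

    def test_deterministic(self, ellipsoid_phantom):
        vol, truth = ellipsoid_phantom
        from noduleseg.pipeline import seed_roi_from_truth

        seed = seed_roi_from_truth(truth)
        a = propagate_axial(vol, seed, oracle_segmenter(truth), AROIConfig())
        b = propagate_axial(vol, seed, oracle_segmenter(truth), AROIConfig())
        np.testing.assert_array_equal(a.data, b.data)
        assert a.report == b.report

    def test_whole_nodule_recovery(self, ellipsoid_phantom):
        vol, truth = ellipsoid_phantom
        from noduleseg.pipeline import seed_roi_from_truth

        out = propagate_axial(
            vol, seed_roi_from_truth(truth), oracle_segmenter(truth), AROIConfig()
        )
        assert dsc(out, truth) >= 0.99

    def test_segmenter_bad_shape_rejected(self, ellipsoid_phantom):
        vol, truth = ellipsoid_phantom
        from noduleseg.pipeline import seed_roi_from_truth

        def bad(patch, ref):
            return np.zeros((3, 3), np.uint8)

        with pytest.raises(ContractViolation):
            propagate_axial(vol, seed_roi_from_truth(truth), bad, AROIConfig())


class TestExtractVOI:
    def test_single_voxel_padded(self):
        data = np.zeros((12, 12, 12), np.uint8)
        data[5, 5, 5] = 1
        box = extract_voi(MaskVolume(data, (1, 1, 1)), pad=2)
        assert (box.z1, box.z2, box.y1, box.y2, box.x1, box.x2) == (3, 8, 3, 8, 3, 8)

    def test_full_volume_no_pad(self):
        box = extract_voi(MaskVolume(np.ones((4, 5, 6), np.uint8), (1, 1, 1)), pad=0)
        assert box.shape == (4, 5, 6)

    def test_empty_mask_signals_none(self):
        assert extract_voi(MaskVolume(np.zeros((3, 3, 3), np.uint8), (1, 1, 1))) is None

    def test_contains_all_foreground(self, rng):
        for _ in range(20):
            data = (rng.random((10, 11, 12)) < 0.05).astype(np.uint8)
            if data.sum() == 0:
                continue
            box = extract_voi(MaskVolume(data, (1, 1, 1)), pad=int(rng.integers(0, 3)))
            inside = data[box.z1 : box.z2, box.y1 : box.y2, box.x1 : box.x2]
            assert inside.sum() == data.sum()
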