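"""Puncta detection, unit-intensity calibration and copy decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from puncta import (
    CalibrationError,
    SpotParams,
    SpotRecord,
    calibrate_unit_intensity,
    count_copies,
    detect_spots,
)
from puncta.spots import count_all_copies

from conftest import gaussian_spot_image

PIXEL = 0.2


def _record(integrated, peak, probe="PPIB"):
    return SpotRecord(
        probe=probe,
        centroid_um=(0.0, 0.0),
        area_um2=0.6,
        integrated_intensity=integrated,
        peak_intensity=peak,
    )


def test_blank_channel_yields_no_spots():
    assert detect_spots(np.zeros((64, 64)), PIXEL) == []


def test_non_2d_channel_rejected():
    with pytest.raises(ValueError):
        detect_spots(np.zeros((4, 4, 4)), PIXEL)


def test_single_gaussian_spot_detected_with_area():
    im = gaussian_spot_image(sigma_px=1.5, integrated=1.5, background=0.02)
    spots = detect_spots(im, PIXEL, probe="PPIB")
    assert len(spots) == 1
    s = spots[0]
    assert s.area_um2 >= 0.45
    assert s.centroid_um == pytest.approx((32.5 * PIXEL, 32.5 * PIXEL), abs=PIXEL)
    assert s.integrated_intensity == pytest.approx(1.5, rel=0.1)


def test_spot_below_minimum_signal_area_rejected():
    """A footprint of 0.40 µm² (10 px at 0.2 µm/px) fails the 0.45 µm²
    minimum signal size and is discarded."""
    im = np.zeros((32, 32))
    rr, cc = np.array([10, 10, 10, 11, 11, 11, 12, 12, 12, 13]), np.array(
        [10, 11, 12, 10, 11, 12, 10, 11, 12, 11]
    )
    im[rr, cc] = 0.12
    assert len(rr) * PIXEL**2 == pytest.approx(0.40)
    assert detect_spots(im, PIXEL) == []
    # one more pixel crosses the threshold area and the spot is kept
    im[13, 10] = 0.12
    im[13, 12] = 0.12
    spots = detect_spots(im, PIXEL)
    assert len(spots) == 1 and spots[0].area_um2 >= 0.45


class TestCalibration:
    def test_median_of_isolated_spots(self):
        spots = [_record(v, peak=0.10) for v in (9, 10, 10, 11, 30)]
        assert calibrate_unit_intensity(spots) == 10.0

    def test_all_clusters_is_an_error(self):
        spots = [_record(10, peak=0.5) for _ in range(10)]
        with pytest.raises(CalibrationError, match="unit_intensity manually"):
            calibrate_unit_intensity(spots)

    def test_calibrated_unit_close_to_generator_truth(self, processed_scene):
        cfg = processed_scene[0]
        unit = processed_scene[5]
        assert unit == pytest.approx(cfg.unit_copy_intensity, rel=0.10)


class TestCountCopies:
    def test_low_peak_is_single_copy(self):
        # peak 0.10 <= copy intensity threshold 0.15 → physically separated
        assert count_copies(_record(integrated=5.0, peak=0.10), 1.0) == 1

    def test_cluster_rounds_intensity_ratio(self):
        assert count_copies(_record(integrated=3.4, peak=0.5), 1.0) == 3
        assert count_copies(_record(integrated=3.5, peak=0.5), 1.0) == 4

    def test_dim_cluster_floors_at_one(self):
        assert count_copies(_record(integrated=0.4, peak=0.5), 1.0) == 1

    def test_zero_unit_rejected(self):
        with pytest.raises(ValueError):
            count_copies(_record(1.0, 0.5), 0.0)

    @given(
        st.floats(min_value=0.0, max_value=50.0),
        st.floats(min_value=0.0, max_value=50.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_copies_monotone_in_integrated_intensity(self, a, b):
        lo, hi = sorted((a, b))
        assert count_copies(_record(lo, 0.5), 1.7) <= count_copies(
            _record(hi, 0.5), 1.7
        )


def test_no_retained_spot_below_default_area(processed_scene):
    spots = processed_scene[4]
    assert spots, "expected detected spots on the default field"
    assert min(s.area_um2 for s in spots) >= 0.45


def test_total_recovered_copies_close_to_truth(processed_scene):
    """Total per-probe copies recovered from the image are within 15% of
    the ground-truth total at the default signal-to-background."""
    truth, spots = processed_scene[2], processed_scene[4]
    recovered = sum(s.copies for s in spots)
    expected = truth.total_copies("PPIB")
    assert abs(recovered - expected) <= 0.15 * expected


def test_per_cell_copy_error_small(processed_scene):
    """Mean absolute per-cell copy error <= 1 for cells with <= 10 copies.

    Segmented nucleus ids are matched to ground-truth cells by nearest
    centroid before comparing copy totals.
    """
    truth, nuclei, spots = processed_scene[2], processed_scene[3], processed_scene[4]
    recovered: dict[int, int] = {}
    for s in spots:
        if s.cell_id is not None:
            recovered[s.cell_id] = recovered.get(s.cell_id, 0) + s.copies
    seg_xy = np.array([n.centroid_um for n in nuclei])
    errors = []
    for nuc in truth.nuclei:
        copies = truth.cell_probe_copies.get((nuc.id, "PPIB"), 0)
        if copies > 10:
            continue
        d = np.hypot(seg_xy[:, 0] - nuc.centroid_um[0], seg_xy[:, 1] - nuc.centroid_um[1])
        seg_id = nuclei[int(d.argmin())].id
        errors.append(abs(recovered.get(seg_id, 0) - copies))
    assert errors, "expected some cells with <= 10 true copies"
    assert np.mean(errors) <= 1.0


def test_merged_puncta_preserve_copy_total():
    """Two unit spots rendered close enough to merge are still counted as
    two copies through the cluster-intensity rule."""
    im = gaussian_spot_image(center_px=(32.0, 31.0), background=0.02)
    im += gaussian_spot_image(center_px=(32.0, 33.0))
    spots = detect_spots(im, PIXEL, SpotParams(spot_aggressiveness=0.0))
    unit = 1.5
    count_all_copies(spots, unit)
    assert sum(s.copies for s in spots) == 2
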