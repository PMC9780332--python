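"""Condensate calling: midpoint reference, detection, fractions, sweeps."""

import numpy as np
import pytest

import phasetag as pt
from phasetag.errors import DegenerateCellError, EmptyInputError
from phasetag.micrograph import Micrograph
from phasetag.segment import CellRegion
from conftest import clean_scene_params


def _segmented_clean_scene(**overrides):
    img, gt = pt.generate_scene(clean_scene_params(**overrides))
    return img, gt, pt.segment_cells(img)


def test_midpoint_reference_uniform_cell():
    img, _, regions = _segmented_clean_scene(condensate_fraction=0.0)
    for r in regions:
        assert pt.midpoint_reference(r, img) == 100.0


def test_midpoint_reference_ignores_polar_focus():
    """Cytoplasm 100, polar focus at rho=2: the midpoint still reads 100."""
    img, _, regions = _segmented_clean_scene(partition_ratio=2.0)
    assert regions
    for r in regions:
        assert pt.midpoint_reference(r, img) == 100.0


def test_midpoint_reference_degenerate_axis():
    mask = np.ones((1, 9), dtype=bool)
    cell = CellRegion(
        label=1, mask=mask, bbox=(slice(40, 41), slice(40, 49)),
        centroid=(40.0, 44.0), medial_axis=np.array([[40.0, 44.0]]),
        area_px=9, length_um=0.6, width_um=0.065, circularity=0.5, angularity=0.0,
    )
    img = Micrograph(np.full((96, 96), 50.0))
    with pytest.raises(DegenerateCellError):
        pt.midpoint_reference(cell, img)


def test_midpoint_reference_one_pixel_wide_cell():
    """A width-1 cell: the reference is the median of midpoint-adjacent pixels."""
    arr = np.zeros((64, 64))
    arr[32, 20:45] = np.arange(20, 45, dtype=float)  # 1-px line, ramp values
    mask = np.zeros((1, 25), dtype=bool)
    mask[:] = True
    axis = np.array([[32.0, c] for c in range(20, 45)])
    cell = CellRegion(
        label=1, mask=mask, bbox=(slice(32, 33), slice(20, 45)),
        centroid=(32.0, 32.0), medial_axis=axis,
        area_px=25, length_um=25 * 0.065, width_um=0.065,
        circularity=0.3, angularity=0.0,
    )
    ref = pt.midpoint_reference(cell, Micrograph(arr), disk_radius_px=3)
    # disk of radius 3 on a 1-px line: the 7 pixels centred at column 32
    assert ref == np.median(np.arange(29, 36))


def test_detect_negative_on_uniform_cell():
    img, _, regions = _segmented_clean_scene(condensate_fraction=0.0)
    for r in regions:
        call = pt.detect_condensates(r, img)
        assert not call.has_condensate
        assert call.enrichment_ratio == 1.0
        assert call.foci == []


def test_detect_exact_enrichment_psf_off():
    """rho=2.0 cells, noise and PSF off: enrichment 2.0 +/- 0.05."""
    img, gt, regions = _segmented_clean_scene(partition_ratio=2.0)
    assert len(regions) == len(gt.cells)
    for r in regions:
        call = pt.detect_condensates(r, img)
        assert call.has_condensate
        assert call.enrichment_ratio == pytest.approx(2.0, abs=0.05)


def test_detect_below_threshold_negative():
    img, _, regions = _segmented_clean_scene(partition_ratio=1.15)
    assert regions
    for r in regions:
        assert not pt.detect_condensates(r, img, threshold=1.20).has_condensate


def test_detect_threshold_must_exceed_one():
    img, _, regions = _segmented_clean_scene()
    with pytest.raises(ValueError):
        pt.detect_condensates(regions[0], img, threshold=1.0)


def test_min_focus_px_suppresses_small_foci():
    img, _, regions = _segmented_clean_scene(partition_ratio=2.0)
    r = regions[0]
    call_strict = pt.detect_condensates(r, img, min_focus_px=10_000)
    assert not call_strict.has_condensate


def test_fraction_arithmetic():
    calls = [
        pt.CondensateCall(i, 100.0, [], i < 7, 1.0, 1.2) for i in range(10)
    ]
    fr = pt.fraction_with_condensates(calls)
    assert fr.fraction == pytest.approx(0.7)
    negs = [pt.CondensateCall(i, 100.0, [], False, 1.0, 1.2) for i in range(5)]
    assert pt.fraction_with_condensates(negs).fraction == 0.0
    with pytest.raises(EmptyInputError):
        pt.fraction_with_condensates([])


@pytest.mark.parametrize(
    "fraction,expected", [(0.10, False), (0.11, True), (0.95, True)]
)
def test_classify_strain_cutoff(fraction, expected):
    assert pt.classify_strain(fraction) is expected


def test_sweep_validation():
    img, _, regions = _segmented_clean_scene()
    with pytest.raises(ValueError):
        pt.threshold_sweep(regions, img, [1.5, 1.2])
    with pytest.raises(ValueError):
        pt.threshold_sweep(regions, img, [0.9, 1.2])


def test_sweep_step_at_true_partition_ratio():
    """All cells at rho=1.5: fraction ~1 below 1.5, ~0 above."""
    img, _, regions = _segmented_clean_scene(partition_ratio=1.5)
    sw = pt.threshold_sweep(regions, img, [1.05, 1.45, 1.55, 1.9])
    assert sw.fraction.iloc[0] == 1.0
    assert sw.fraction.iloc[1] == 1.0
    assert sw.fraction.iloc[2] == 0.0
    assert sw.fraction.iloc[3] == 0.0


def test_sweep_mixed_partition_ratios():
    """Equal halves at rho 1.2 and 1.8: fractions 1.0, 0.5, 0.0."""
    img1, _, regs1 = _segmented_clean_scene(partition_ratio=1.2, seed=1, n_cells=10)
    img2, _, regs2 = _segmented_clean_scene(partition_ratio=1.8, seed=2, n_cells=10)
    assert len(regs1) == len(regs2) == 10
    grid = [1.05, 1.5, 1.9]
    f1 = pt.threshold_sweep(regs1, img1, grid).fraction.to_numpy()
    f2 = pt.threshold_sweep(regs2, img2, grid).fraction.to_numpy()
    combined = (f1 + f2) / 2
    assert np.allclose(combined, [1.0, 0.5, 0.0])


def test_sweep_monotone_on_noisy_scene(noisy_scene):
    img, _ = noisy_scene
    sub = pt.rolling_ball_subtract(img, 100)
    regions = pt.segment_cells(sub)
    sw = pt.threshold_sweep(regions, sub)
    assert (np.diff(sw.fraction.to_numpy()) <= 1e-12).all()


def test_calls_invariant_to_global_intensity_scale(noisy_scene):
    """Ratio-based detection: multiplying the image by a scalar changes nothing."""
    img, _ = noisy_scene
    sub = pt.rolling_ball_subtract(img, 100)
    regions = pt.segment_cells(sub)
    scaled = Micrograph(sub.pixels * 2.7, sub.bit_depth, sub.pixel_size)
    for r in regions[:10]:
        a = pt.detect_condensates(r, sub)
        b = pt.detect_condensates(r, scaled)
        assert a.has_condensate == b.has_condensate
        assert a.enrichment_ratio == pytest.approx(b.enrichment_ratio, rel=1e-9)
        assert len(a.foci) == len(b.foci)
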