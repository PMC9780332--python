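"""Background subtraction, Li thresholding, and cell segmentation."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.filters import threshold_li as skimage_li

import phasetag as pt
from phasetag.errors import DegenerateImageError
from phasetag.micrograph import Micrograph
from conftest import clean_scene_params


def brute_force_ball_opening(arr: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a non-flat ball element, by explicit loops."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    fp = xx**2 + yy**2 <= radius**2
    h = np.sqrt(np.clip(radius**2 - (xx**2 + yy**2), 0, None))
    n = arr.shape[0]
    pad = np.pad(arr, radius, mode="edge")
    ero = np.empty_like(arr)
    for i in range(n):
        for j in range(n):
            win = pad[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            ero[i, j] = np.min(win[fp] - h[fp])
    pad_e = np.pad(ero, radius, mode="edge")
    opened = np.empty_like(arr)
    for i in range(n):
        for j in range(n):
            win = pad_e[i : i + 2 * radius + 1, j : j + 2 * radius + 1]
            opened[i, j] = np.max(win[fp] + h[fp])
    return opened


def li_objective(values: np.ndarray, t: float) -> float:
    """Li & Lee cross-entropy objective (up to the constant sum g log g)."""
    lo, hi = values[values < t], values[values >= t]
    if lo.size == 0 or hi.size == 0:
        return np.inf
    t0 = lo.sum() * np.log(lo.mean()) if lo.sum() > 0 else 0.0
    t1 = hi.sum() * np.log(hi.mean()) if hi.sum() > 0 else 0.0
    return -(t0 + t1)


def _micro(arr, **kw):
    kw.setdefault("bit_depth", 16)
    kw.setdefault("pixel_size", 0.065)
    return Micrograph(np.asarray(arr, float), kw["bit_depth"], kw["pixel_size"])


# -- micrograph container --------------------------------------------------


def test_micrograph_validation():
    with pytest.raises(ValueError):
        Micrograph(np.full((8, 8), 1.0))  # too small
    with pytest.raises(ValueError):
        Micrograph(np.full((32, 32), -1.0))
    with pytest.raises(ValueError):
        Micrograph(np.full((32, 32), 1.0), bit_depth=12)


def test_tiff_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    img = _micro(rng.integers(0, 65535, (64, 64)))
    path = tmp_path / "x.tiff"
    img.write_tiff(path)
    back = pt.read_tiff(path, pixel_size=img.pixel_size)
    assert len(back) == 1
    assert np.array_equal(back[0].pixels, img.quantized())
    assert back[0].bit_depth == 16


# -- rolling ball ----------------------------------------------------------


def test_rolling_ball_flat_image_maps_to_zero():
    out = pt.rolling_ball_subtract(_micro(np.full((128, 128), 50.0)), 100)
    assert np.allclose(out.pixels, 0.0, atol=1e-9)


def test_rolling_ball_preserves_small_bright_spot():
    arr = np.full((128, 128), 50.0)
    arr[60:63, 60:63] = 180.0
    out = pt.rolling_ball_subtract(_micro(arr), 100).pixels
    assert out[61, 61] == pytest.approx(130.0, abs=1.0)
    outside = out.copy()
    outside[55:68, 55:68] = 0
    assert outside.max() < 1.0


def test_rolling_ball_matches_brute_force_opening():
    rng = np.random.default_rng(1)
    arr = ndimage.gaussian_filter(rng.uniform(0, 255, (64, 64)), 2)
    out = pt.rolling_ball_subtract(_micro(arr), 10, downscale=1).pixels
    expected = np.clip(arr - brute_force_ball_opening(arr, 10), 0, None)
    assert np.allclose(out, expected, atol=1e-9)


def test_rolling_ball_ramp_residual_small():
    """A ball of radius 10 rolls flush under a gentle plane: residual ~0 away
    from the border (within one radius of the edge the ball loses support --
    an artifact shared exactly by the brute-force opening)."""
    col = np.linspace(0, 100, 64)
    ramp = np.tile(col, (64, 1))
    out = pt.rolling_ball_subtract(_micro(ramp), 10, downscale=1).pixels
    assert out[:, :-10].max() < 0.05 * np.ptp(ramp)
    expected = np.clip(ramp - brute_force_ball_opening(ramp, 10), 0, None)
    assert np.allclose(out, expected, atol=1e-9)


def test_rolling_ball_translation_equivariance():
    rng = np.random.default_rng(2)
    patch = rng.uniform(0, 200, (16, 16))
    a = np.full((96, 96), 30.0)
    b = np.full((96, 96), 30.0)
    a[20:36, 20:36] = patch
    b[50:66, 44:60] = patch
    out_a = pt.rolling_ball_subtract(_micro(a), 12, downscale=1).pixels
    out_b = pt.rolling_ball_subtract(_micro(b), 12, downscale=1).pixels
    assert np.allclose(out_a[20:36, 20:36], out_b[50:66, 44:60], atol=1e-9)


def test_rolling_ball_background_monotone():
    """Pointwise larger images have pointwise larger background estimates."""
    rng = np.random.default_rng(3)
    lo = ndimage.gaussian_filter(rng.uniform(0, 200, (64, 64)), 2)
    hi = lo + rng.uniform(0, 50, (64, 64))
    bg_lo = lo - pt.rolling_ball_subtract(_micro(lo), 10, downscale=1).pixels
    bg_hi = hi - pt.rolling_ball_subtract(_micro(hi), 10, downscale=1).pixels
    assert np.all(bg_hi >= bg_lo - 1e-9)


def test_rolling_ball_paraboloid_variant_runs():
    rng = np.random.default_rng(4)
    arr = ndimage.gaussian_filter(rng.uniform(0, 255, (64, 64)), 2)
    out = pt.rolling_ball_subtract(_micro(arr), 10, kernel="paraboloid", downscale=1)
    assert out.pixels.min() >= 0


def test_rolling_ball_radius_validation():
    img = _micro(np.full((64, 64), 1.0))
    with pytest.raises(ValueError):
        pt.rolling_ball_subtract(img, 0)
    with pytest.raises(ValueError):
        pt.rolling_ball_subtract(img, 64)


# -- Li threshold ----------------------------------------------------------


def test_li_separates_two_modes():
    arr = np.full(1024, 10.0)
    arr[:100] = 100.0
    t = pt.li_threshold(arr.reshape(32, 32))
    assert 10 < t < 100


def test_li_constant_image_raises():
    with pytest.raises(DegenerateImageError):
        pt.li_threshold(np.full((32, 32), 5.0))


def test_li_matches_brute_force_argmin():
    """Exact agreement with naive minimization over all candidate splits."""
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = 32 * 32
        f = rng.uniform(0.2, 0.8)
        mu0 = rng.uniform(40, 80)
        mu1 = rng.uniform(mu0 + 30, mu0 + 90)
        img = np.concatenate(
            [rng.normal(mu0, 12, int(n * f)), rng.normal(mu1, 18, n - int(n * f))]
        )
        img = np.clip(np.round(img), 0, 255).reshape(32, 32)
        t_impl = pt.li_threshold(img)
        vals = np.unique(img)
        mids = (vals[:-1] + vals[1:]) / 2
        objs = [li_objective(img.ravel(), t) for t in mids]
        assert abs(t_impl - mids[int(np.argmin(objs))]) <= 1.0


def test_li_consistent_with_skimage_fixed_point():
    rng = np.random.default_rng(9)
    arr = np.clip(ndimage.gaussian_filter(rng.uniform(0, 255, (64, 64)), 1.5), 0, 255)
    assert abs(pt.li_threshold(arr) - skimage_li(arr)) <= 5.0


def test_li_binarization_recovers_true_masks():
    """Noise-free scene: thresholding recovers >=99% of true cell pixels."""
    img, gt = pt.generate_scene(clean_scene_params(n_cells=20, image_shape=(512, 512)))
    binary = img.pixels > pt.li_threshold(img)
    truth = gt.labels > 0
    assert (binary & truth).sum() / truth.sum() >= 0.99


# -- segmentation ----------------------------------------------------------


def test_segment_exact_recovery_noise_free():
    """20 clean cells: all found, centroids within 1 px of ground truth."""
    img, gt = pt.generate_scene(clean_scene_params(
        n_cells=20, image_shape=(512, 512), condensate_fraction=0.0,
    ))
    regions = pt.segment_cells(img)
    assert len(regions) == 20
    truth_centroids = {c.label: c.centroid for c in gt.cells}
    for r in regions:
        lbl = gt.labels[int(round(r.centroid[0])), int(round(r.centroid[1]))]
        tr, tc = truth_centroids[lbl]
        assert np.hypot(r.centroid[0] - tr, r.centroid[1] - tc) <= 1.0


def test_shape_descriptors_match_rendered_geometry():
    """Length within 2 px and width within 1 px of the true spherocylinder."""
    img, gt = pt.generate_scene(clean_scene_params(
        n_cells=20, image_shape=(512, 512), condensate_fraction=0.0, seed=11,
    ))
    regions = pt.segment_cells(img)
    assert len(regions) == 20
    for r in regions:
        truth = gt.cells[gt.labels[int(round(r.centroid[0])), int(round(r.centroid[1]))] - 1]
        assert abs(r.length_um - truth.length_um) / img.pixel_size <= 2.0
        assert abs(r.width_um - truth.width_um) / img.pixel_size <= 1.0
        assert r.length_um >= r.width_um
        assert r.angularity <= 0.35


def test_round_debris_blob_rejected():
    arr = np.zeros((64, 64))
    yy, xx = np.mgrid[:64, :64]
    arr[(yy - 32) ** 2 + (xx - 32) ** 2 <= 12**2] = 200.0
    assert pt.segment_cells(_micro(arr)) == []


def test_blank_image_gives_empty_list():
    assert pt.segment_cells(_micro(np.zeros((64, 64)))) == []


def test_border_touching_component_discarded():
    arr = np.zeros((96, 96))
    arr[0:14, 30:70] = 200.0  # rod touching the top border
    arr[50:64, 30:70] = 200.0  # same rod shape, interior
    regions = pt.segment_cells(_micro(arr))
    assert len(regions) == 1
    assert 45 < regions[0].centroid[0] < 70


def test_segmentation_recall_precision_default_noise():
    """Cell-level recall and precision >= 0.95 (IoU > 0.5) on noisy scenes."""
    matched = 0
    n_truth = 0
    n_regions = 0
    for seed in (0, 1):
        params = pt.SceneParams(image_shape=(512, 512), n_cells=40, seed=seed)
        img, gt = pt.generate_scene(params)
        sub = pt.rolling_ball_subtract(img, 100)
        regions = pt.segment_cells(sub)
        n_truth += len(gt.cells)
        n_regions += len(regions)
        for r in regions:
            gmask = r.global_mask(img.shape)
            labels, counts = np.unique(gt.labels[gmask], return_counts=True)
            best = labels[np.argmax(counts)] if labels.size else 0
            if best == 0:
                continue
            tmask = gt.labels == best
            iou = (gmask & tmask).sum() / (gmask | tmask).sum()
            if iou > 0.5:
                matched += 1
    assert matched / n_truth >= 0.95  # recall
    assert matched / n_regions >= 0.95  # precision


def test_medial_axis_endpoints_inside_mask(noisy_scene):
    img, _ = noisy_scene
    sub = pt.rolling_ball_subtract(img, 100)
    regions = pt.segment_cells(sub)
    assert regions
    for r in regions:
        for pt_ in (r.medial_axis[0], r.medial_axis[-1]):
            i, j = int(round(pt_[0])), int(round(pt_[1]))
            assert r.mask[i - r.bbox[0].start, j - r.bbox[1].start]


def test_shape_constraint_validation():
    with pytest.raises(ValueError):
        pt.ShapeConstraints(area_px=(100.0, 100.0))
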