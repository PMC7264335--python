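"""Segmentation operators against naive oracles and forced constructions."""

import numpy as np
import pytest
from skimage import measure

import fluorequant as fq
from fluorequant.io import ChannelStack
from fluorequant.segmentation import (
    SegmentationParams,
    despeckle,
    label_components,
    li_threshold,
    project_max,
    relabel_raster_order,
    segment_cells,
    size_filter,
    subtract_channel,
)

from conftest import (
    flood_fill_components,
    greedy_centroid_match,
    li_exhaustive,
    median3x3_naive,
)


# -- project_max -----------------------------------------------------------

def test_project_max_single_plane_identity(default_field):
    stack, _, _ = default_field
    assert np.array_equal(project_max(stack, "nuclear"), stack.pixels[0, 0])


def test_project_max_two_plane_example():
    planes = np.array([[[0, 5], [3, 1]], [[2, 2], [2, 2]]], dtype=np.uint16)
    stack = ChannelStack(planes[:, None], {"sensor": 0})
    assert np.array_equal(project_max(stack, "sensor"), [[2, 5], [3, 2]])


def test_project_max_equals_per_pixel_loop_oracle():
    rng = np.random.default_rng(0)
    planes = rng.integers(0, 1000, (3, 1, 8, 9)).astype(np.uint16)
    stack = ChannelStack(planes, {"sensor": 0})
    result = project_max(stack, "sensor")
    for r in range(8):
        for c in range(9):
            assert result[r, c] == max(planes[z, 0, r, c] for z in range(3))


def test_project_max_unknown_role():
    stack = ChannelStack(np.zeros((1, 4, 4), dtype=np.uint16), {"sensor": 0})
    with pytest.raises(fq.ConfigurationError):
        project_max(stack, "nuclear")


# -- subtract_channel ------------------------------------------------------

def test_subtract_clips_at_zero_without_wraparound():
    a = np.array([[5, 200]], dtype=np.uint16)
    b = np.array([[7, 50]], dtype=np.uint16)
    out = subtract_channel(a, b)
    assert out.tolist() == [[0, 150]]
    assert out.dtype == np.uint16


def test_subtract_shape_mismatch():
    with pytest.raises(fq.ParameterError):
        subtract_channel(np.zeros((2, 2)), np.zeros((3, 2)))


# -- li_threshold ----------------------------------------------------------

def test_li_two_level_image_separates_exactly():
    """60% of pixels at 50, 40% at 200: the threshold must fall in [50, 200)
    so that strict > binarization splits the populations exactly."""
    img = np.concatenate([np.full(60, 50), np.full(40, 200)]).astype(np.uint8)
    img = img.reshape(10, 10)
    t = li_threshold(img)
    assert 50 <= t < 200
    assert np.array_equal(img > t, img == 200)


def test_li_constant_image_is_degenerate():
    with pytest.raises(fq.DegenerateInputError):
        li_threshold(np.full((5, 5), 7, dtype=np.uint8))


@pytest.mark.parametrize("seed", range(8))
def test_li_matches_exhaustive_oracle_random(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    assert li_threshold(img) == li_exhaustive(img)


def test_li_matches_oracle_on_bimodal_with_zeros():
    """Zero-valued bins follow the g*log(g) -> 0 convention; the vectorized
    path must agree with the naive oracle in their presence."""
    rng = np.random.default_rng(9)
    img = np.where(
        rng.random((24, 24)) < 0.5,
        rng.integers(0, 30, (24, 24)),
        rng.integers(150, 255, (24, 24)),
    ).astype(np.uint8)
    assert li_threshold(img) == li_exhaustive(img)


def test_li_sixteen_bit_support():
    rng = np.random.default_rng(3)
    img = rng.integers(0, 4000, (32, 32)).astype(np.uint16)
    assert li_threshold(img) == li_exhaustive(img)


# -- despeckle -------------------------------------------------------------

def test_despeckle_removes_isolated_pixel():
    img = np.zeros((7, 7), dtype=np.uint8)
    img[3, 3] = 1
    assert despeckle(img, 1).sum() == 0


def test_despeckle_identity_cases():
    img = np.full((5, 5), 9, dtype=np.uint8)
    assert np.array_equal(despeckle(img, 3), img)
    rng = np.random.default_rng(1)
    noisy = rng.integers(0, 2, (9, 9)).astype(np.uint8)
    assert despeckle(noisy, 0) is noisy


@pytest.mark.parametrize("seed,binary", [(0, True), (1, True), (2, False), (3, False)])
def test_despeckle_four_rounds_equals_naive_oracle(seed, binary):
    rng = np.random.default_rng(seed)
    if binary:
        img = (rng.random((20, 20)) < 0.4).astype(np.uint8)
    else:
        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
    expected = img
    for _ in range(4):
        expected = median3x3_naive(expected)
    assert np.array_equal(despeckle(img, 4), expected)


def test_despeckle_never_invents_values():
    rng = np.random.default_rng(5)
    img = rng.choice([0, 10, 200], size=(15, 15)).astype(np.uint8)
    out = despeckle(img, 2)
    assert set(np.unique(out)) <= set(np.unique(img))


# -- size_filter / relabel -------------------------------------------------

def _labels_with_areas(areas):
    """Horizontal 2-px-tall bars of the requested pixel areas, separated."""
    width = max((a + 1) // 2 for a in areas)
    img = np.zeros((4 * len(areas), width + 2), dtype=np.int32)
    for i, area in enumerate(areas):
        r = 4 * i
        full, extra = divmod(area, 2)
        img[r, 1 : 1 + full] = i + 1
        img[r + 1, 1 : 1 + full] = i + 1
        if extra:
            img[r, 1 + full] = i + 1
    return img


def test_size_filter_bounds_are_inclusive():
    """Areas {19, 20, 150, 151} with the 20-150 px nucleus range: exactly the
    boundary-hitting 20 and 150 px objects survive."""
    labels = _labels_with_areas([19, 20, 150, 151])
    out = size_filter(labels, 20, 150)
    survivors = sorted(np.bincount(out.ravel())[1:])
    assert survivors == [20, 150]
    assert out.max() == 2  # dense relabel


def test_size_filter_empty_and_passthrough():
    empty = np.zeros((5, 5), dtype=np.int32)
    assert np.array_equal(size_filter(empty, 1, 10), empty)
    labels = _labels_with_areas([10, 12])
    out = size_filter(labels, 5, 20)
    assert sorted(np.unique(out)) == [0, 1, 2]
    assert np.array_equal(out > 0, labels > 0)


def test_size_filter_min_above_max():
    with pytest.raises(fq.ParameterError):
        size_filter(np.zeros((3, 3), dtype=int), 10, 5)


def test_relabel_is_raster_order_stable():
    labels = np.array([[0, 7, 0], [3, 0, 7], [3, 0, 0]])
    out = relabel_raster_order(labels)
    # label 7 appears first in raster order -> becomes 1
    assert out[0, 1] == 1 and out[1, 0] == 2


# -- connectivity ----------------------------------------------------------

@pytest.mark.parametrize("connectivity", [4, 8])
def test_components_match_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(2)
    binary = (rng.random((25, 25)) < 0.35).astype(np.uint8)
    labels = label_components(binary, connectivity)
    assert labels.max() == flood_fill_components(binary, connectivity)


def test_diagonal_blobs_split_under_4_connectivity():
    binary = np.zeros((6, 6), dtype=np.uint8)
    binary[1, 1] = binary[2, 2] = binary[3, 3] = 1
    assert label_components(binary, 8).max() == 1
    assert label_components(binary, 4).max() == 3
    assert label_components(binary, 4).max() == flood_fill_components(binary, 4)


# -- segment_cells chain ---------------------------------------------------

def test_segment_recovers_noise_free_field_exactly(noise_free_field, well_seg_params):
    """Object count equals ground truth and every centroid matches a distinct
    true centroid within 2 px under greedy matching."""
    stack, _, gt = noise_free_field
    labels = segment_cells(stack, "nuclear", well_seg_params)
    assert labels.max() == len(gt)
    props = measure.regionprops(labels)
    recovered = np.array([p.centroid for p in props])
    truth = gt[["row", "col"]].to_numpy()
    assert greedy_centroid_match(recovered, truth, max_dist=2.0) == len(gt)


def test_segment_size_filter_forces_object_selection(well_seg_params):
    """One 10 px and one ~60 px object with bounds [20, 150]: exactly the
    large object is returned."""
    img = np.full((40, 40), 10, dtype=np.uint16)
    img[2:4, 2:7] = 500          # 10 px
    img[15:23, 15:23] = 500      # 64 px
    stack = ChannelStack(img, {"nuclear": 0})
    params = SegmentationParams(
        despeckle_rounds=0, min_area_px=20, max_area_px=150
    )
    labels = segment_cells(stack, "nuclear", params)
    assert labels.max() == 1
    assert np.bincount(labels.ravel())[1] == 64


def test_segment_constant_channel_is_degenerate(well_seg_params):
    stack = ChannelStack(np.full((1, 64, 64), 5, dtype=np.uint16), {"nuclear": 0})
    with pytest.raises(fq.DegenerateInputError):
        segment_cells(stack, "nuclear", well_seg_params)


def test_segment_is_deterministic(default_field, well_seg_params):
    stack, _, _ = default_field
    a = segment_cells(stack, "nuclear", well_seg_params)
    b = segment_cells(stack, "nuclear", well_seg_params)
    assert np.array_equal(a, b)


def test_border_policy_drop_removes_border_objects():
    img = np.full((30, 30), 10, dtype=np.uint16)
    img[0:6, 0:6] = 500       # touches border
    img[12:18, 12:18] = 500   # interior
    stack = ChannelStack(img, {"nuclear": 0})
    keep = segment_cells(
        stack, "nuclear", SegmentationParams(despeckle_rounds=0, min_area_px=1,
                                             max_area_px=100, border_policy="keep")
    )
    drop = segment_cells(
        stack, "nuclear", SegmentationParams(despeckle_rounds=0, min_area_px=1,
                                             max_area_px=100, border_policy="drop")
    )
    assert keep.max() == 2 and drop.max() == 1
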