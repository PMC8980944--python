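"""Crop/resize/normalize/split/cache contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokeseg.preprocessing import (ATLAS_CROP, PreprocessConfig, cache_slices,
                                     crop_slice, extract_slices,
                                     load_cached_slices, normalize_volume,
                                     preprocess_subject, resize_bilinear,
                                     resize_nearest, split_subjects)
from strokeseg.synthetic import SubjectVolume


def test_crop_full_scale_slice_gives_180_square():
    out = crop_slice(np.zeros((233, 197)), *ATLAS_CROP)
    assert out.shape == (180, 180)
    # the box must actually lie inside the 233 x 197 slice
    (r0, c0), (r1, c1) = ATLAS_CROP
    assert r1 <= 233 and c1 <= 197


def test_crop_identity():
    x = np.arange(12.0).reshape(3, 4)
    assert np.array_equal(crop_slice(x, (0, 0), (3, 4)), x)


def test_crop_interior_block_by_hand_indexing():
    x = np.arange(16.0).reshape(4, 4)
    out = crop_slice(x, (1, 1), (3, 3))
    assert np.array_equal(out, np.array([[5.0, 6.0], [9.0, 10.0]]))


def test_crop_out_of_bounds_names_axis():
    with pytest.raises(ValueError, match="row"):
        crop_slice(np.zeros((5, 5)), (0, 0), (6, 5))
    with pytest.raises(ValueError, match="column"):
        crop_slice(np.zeros((5, 5)), (0, 0), (5, 6))


def test_resize_shapes_and_constant_preservation():
    assert resize_bilinear(np.zeros((180, 180)), (192, 192)).shape == (192, 192)
    const = resize_bilinear(np.full((7, 9), 0.42), (13, 4))
    assert np.allclose(const, 0.42, atol=1e-6)


def test_resize_upsample_rows_monotone_matches_bilinear_weights():
    x = np.array([[0.0, 1.0], [0.0, 1.0]])
    out = resize_bilinear(x, (4, 4))
    assert (np.diff(out, axis=1) >= -1e-7).all()
    # closed-form: half-pixel-center bilinear weights along one row
    src = np.clip((np.arange(4) + 0.5) * 2 / 4 - 0.5, 0, 1)
    expected_row = (1 - src) * 0.0 + src * 1.0
    assert np.allclose(out[0], expected_row, atol=1e-6)


def test_mask_resize_preserves_binariness():
    mask = np.zeros((10, 10), dtype=np.uint8)
    mask[3:7, 3:7] = 1
    out = resize_nearest(mask, (17, 23))
    assert set(np.unique(out)) <= {0, 1}


def test_normalize_examples():
    v = np.array([[[0.0, 50.0, 100.0]]])
    assert np.allclose(normalize_volume(v), [[[0.0, 0.5, 1.0]]])
    assert normalize_volume(np.full((2, 2, 2), 7.0)).sum() == 0.0
    with pytest.raises(ValueError):
        normalize_volume(np.array([[[np.nan]]]))


def _subject(n_slices=4, h=40, w=40):
    rng = np.random.default_rng(0)
    img = rng.random((n_slices, h, w)).astype(np.float32)
    msk = (rng.random((n_slices, h, w)) > 0.9).astype(np.uint8)
    return SubjectVolume("sub-x", img, msk)


def test_extract_slices_count_and_order():
    cfg = PreprocessConfig(crop=None, target=(32, 32))
    subject = _subject(n_slices=5)
    samples = extract_slices(subject, cfg)
    assert len(samples) == 5
    assert [s.slice_index for s in samples] == list(range(5))
    assert all(s.image.shape == (32, 32) for s in samples)
    assert all(set(np.unique(s.mask)) <= {0, 1} for s in samples)


def test_extract_single_slice_volume():
    cfg = PreprocessConfig(crop=None, target=(32, 32))
    assert len(extract_slices(_subject(n_slices=1), cfg)) == 1


def test_full_scale_pipeline_output_is_192():
    rng = np.random.default_rng(1)
    subject = SubjectVolume(
        "sub-y", rng.random((2, 233, 197)).astype(np.float32),
        np.zeros((2, 233, 197), dtype=np.uint8))
    samples = extract_slices(subject, PreprocessConfig())
    assert all(s.image.shape == (192, 192) for s in samples)


def test_preprocess_subject_round_trips_slice_order():
    cfg = PreprocessConfig(crop=None, target=(40, 40))
    subject = _subject()
    img, msk = preprocess_subject(subject, cfg)
    assert img.shape == subject.image.shape
    # target equals native size and no crop: the pipeline is lossless
    # apart from normalization
    assert np.array_equal(msk, subject.mask)


def test_split_fullscale_sizes_partition():
    ids = [f"s{i:03d}" for i in range(229)]
    split = split_subjects(ids, (137, 36, 56), seed=0)
    assert len(split.train_ids) == 137
    assert len(split.val_ids) == 36
    assert len(split.test_ids) == 56
    assert split.all_ids == set(ids)


def test_split_degenerate_all_train():
    ids = list("abcd")
    split = split_subjects(ids, (4, 0, 0), seed=1)
    assert set(split.train_ids) == set(ids)


def test_split_deterministic_and_size_checked():
    ids = [f"s{i}" for i in range(10)]
    a = split_subjects(ids, (6, 2, 2), seed=42)
    b = split_subjects(ids, (6, 2, 2), seed=42)
    assert a == b
    with pytest.raises(ValueError, match="sum"):
        split_subjects(ids, (6, 2, 1), seed=0)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.integers(5, 40))
def test_split_is_bijection_for_any_seed(seed, n):
    ids = [f"s{i}" for i in range(n)]
    n_train = n // 2
    n_val = n // 4
    split = split_subjects(ids, (n_train, n_val, n - n_train - n_val), seed)
    assert split.all_ids == set(ids)
    assert len(split.train_ids) + len(split.val_ids) + len(split.test_ids) == n


def test_cache_round_trip(tmp_path):
    cfg = PreprocessConfig(crop=None, target=(32, 32))
    samples = extract_slices(_subject(), cfg)
    cache_slices(samples, tmp_path)
    back = load_cached_slices(tmp_path)
    assert len(back) == len(samples)
    for a, b in zip(samples, back):
        assert a.subject_id == b.subject_id and a.slice_index == b.slice_index
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
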