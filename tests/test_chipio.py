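"""Data model, IO round trips, resizing, normalisation, splits and budgets."""

import math

import imageio.v3 as iio
import numpy as np
import pytest

from phenogan.chipio import (UNLABELED, ChipDataset, ImageChip, SplitSpec,
                             bilinear_resize, load_dataset, normalize_for_gan,
                             denormalize_from_gan, resize_chip, round_half_up,
                             save_dataset, split_dataset, subsample_budget)

from conftest import make_plain_dataset


def test_imagechip_validation():
    with pytest.raises(ValueError, match="3"):
        ImageChip(np.zeros((8, 8, 4), dtype=np.float32))
    with pytest.raises(ValueError, match="square"):
        ImageChip(np.zeros((8, 10, 3), dtype=np.float32))
    with pytest.raises(ValueError, match="range"):
        ImageChip(np.full((8, 8, 3), 2.0, dtype=np.float32))


def test_dataset_rejects_duplicate_ids_and_bad_labels():
    px = np.zeros((8, 8, 3), dtype=np.float32)
    with pytest.raises(ValueError, match="unique"):
        ChipDataset([ImageChip(px)] * 2, [0, 1], ["a", "a"])
    with pytest.raises(ValueError, match="labels"):
        ChipDataset([ImageChip(px)], [3], ["a"])


def test_save_then_load_roundtrips_exactly(small_dataset, tmp_path):
    """The generator quantises to the 8-bit grid, so PNG IO is lossless."""
    save_dataset(small_dataset, tmp_path)
    back = load_dataset(tmp_path)
    assert back.ids == small_dataset.ids
    assert np.array_equal(back.labels, small_dataset.labels)
    for a, b in zip(back.chips, small_dataset.chips):
        assert np.array_equal(a.pixels, b.pixels)


def test_missing_labels_become_unlabeled(small_dataset, tmp_path):
    save_dataset(small_dataset, tmp_path)
    table = (tmp_path / "labels.csv").read_text().splitlines()
    (tmp_path / "labels.csv").write_text("\n".join(table[:-10]) + "\n")
    back = load_dataset(tmp_path)
    assert int(np.sum(back.labels == UNLABELED)) == 10


def test_grayscale_image_rejected(tmp_path):
    iio.imwrite(tmp_path / "bad.png", np.zeros((8, 8), dtype=np.uint8))
    with pytest.raises(ValueError, match="3-channel"):
        load_dataset(tmp_path)


def test_resize_identity_and_constant():
    chip = ImageChip(np.full((108, 108, 3), 0.25, dtype=np.float32))
    same = resize_chip(chip, 108)
    assert np.array_equal(same.pixels, chip.pixels)
    down = resize_chip(chip, 72)
    assert down.pixels.shape == (72, 72, 3)
    assert np.allclose(down.pixels, 0.25, atol=1e-6)


def test_resize_matches_loop_bilinear_oracle():
    """Vectorised bilinear equals an explicit per-pixel reference."""
    rng = np.random.default_rng(0)
    img = rng.random((108, 108, 3)).astype(np.float32)
    out = bilinear_resize(img, 72, 72)

    def oracle(img, oh, ow):
        h, w = img.shape[:2]
        res = np.zeros((oh, ow, 3), dtype=np.float64)
        for i in range(oh):
            for j in range(ow):
                sy = (i + 0.5) * h / oh - 0.5
                sx = (j + 0.5) * w / ow - 0.5
                y0 = min(max(int(math.floor(sy)), 0), h - 1)
                x0 = min(max(int(math.floor(sx)), 0), w - 1)
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                fy = min(max(sy - y0, 0.0), 1.0)
                fx = min(max(sx - x0, 0.0), 1.0)
                res[i, j] = ((1 - fy) * ((1 - fx) * img[y0, x0] + fx * img[y0, x1])
                             + fy * ((1 - fx) * img[y1, x0] + fx * img[y1, x1]))
        return res

    ref = oracle(img, 72, 72)
    assert np.abs(out - ref).max() < 1e-5


def test_normalize_endpoints_midpoint_and_roundtrip():
    px = np.zeros((8, 8, 3), dtype=np.float32)
    px[0, 0] = 1.0
    px[0, 1] = 0.5
    chip = ImageChip(px)
    norm = normalize_for_gan(chip)
    assert norm.pixels[1, 1, 0] == -1.0
    assert norm.pixels[0, 0, 0] == 1.0
    assert norm.pixels[0, 1, 0] == 0.0
    assert np.isclose(norm.pixels.mean(), 2 * chip.pixels.mean() - 1)
    back = denormalize_from_gan(norm)
    assert np.allclose(back.pixels, chip.pixels)
    with pytest.raises(ValueError, match="twice"):
        normalize_for_gan(norm)


def test_split_sizes_at_round_numbers():
    tr, va, te = split_dataset(make_plain_dataset(100), SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (64, 16, 20)


def test_split_reproduces_full_scale_pool_size():
    """80% of 3,921 chips is a 3,137-image training pool (round half up)."""
    ds = make_plain_dataset(3921, side=8)
    tr, va, te = split_dataset(ds, SplitSpec(seed=1))
    assert len(tr) + len(va) == 3137
    assert len(te) == 784


def test_split_partition_is_disjoint_exhaustive_and_deterministic():
    ds = make_plain_dataset(101)
    a = split_dataset(ds, SplitSpec(seed=5))
    b = split_dataset(ds, SplitSpec(seed=5))
    ids = [set(p.ids) for p in a]
    assert sum(len(s) for s in ids) == 101
    assert ids[0] | ids[1] | ids[2] == set(ds.ids)
    assert all(x.ids == y.ids for x, y in zip(a, b))


def test_split_rejects_unlabeled_chips():
    ds = make_plain_dataset(20)
    ds.labels[3] = UNLABELED
    with pytest.raises(ValueError, match="label"):
        split_dataset(ds, SplitSpec(seed=0))


@pytest.mark.parametrize("n,fraction,expected", [
    (3137, 0.01, 32),
    (3137, 0.10, 314),
])
def test_budget_sizes_match_full_scale_design(n, fraction, expected):
    labeled, unlabeled = subsample_budget(make_plain_dataset(n), fraction, 0)
    assert len(labeled) == expected
    assert len(labeled) + len(unlabeled) == n
    assert np.all(unlabeled.labels == UNLABELED)


def test_full_budget_reveals_everything():
    ds = make_plain_dataset(50)
    labeled, unlabeled = subsample_budget(ds, 1.0, 0)
    assert len(labeled) == 50 and len(unlabeled) == 0


def test_budget_is_stratified_and_conserves_ids():
    ds = make_plain_dataset(200, positive_fraction=0.5, seed=3)
    labeled, unlabeled = subsample_budget(ds, 0.02, 4)   # 4 labels
    assert len(labeled) == 4
    assert set(labeled.ids) | set(unlabeled.ids) == set(ds.ids)
    assert {0, 1} <= set(labeled.labels.tolist())        # both classes kept


def test_budget_rejects_bad_fractions():
    ds = make_plain_dataset(10)
    for f in (0.0, -0.2, 1.5):
        with pytest.raises(ValueError, match="fraction"):
            subsample_budget(ds, f, 0)


def test_round_half_up():
    assert round_half_up(3136.8) == 3137
    assert round_half_up(2.5) == 3
    assert round_half_up(2.4) == 2
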