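"""Particle extraction and shape measurement against analytic/brute-force oracles."""

import math

import numpy as np
import pytest

import mitomorph as mm


def _square_roi(x0, y0, x1, y1):
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


# ------------------------------------------------------------------ apply_roi

def test_whole_image_roi_is_identity():
    rng = np.random.default_rng(0)
    mask = rng.random((40, 40)) < 0.3
    roi = [_square_roi(-0.5, -0.5, 39.5, 39.5)]
    np.testing.assert_array_equal(mm.apply_roi(mask, roi), mask)


def test_disjoint_roi_empties_mask():
    mask = np.zeros((40, 40), dtype=bool)
    mask[5:15, 5:15] = True
    out = mm.apply_roi(mask, [_square_roi(25, 25, 38, 38)])
    assert not out.any()


def test_roi_clips_half_of_block():
    mask = np.zeros((60, 60), dtype=bool)
    mask[10:50, 10:50] = True  # 40x40 block = 1600 px
    # polygon covering columns 10..29 inclusive (pixel centers, boundary in)
    out = mm.apply_roi(mask, [_square_roi(10, 0, 29, 59)])
    assert out.sum() == 800


def test_empty_roi_set_is_an_error():
    with pytest.raises(ValueError):
        mm.apply_roi(np.ones((8, 8), dtype=bool), [])


# --------------------------------------------------------------- labeling

def test_diagonal_pixels_are_one_particle():
    mask = np.zeros((5, 5), dtype=bool)
    mask[1, 1] = mask[2, 2] = True
    assert mm.label_particles(mask).max() == 1


def test_empty_mask_has_no_particles():
    assert mm.label_particles(np.zeros((5, 5), dtype=bool)).max() == 0


def test_three_disjoint_squares():
    mask = np.zeros((30, 30), dtype=bool)
    for i in range(3):
        mask[2 + 10 * i : 6 + 10 * i, 2:6] = True
    assert mm.label_particles(mask).max() == 3


# ------------------------------------------------------------- size filter

def test_size_filter_bound_is_exclusive():
    # one particle of exactly 600 px, one of 601: only the 601 survives
    mask = np.zeros((80, 80), dtype=bool)
    mask[2:22, 2:32] = True                        # 20x30 = 600 px
    mask[40:60, 2:32] = True
    mask[60, 2] = True                             # 601 px
    labels = mm.label_particles(mask)
    kept = mm.filter_by_size(labels, 600)
    kept_sizes = np.bincount(kept.ravel())[1:]
    kept_sizes = kept_sizes[kept_sizes > 0]
    assert list(kept_sizes) == [601]


def test_size_filter_zero_keeps_all():
    mask = np.zeros((20, 20), dtype=bool)
    mask[1, 1] = True
    mask[5:7, 5:7] = True
    labels = mm.label_particles(mask)
    assert (mm.filter_by_size(labels, 0) == labels).all()


def test_size_filter_counts():
    mask = np.zeros((120, 120), dtype=bool)
    mask[0:10, 0:10] = True            # 100
    mask[20:46, 20:45] = True          # 650
    mask[60:110, 60:120] = True        # 3000
    labels = mm.label_particles(mask)
    kept = mm.filter_by_size(labels, 600)
    assert len(np.unique(kept)) - 1 == 2


# ------------------------------------------------------------ measurement

def test_digital_disk_measures(disk_mask):
    rec = mm.measure_particle(disk_mask)
    assert rec["area"] == pytest.approx(math.pi * 900.0, rel=0.02)
    assert rec["circularity"] >= 0.9
    assert rec["aspect_ratio"] == pytest.approx(1.0, rel=0.05)
    assert rec["feret"] == pytest.approx(60.0, rel=0.02)
    assert rec["roundness"] == pytest.approx(1.0, rel=0.05)


def test_two_pixel_feret_pixel_center_convention():
    pts = np.array([[0, 0], [4, 3]])  # rows/cols: 3-4-5 triangle
    assert mm.feret_diameter(pts) == pytest.approx(5.0)
    assert mm.feret_diameter(np.array([[3, 3]])) == 0.0


def test_form_factor_circularity_identity(random_blobs):
    for m in random_blobs[:20]:
        rec = mm.measure_particle(m)
        uncapped = 4.0 * math.pi * rec["area"] / rec["perimeter"] ** 2
        assert rec["form_factor"] * uncapped == pytest.approx(1.0, abs=1e-12)


def test_feret_equals_bruteforce_on_random_blobs(random_blobs):
    for m in random_blobs:
        coords = np.argwhere(m).astype(float)
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        brute = math.sqrt(d2.max())
        assert mm.measure_particle(m)["feret"] == pytest.approx(brute, abs=1e-9)


def test_translation_invariance(random_blobs):
    m = random_blobs[0]
    big = np.zeros((96, 96), dtype=bool)
    big[10:58, 10:58] = m
    shifted = np.roll(np.roll(big, 17, axis=0), 9, axis=1)
    r1 = mm.measure_particle(big)
    r2 = mm.measure_particle(shifted)
    for k in mm.PARAMETERS:
        assert r1[k] == pytest.approx(r2[k], abs=1e-9)


def test_rotation_90_invariance(disk_mask, random_blobs):
    for m in [disk_mask, *random_blobs[:5]]:
        r1 = mm.measure_particle(m)
        r2 = mm.measure_particle(np.rot90(m))
        for k in ("area", "feret", "aspect_ratio"):
            assert r1[k] == pytest.approx(r2[k], abs=1e-9)
        assert r2["perimeter"] == pytest.approx(r1["perimeter"], rel=0.01)
        assert r2["circularity"] == pytest.approx(r1["circularity"], rel=0.02)


@pytest.mark.parametrize("scale", [1.5, 2.0])
def test_area_scales_quadratically(scale):
    def disk(r):
        n = int(2 * r + 10)
        yy, xx = np.mgrid[0:n, 0:n]
        return (xx - n / 2) ** 2 + (yy - n / 2) ** 2 <= r * r

    r0 = 16.0
    a1 = mm.measure_particle(disk(r0))["area"]
    a2 = mm.measure_particle(disk(r0 * scale))["area"]
    assert a2 / a1 == pytest.approx(scale**2, rel=0.02)


def test_degenerate_line_particle_flagged():
    m = np.zeros((3, 12), dtype=bool)
    m[1, 1:11] = True
    rec = mm.measure_particle(m)
    assert rec["degenerate"] == 1.0
    assert rec["minor"] == 1.0
    assert rec["aspect_ratio"] >= 1.0


def test_holes_kept_unless_filled():
    m = np.zeros((30, 30), dtype=bool)
    m[5:25, 5:25] = True
    m[12:18, 12:18] = False
    assert mm.measure_particle(m)["area"] == 400 - 36
    assert mm.measure_particle(m, fill_holes=True)["area"] == 400


# ----------------------------------------------------------- measure_image

def test_measure_image_on_synthetic_scene():
    rng = np.random.default_rng(8)
    particles = []
    for cx, cy in [(60, 60), (180, 60), (60, 180), (180, 180), (120, 120)]:
        a = rng.uniform(22, 28)
        particles.append(mm.ParticleSpec((cx, cy), a, a * 0.8, rng.uniform(0, np.pi)))
    spec = mm.SceneSpec(particles=tuple(particles), noise_sd=0.0, seed=1)
    img, gt = mm.render_scene(spec)
    res = mm.run_preprocess(img)
    df = mm.measure_image(
        res.mask, mm.scene_roi_polygons(spec), image_id="c", condition="x"
    )
    assert len(df) == 5
    # match measured to planted by centroid and compare areas within 5%
    for _, row in df.iterrows():
        d = np.hypot(gt["x"] - row["centroid_x"], gt["y"] - row["centroid_y"])
        truth = gt.loc[d.idxmin()]
        assert row["area"] == pytest.approx(truth["area"], rel=0.05)


def test_measure_image_filters_small_particle():
    spec = mm.SceneSpec(
        particles=(mm.ParticleSpec((128, 128), 12.0, 12.0),),  # ~452 px < 600
        noise_sd=0.0, seed=1,
    )
    img, _ = mm.render_scene(spec)
    res = mm.run_preprocess(img)
    df = mm.measure_image(res.mask, mm.scene_roi_polygons(spec))
    assert df.empty
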