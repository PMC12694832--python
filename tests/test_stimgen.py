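"""Stimulus generator: textures, figures, glyphs, scenes, region maps."""

import numpy as np
import pytest
from scipy import ndimage

from segnet import stimgen
from segnet.glyphs import synth_glyph
from segnet.stimgen import (FigureSpec, GlyphSpec, PlacementError, TextureSpec,
                            compose_scene, generate_dataset,
                            make_background_texture, region_map, render_glyph,
                            render_texture_figure, sample_scene)


def tex(orientation, **kw):
    return TextureSpec(orientation=orientation, **kw)


# ---------------------------------------------------------------------------
# textures


def fft_orientation(img):
    """Independent estimate of texture orientation from the 2-D spectrum.

    Oriented bars concentrate spectral power along the axis perpendicular
    to their orientation; returns the estimated bar orientation in degrees.
    """
    f = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean()))) ** 2
    h, w = f.shape
    cy, cx = h // 2, w // 2
    f[cy - 2:cy + 3, cx - 2:cx + 3] = 0  # remove DC / low-frequency leakage
    rows, cols = np.indices(f.shape)
    fy, fx = rows - cy, cols - cx
    # power-weighted axial mean of the doubled angle (axial statistics)
    ang = np.arctan2(fy, fx)
    wgt = f.ravel()
    c = np.sum(wgt * np.cos(2 * ang.ravel()))
    s = np.sum(wgt * np.sin(2 * ang.ravel()))
    freq_axis = np.degrees(0.5 * np.arctan2(s, c))
    return (freq_axis + 90.0) % 180.0


def test_zero_contrast_gives_blank_field():
    g = make_background_texture((40, 40), tex(30.0, contrast=0.0), seed=3)
    assert g.shape == (40, 40) and not g.any()


def test_texture_determinism_and_range():
    a = make_background_texture((56, 56), tex(70.0), seed=9)
    b = make_background_texture((56, 56), tex(70.0), seed=9)
    assert np.array_equal(a, b)
    assert a.min() >= 0.0 and a.max() <= 1.0 and a.any()
    c = make_background_texture((56, 56), tex(70.0), seed=10)
    assert not np.array_equal(a, c)


def test_zero_density_is_degenerate():
    with pytest.raises(ValueError):
        make_background_texture((40, 40), tex(0.0, element_density=0.0), seed=0)


@pytest.mark.parametrize("ori", [0.0, 90.0])
def test_fourier_peak_recovers_orientation(ori):
    g = make_background_texture((112, 112), tex(ori, element_density=10.0), seed=4)
    est = fft_orientation(g)
    delta = min(abs(est - ori), 180 - abs(est - ori))
    assert delta < 12.0


def test_orthogonal_textures_have_orthogonal_spectra():
    g0 = make_background_texture((112, 112), tex(0.0, element_density=10.0), seed=4)
    g90 = make_background_texture((112, 112), tex(90.0, element_density=10.0), seed=4)
    d = abs(fft_orientation(g0) - fft_orientation(g90))
    assert abs(min(d, 180 - d) - 90.0) < 15.0


def test_orientation_wraps_mod_180():
    assert TextureSpec(orientation=190.0).orientation == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# texture figures


def point_in_polygon_count(corners, shape):
    """Oracle: count pixels whose integer coordinates fall inside the
    polygon, via shapely."""
    from shapely.geometry import Point, Polygon

    poly = Polygon([(r, c) for r, c in corners])
    n = 0
    rmin, rmax = int(corners[:, 0].min()) - 1, int(corners[:, 0].max()) + 2
    cmin, cmax = int(corners[:, 1].min()) - 1, int(corners[:, 1].max()) + 2
    for r in range(max(rmin, 0), min(rmax, shape[0])):
        for c in range(max(cmin, 0), min(cmax, shape[1])):
            if poly.intersects(Point(r, c)):
                n += 1
    return n


def test_axis_aligned_square_mask_area():
    canvas = np.zeros((56, 56), dtype=np.float32)
    fig = FigureSpec("square", (28.0, 28.0), (10, 10), 0.0, tex(90.0))
    _, mask = render_texture_figure(canvas, fig, seed=0)
    assert mask.sum() == 100


def test_rotated_square_matches_polygon_oracle():
    canvas = np.zeros((56, 56), dtype=np.float32)
    fig = FigureSpec("square", (28.3, 27.6), (12, 12), 45.0, tex(90.0))
    out, mask = render_texture_figure(canvas, fig, seed=1)
    oracle = point_in_polygon_count(fig.corners(), canvas.shape)
    # scanline fill and point-in-polygon may disagree on boundary points
    assert abs(int(mask.sum()) - oracle) <= 8
    assert np.array_equal(out != canvas, (out != canvas) & mask)


def test_square_with_unequal_sides_rejected():
    with pytest.raises(ValueError):
        FigureSpec("square", (28, 28), (10, 14), 0.0, tex(0.0))


def test_figure_outside_canvas_rejected():
    canvas = np.zeros((56, 56), dtype=np.float32)
    fig = FigureSpec("square", (4.0, 4.0), (20, 20), 0.0, tex(90.0))
    with pytest.raises(PlacementError):
        render_texture_figure(canvas, fig, seed=0)


# ---------------------------------------------------------------------------
# glyphs


def test_glyph_centered_within_one_pixel():
    canvas = np.zeros((56, 56), dtype=np.float32)
    g = GlyphSpec(3, (28.0, 28.0), scale=1.0, seed=5)
    _, mask = render_glyph(canvas, g)
    r, c = np.argwhere(mask).mean(axis=0)
    # glyph strokes are roughly but not exactly centered in their bitmap
    assert abs(r - 28) < 3 and abs(c - 28) < 3


def test_glyph_scaling_matches_nearest_neighbour_oracle():
    canvas = np.zeros((80, 80), dtype=np.float32)
    base = GlyphSpec(8, (40.0, 40.0), scale=1.0, seed=2)
    _, m1 = render_glyph(canvas, base)
    _, m2 = render_glyph(canvas, GlyphSpec(8, (40.0, 40.0), scale=2.0, seed=2))
    # oracle: nearest-neighbour upsampling of the unit-scale stroke mask
    nn_count = np.kron(m1, np.ones((2, 2), dtype=bool)).sum()
    assert abs(int(m2.sum()) - int(nn_count)) / nn_count < 0.15
    assert m2.sum() > 3 * m1.sum()


def test_threshold_one_passes_nothing():
    canvas = np.random.default_rng(0).uniform(0, 1, (56, 56)).astype(np.float32)
    out, mask = render_glyph(canvas, GlyphSpec(7, (28.0, 28.0), seed=1),
                             threshold=1.0)
    assert not mask.any() and np.array_equal(out, canvas)


def test_clipped_glyph_rejected():
    canvas = np.zeros((56, 56), dtype=np.float32)
    with pytest.raises(PlacementError):
        render_glyph(canvas, GlyphSpec(0, (2.0, 2.0), scale=1.0))


def test_synth_glyph_contract():
    with pytest.raises(ValueError):
        synth_glyph(10, 0)
    a = synth_glyph(4, 11)
    assert np.array_equal(a, synth_glyph(4, 11))
    rows = np.argwhere(a > 0.3)
    h = rows[:, 0].max() - rows[:, 0].min()
    w = rows[:, 1].max() - rows[:, 1].min()
    one = synth_glyph(1, 3)
    r1 = np.argwhere(one > 0.3)
    assert (r1[:, 0].max() - r1[:, 0].min()) > (r1[:, 1].max() - r1[:, 1].min())


def test_glyph_classes_distinguishable_by_overlap():
    """Mean intra-class stroke overlap exceeds mean inter-class overlap."""
    renders = {k: [synth_glyph(k, s) > 0.3 for s in range(5)] for k in range(10)}

    def overlap(a, b):
        return (a & b).sum() / max((a | b).sum(), 1)

    intra, inter = [], []
    for k in range(10):
        for i in range(5):
            for j in range(i + 1, 5):
                intra.append(overlap(renders[k][i], renders[k][j]))
        for k2 in range(k + 1, 10):
            inter.append(overlap(renders[k][0], renders[k2][0]))
    assert np.mean(intra) > np.mean(inter)


# ---------------------------------------------------------------------------
# scenes


def test_single_square_scene_one_hot():
    fig = FigureSpec("square", (28.0, 28.0), (16, 16), 10.0, tex(120.0))
    s = compose_scene([fig], tex(30.0), seed=0)
    assert s.labels.tolist() == [1] + [0] * 11
    assert s.masks[0].any() and not s.masks[1:].any()


def test_square_and_two_digits_has_three_labels():
    scene = [
        FigureSpec("square", (16.0, 16.0), (14, 14), 0.0, tex(100.0)),
        GlyphSpec(5, (16.0, 42.0), scale=0.8, seed=1),
        GlyphSpec(6, (42.0, 42.0), scale=0.8, seed=2),
    ]
    s = compose_scene(scene, tex(10.0), seed=3)
    assert s.labels.sum() == 3
    assert s.labels[0] == 1 and s.labels[2 + 5] == 1 and s.labels[2 + 6] == 1


def test_identical_centers_rejected():
    scene = [GlyphSpec(5, (28.0, 28.0), seed=1), GlyphSpec(6, (28.0, 28.0), seed=2)]
    with pytest.raises(PlacementError):
        compose_scene(scene, tex(10.0), seed=0)


def test_scene_size_bounds():
    with pytest.raises(ValueError):
        compose_scene([], tex(0.0), seed=0)


# ---------------------------------------------------------------------------
# datasets


def test_single_class_pool():
    stimuli = generate_dataset(10, class_pool=[0], seed=5)
    assert len(stimuli) == 10
    assert all(s.labels[0] == 1 and s.labels.sum() == 1 for s in stimuli)


def test_empty_pool_rejected():
    with pytest.raises(ValueError):
        generate_dataset(5, class_pool=[], seed=0)
    with pytest.raises(ValueError):
        generate_dataset(0, class_pool=[0], seed=0)


def test_dataset_determinism():
    a = generate_dataset(6, seed=21)
    b = generate_dataset(6, seed=21)
    for x, y in zip(a, b):
        assert np.array_equal(x.image, y.image)
        assert np.array_equal(x.masks, y.masks)


def test_class_frequencies_within_binomial_bound():
    """Class draw frequencies stay within 3 SD of the sampling expectation."""
    n = 400
    stimuli = generate_dataset(n, seed=31)
    counts = np.stack([s.labels for s in stimuli]).sum(axis=0)
    # per image: n_obj ~ U{1,2,3}, classes drawn without replacement from 12
    p = 2.0 / 12.0  # E[n_obj]/12
    sd = np.sqrt(n * p * (1 - p))
    assert np.all(np.abs(counts - n * p) < 3 * sd + 1)


def test_label_mask_consistency_and_disjointness():
    for s in generate_dataset(25, seed=41):
        for k in range(12):
            assert bool(s.labels[k]) == bool(s.masks[k].any())
        assert (s.masks.sum(axis=0) <= 1).all()
        assert 1 <= len(s.scene) <= 3


def test_figure_ground_camouflage():
    """Texture figures are orientation-defined, not luminance-defined."""
    diffs = []
    for s in generate_dataset(40, class_pool=[0, 1], seed=51):
        for k in (0, 1):
            if s.labels[k]:
                rm = region_map(s.masks[k], 2,
                                [s.masks[j] for j in s.present_classes() if j != k])
                diffs.append(s.image[rm.pixels(stimgen.FIGURE)].mean()
                             - s.image[rm.pixels(stimgen.GROUND)].mean())
    assert abs(np.mean(diffs)) < 0.05


# ---------------------------------------------------------------------------
# region maps


def brute_force_regions(mask, w):
    """Oracle: per-pixel Chebyshev-neighbourhood scan."""
    h, wd = mask.shape
    dil = np.zeros_like(mask)
    ero = np.ones_like(mask)
    for r in range(h):
        for c in range(wd):
            window = mask[max(r - w, 0):r + w + 1, max(c - w, 0):c + w + 1]
            dil[r, c] = window.any()
            full = (r - w >= 0 and r + w < h and c - w >= 0 and c + w < wd
                    and window.all())
            ero[r, c] = full
    return ero, dil & ~ero, ~dil


def test_region_map_matches_bruteforce():
    mask = np.zeros((30, 30), dtype=bool)
    mask[10:20, 8:18] = True
    rm = region_map(mask, edge_width=1)
    fig_o, edge_o, ground_o = brute_force_regions(mask, 1)
    assert np.array_equal(rm.pixels(stimgen.FIGURE), fig_o)
    assert np.array_equal(rm.pixels(stimgen.EDGE), edge_o)
    assert np.array_equal(rm.pixels(stimgen.GROUND), ground_o)
    assert rm.pixels(stimgen.FIGURE).sum() == 64  # 10x10 eroded by 1 -> 8x8


def test_region_partition_is_exact():
    mask = np.zeros((56, 56), dtype=bool)
    mask[20:35, 25:40] = True
    other = np.zeros_like(mask)
    other[5:10, 5:10] = True
    rm = region_map(mask, edge_width=2, other_masks=[other])
    counts = np.bincount(rm.assignment.ravel(), minlength=4)
    assert counts.sum() == 56 * 56
    assert np.array_equal(rm.pixels(stimgen.EXCLUDED), other)


def test_full_canvas_mask_has_no_ground():
    mask = np.ones((20, 20), dtype=bool)
    rm = region_map(mask, edge_width=1)
    assert not rm.pixels(stimgen.GROUND).any()


def test_region_map_errors():
    with pytest.raises(ValueError):
        region_map(np.zeros((10, 10), dtype=bool), 1)
    m = np.zeros((10, 10), dtype=bool)
    m[4, 4] = True
    with pytest.raises(ValueError):
        region_map(m, 0)


# ---------------------------------------------------------------------------
# on-disk round trip


def test_dataset_round_trip(tmp_path):
    stimuli = generate_dataset(3, class_pool=[0, 1, 5], seed=61)
    stimgen.save_dataset(stimuli, tmp_path)
    loaded = stimgen.load_dataset(tmp_path)
    assert len(loaded) == 3
    for a, b in zip(stimuli, loaded):
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.masks, b.masks)
        assert np.abs(a.image - b.image).max() < 1 / 250  # 8-bit PNG quantization
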