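"""Border statistics: closed-form uniform-image checks, brute-force mask
enumeration, planted-enrichment recovery, and the group t test against the
textbook pooled-variance formula."""

import numpy as np
import pytest
from scipy import stats

from pcpcad.borders import (
    BoundarySet,
    border_accumulation,
    border_complexes,
    border_stats,
    compare_groups,
    make_edge_mask,
)
from pcpcad.synthetic import SyntheticImageSpec, make_cell_image


def hline(shape=(20, 25)):
    return BoundarySet(polylines=[np.array([[5.0, 5.0], [5.0, 14.0]])], image_shape=shape)


def brute_force_mask(boundaries, r):
    """Oracle: a pixel is in the mask iff its centre lies within r + 0.5 of
    any rasterized line pixel (independent enumeration, no morphology)."""
    from pcpcad.borders import rasterize_boundaries

    raster = np.argwhere(rasterize_boundaries(boundaries))
    rows, cols = boundaries.image_shape
    mask = np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            d2 = ((raster - [i, j]) ** 2).sum(axis=1)
            mask[i, j] = (d2 <= (r + 0.5) ** 2).any()
    return mask


def test_dilated_line_mask_pixel_count():
    b = hline()
    mask = make_edge_mask(b, 1).mask
    assert mask.sum() == 36  # 10×3 core + two 3-pixel end caps
    np.testing.assert_array_equal(mask, brute_force_mask(b, 1))


@pytest.mark.parametrize("r", [1, 2, 3])
def test_mask_matches_brute_force_enumeration(r):
    b = hline()
    np.testing.assert_array_equal(make_edge_mask(b, r).mask, brute_force_mask(b, r))


def test_mask_grows_monotonically_with_radius():
    b = hline()
    counts = [make_edge_mask(b, r).mask.sum() for r in (1, 2, 3, 4)]
    assert all(b2 > b1 for b1, b2 in zip(counts, counts[1:]))


def test_zero_radius_rejected():
    with pytest.raises(ValueError, match=">= 1"):
        make_edge_mask(hline(), 0)


def test_polyline_validation():
    with pytest.raises(ValueError, match="bounds"):
        BoundarySet(polylines=[np.array([[0.0, 0.0], [50.0, 0.0]])], image_shape=(20, 20))
    with pytest.raises(ValueError, match="2 vertices"):
        BoundarySet(polylines=[np.array([[1.0, 1.0]])], image_shape=(20, 20))


def test_total_length_is_sum_of_segments():
    b = BoundarySet(
        polylines=[np.array([[0.0, 0.0], [0.0, 3.0], [4.0, 3.0]])], image_shape=(10, 10)
    )
    assert b.total_length == pytest.approx(7.0, abs=1e-9)


def test_accumulation_uniform_closed_form():
    b = hline()
    mask = make_edge_mask(b, 1)
    img = np.full(b.image_shape, 2.5)
    L = b.total_length
    assert border_accumulation(img, mask, L) == pytest.approx(
        2.5 * mask.mask.sum() / L, rel=1e-12
    )
    assert border_accumulation(np.zeros(b.image_shape), mask, L) == 0.0


def test_accumulation_linear_in_intensity(rng):
    b = hline()
    mask = make_edge_mask(b, 2)
    img = rng.uniform(0, 10, b.image_shape)
    L = b.total_length
    a1 = border_accumulation(img, mask, L)
    assert border_accumulation(3.0 * img, mask, L) == pytest.approx(3 * a1, rel=1e-12)


def test_complexes_uniform_closed_form():
    b = hline()
    mask = make_edge_mask(b, 1)
    L = b.total_length
    c = 3.0
    img = np.full(b.image_shape, c)
    # blurring a constant image is the identity, so the product is c²
    got = border_complexes(img, img, 2.0, mask, L)
    assert got == pytest.approx(c**2 * mask.mask.sum() / L, rel=1e-9)
    assert border_complexes(img, np.zeros_like(img), 2.0, mask, L) == 0.0


def test_complexes_bilinear(rng):
    b = hline()
    mask = make_edge_mask(b, 1)
    L = b.total_length
    A = rng.uniform(0, 5, b.image_shape)
    B = rng.uniform(0, 5, b.image_shape)
    base = border_complexes(A, B, 1.5, mask, L)
    assert border_complexes(2 * A, 3 * B, 1.5, mask, L) == pytest.approx(6 * base, rel=1e-10)


def test_shape_mismatch_rejected():
    b = hline()
    mask = make_edge_mask(b, 1)
    with pytest.raises(ValueError, match="shape"):
        border_accumulation(np.zeros((5, 5)), mask, b.total_length)
    with pytest.raises(ValueError, match="shape"):
        border_complexes(np.zeros(b.image_shape), np.zeros((5, 5)), 1.0, mask, 9.0)


def test_statistics_invariant_under_polyline_reordering(cell_image):
    (channels, boundaries, _), _ = cell_image
    reordered = BoundarySet(polylines=list(reversed(boundaries.polylines)),
                            image_shape=boundaries.image_shape)
    s1 = border_stats(channels, boundaries)
    s2 = border_stats(channels, reordered)
    assert s1.accumulation_per_channel == pytest.approx(s2.accumulation_per_channel)
    assert s1.complexes == pytest.approx(s2.complexes)


def test_planted_enrichment_recovered(cell_image):
    """Accumulation ratio of an enriched vs a flat channel recovers the
    planted factor (f = 5) within 5%."""
    (channels, boundaries, truth), spec = cell_image
    flat_spec = SyntheticImageSpec(
        border_enrichment_factor=(1.0, 1.0), noise_sd=0.0, seed=spec.seed
    )
    flat, _, _ = make_cell_image(flat_spec)
    mask = make_edge_mask(boundaries, 3)
    L = boundaries.total_length
    ratio = border_accumulation(channels[0], mask, L) / border_accumulation(
        flat[0], mask, L
    )
    assert ratio == pytest.approx(truth["enrichment_factors"][0], rel=0.05)


def test_coincident_enrichment_scores_above_disjoint():
    """Same total signal per channel, but only co-localized borders light
    up the complex statistic."""
    shape = (40, 40)
    b1 = np.array([[10.0, 5.0], [10.0, 34.0]])
    b2 = np.array([[30.0, 5.0], [30.0, 34.0]])
    both = BoundarySet(polylines=[b1, b2], image_shape=shape)
    mask = make_edge_mask(both, 2)
    L = both.total_length

    def stripe(center_row):
        img = np.zeros(shape)
        img[center_row - 2 : center_row + 3, 5:35] = 10.0
        return img

    coincident = border_complexes(stripe(10), stripe(10), 1.0, mask, L)
    disjoint = border_complexes(stripe(10), stripe(30), 1.0, mask, L)
    assert coincident > disjoint


def test_compare_groups_identical_distributions():
    res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t_statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(0.5)


def test_compare_groups_matches_textbook_formula():
    a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    res = compare_groups(a, b, alternative="less")
    # pooled-variance oracle computed from first principles
    na, nb = 3, 3
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t_exp = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p_exp = stats.t.cdf(t_exp, na + nb - 2)
    assert res.t_statistic == pytest.approx(t_exp, abs=1e-12)
    assert res.p_value == pytest.approx(p_exp, abs=1e-12)
    assert res.df == na + nb - 2


def test_compare_groups_study_sample_sizes(rng):
    wt = rng.normal(10, 1, 12)
    mut = rng.normal(9, 1, 10)
    res = compare_groups(wt, mut, alternative="greater")
    assert res.df == 20
    assert res.sem_A == pytest.approx(stats.sem(wt))


def test_compare_groups_degenerate_flagged():
    res = compare_groups([2.0, 2.0], [2.0, 2.0])
    assert res.degenerate
    with pytest.raises(ValueError, match="at least 2"):
        compare_groups([1.0], [1.0, 2.0])


def test_planted_effect_detected_as_significant():
    """A strong planted enrichment difference must give a significant
    one-sided test at the study's sample sizes."""
    rng = np.random.default_rng(7)
    wt_vals, mut_vals = [], []
    base_spec = SyntheticImageSpec(image_shape=(64, 64), n_cells=4, noise_sd=5.0)
    for i in range(12):
        ch, bset, _ = make_cell_image(
            SyntheticImageSpec(image_shape=(64, 64), n_cells=4, noise_sd=5.0,
                               border_enrichment_factor=(5.0, 5.0), seed=100 + i)
        )
        wt_vals.append(border_stats(ch, bset).accumulation_per_channel[0])
    for i in range(10):
        ch, bset, _ = make_cell_image(
            SyntheticImageSpec(image_shape=(64, 64), n_cells=4, noise_sd=5.0,
                               border_enrichment_factor=(1.0, 1.0), seed=200 + i)
        )
        mut_vals.append(border_stats(ch, bset).accumulation_per_channel[0])
    res = compare_groups(wt_vals, mut_vals, alternative="greater")
    assert res.p_value < 1e-4
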