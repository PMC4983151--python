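import numpy as np
import pytest

from transcallosal import (
    OrientationField,
    SyntheticConfig,
    generate_dataset,
    otsu_threshold,
    track_streamlines,
)
from transcallosal.errors import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
)
from transcallosal.surface_mapping import triangle_median_counts


# ---------------------------------------------------------------------------
# generate_dataset
# ---------------------------------------------------------------------------

def test_seeded_determinism():
    cfg = SyntheticConfig(seed=1, n_streamlines=300,
                          mesh_triangles_per_hemisphere=500)
    a = generate_dataset(cfg)
    b = generate_dataset(cfg)
    assert all(
        (x == y).all()
        for x, y in zip(a.tractogram.streamlines, b.tractogram.streamlines)
    )
    np.testing.assert_array_equal(
        a.ground_truth.cc_segment, b.ground_truth.cc_segment
    )


def test_symmetry_limit_coverage():
    # asymmetry 1, effectively infinite sigma, generous streamline count:
    # the two hemispheres' planted coverages agree within 2 points
    cfg = SyntheticConfig(
        seed=2, n_streamlines=20_000, mesh_triangles_per_hemisphere=2000,
        asymmetry=1.0, parasagittal_sigma=1e9,
    )
    gt = generate_dataset(cfg).ground_truth
    cov = gt.hemisphere_coverage
    assert abs(cov["left"] - cov["right"]) < 0.02


def test_left_greater_than_right_with_asymmetry(small_dataset):
    cov = small_dataset.ground_truth.hemisphere_coverage
    assert cov["left"] > cov["right"]


def test_anterior_network_disrupted_early():
    cfg = SyntheticConfig(
        seed=3, n_streamlines=4000, mesh_triangles_per_hemisphere=1000,
        n_networks=4, network_ap_gradient=[0.1, 0.4, 0.6, 0.9],
    )
    gt = generate_dataset(cfg).ground_truth
    assert gt.disruption[1][0] >= 0.9 * gt.network_involvement[1]


def test_disruption_recomputable_from_streamline_records(small_dataset):
    # [DERIVED] rebuild the planted disruption curve for extent 0.2 from
    # the per-streamline ground-truth records alone
    ds = small_dataset
    gt = ds.ground_truth
    cut = gt.cc_segment <= 1
    n_vertices = ds.surface_left.n_vertices
    tri = ds.surface_left.triangles
    involved = []
    for verts in (gt.left_vertex, gt.right_vertex):
        counts = np.bincount(verts[cut], minlength=n_vertices)
        involved.append(triangle_median_counts(counts, tri) >= 1)
    lab = np.concatenate([ds.labels_left.labels, ds.labels_right.labels])
    inv_mask = np.concatenate(involved)
    for net, curve in gt.disruption.items():
        members = lab == net
        assert curve[0] == pytest.approx(inv_mask[members].mean())


def test_disruption_curves_monotone_and_consistent(small_dataset):
    gt = small_dataset.ground_truth
    for net, curve in gt.disruption.items():
        assert all(b >= a for a, b in zip(curve, curve[1:]))
        assert curve[-1] == pytest.approx(gt.network_involvement[net])


def test_labels_are_contiguous_bands(small_dataset):
    ds = small_dataset
    labels = ds.labels_left.labels
    assert set(labels) == set(range(1, 18))
    centroids = ds.surface_left.vertices[ds.surface_left.triangles].mean(axis=1)
    # band means are ordered anterior -> posterior
    means = [centroids[labels == n, 1].mean() for n in range(1, 18)]
    assert all(a > b for a, b in zip(means, means[1:]))


def test_all_streamlines_cross_the_mask(small_pipeline):
    assert small_pipeline["segments"].n_non_callosal == 0


def test_infeasible_geometry_rejected():
    with pytest.raises(ConfigurationError):
        SyntheticConfig(seed=1, cc_extent=(80.0, 40.0, 10.0))
    with pytest.raises(ConfigurationError):
        SyntheticConfig(seed=1, cc_extent=(10.0, 80.0, 10.0))


def test_bad_gradient_rejected():
    with pytest.raises(ConfigurationError):
        SyntheticConfig(seed=1, n_networks=3, network_ap_gradient=[0.5, 0.5])
    with pytest.raises(ConfigurationError):
        SyntheticConfig(seed=1, n_networks=2, network_ap_gradient=[0.5, 1.5])


def test_odd_triangle_count_rejected():
    with pytest.raises(ConfigurationError):
        SyntheticConfig(seed=1, mesh_triangles_per_hemisphere=501)


# ---------------------------------------------------------------------------
# otsu_threshold
# ---------------------------------------------------------------------------

def test_otsu_perfectly_separated_classes():
    values = np.array([0.0, 0, 0, 10, 10, 10])
    t = otsu_threshold(values, 256)
    assert 0.0 < t < 10.0
    lo, hi = values[values < t], values[values >= t]
    assert lo.var() == 0.0 and hi.var() == 0.0


def _brute_force_otsu(values, n_bins):
    """Exhaustive search over every candidate bin-edge threshold."""
    values = np.asarray(values, dtype=float)
    edges = np.linspace(values.min(), values.max(), n_bins + 1)
    best, best_sigma = None, -np.inf
    for e in edges[1:-1]:
        lo, hi = values[values < e], values[values >= e]
        if not len(lo) or not len(hi):
            continue
        sigma = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if sigma > best_sigma + 1e-12:
            best, best_sigma = e, sigma
    return best


def test_otsu_matches_brute_force_on_mixture():
    rng = np.random.default_rng(21)
    for _ in range(5):
        values = np.concatenate([
            rng.normal(1.0, 0.3, 400), rng.normal(5.0, 0.5, 300)
        ])
        got = otsu_threshold(values, 64)
        expect = _brute_force_otsu(values, 64)
        assert got == pytest.approx(expect, abs=1e-9)


def test_otsu_degenerate_input():
    with pytest.raises(DegenerateInputError):
        otsu_threshold([3.0, 3.0, 3.0])


def test_tracking_threshold_is_fraction_of_otsu():
    # the tracker's anisotropy threshold is conventionally 0.6 x Otsu
    rng = np.random.default_rng(22)
    aniso = np.concatenate([rng.normal(0.1, 0.02, 500),
                            rng.normal(0.7, 0.05, 500)])
    threshold = 0.6 * otsu_threshold(aniso, 256)
    assert 0.0 < threshold < 0.7
    field = _uniform_field(threshold_region=True, low=0.5 * threshold)
    tg = track_streamlines(field, np.array([[0.0, 0, 0]]), step_mm=1.0,
                           min_len_mm=2.0, max_len_mm=300.0,
                           anisotropy_threshold=threshold)
    # low-anisotropy half blocks propagation beyond x = 10
    assert max(sl[:, 0].max() for sl in tg.streamlines) <= 11.0


# ---------------------------------------------------------------------------
# track_streamlines
# ---------------------------------------------------------------------------

def _uniform_field(shape=(41, 11, 11), origin=(-20.0, -5.0, -5.0),
                   threshold_region=False, low=0.0):
    direction = np.zeros(shape + (3,))
    direction[..., 0] = 1.0
    aniso = np.ones(shape)
    if threshold_region:
        aniso[30:] = low  # x >= 10 mm is sub-threshold
    affine = np.eye(4)
    affine[:3, 3] = origin
    return OrientationField(shape, affine, direction, aniso)


def test_uniform_field_straight_polyline():
    tg = track_streamlines(
        _uniform_field(), np.array([[0.0, 0.0, 0.0]]), step_mm=1.0,
        min_len_mm=5.0, max_len_mm=20.0,
    )
    assert tg.n_streamlines == 1
    sl = tg.streamlines[0]
    steps = np.linalg.norm(np.diff(sl, axis=0), axis=1)
    np.testing.assert_allclose(steps, 1.0)
    np.testing.assert_allclose(sl[:, 1:], 0.0, atol=1e-12)
    assert (len(sl) - 1) * 1.0 == 20.0


def test_right_angle_discontinuity_terminates_at_60_degrees():
    shape = (41, 41, 5)
    direction = np.zeros(shape + (3,))
    direction[:20, :, :, 0] = 1.0  # +x for x < ~0
    direction[20:, :, :, 1] = 1.0  # +y beyond
    affine = np.eye(4)
    affine[:3, 3] = [-20.0, -20.0, -2.0]
    field = OrientationField(shape, affine, direction, np.ones(shape))
    tg = track_streamlines(
        field, np.array([[-10.0, 0.0, 0.0]]), step_mm=1.0,
        angular_limit_deg=60.0, min_len_mm=2.0, max_len_mm=300.0,
    )
    sl = tg.streamlines[0]
    # the forward half stops where the 90 degree turn begins
    assert sl[:, 0].max() <= 0.5
    assert (np.abs(sl[:, 1]) < 1e-9).all()


def test_short_streamline_discarded():
    field = _uniform_field(shape=(7, 5, 5), origin=(-3.0, -2.0, -2.0))
    tg = track_streamlines(field, np.array([[0.0, 0.0, 0.0]]), step_mm=1.0,
                           min_len_mm=10.0, max_len_mm=300.0)
    assert tg.n_streamlines == 0


def test_length_window_respected():
    rng = np.random.default_rng(30)
    seeds = rng.uniform(-15, 15, size=(50, 3)) * np.array([1, 0.2, 0.2])
    tg = track_streamlines(_uniform_field(), seeds, step_mm=1.0,
                           min_len_mm=10.0, max_len_mm=30.0)
    for sl in tg.streamlines:
        length = 1.0 * (len(sl) - 1)
        assert 10.0 <= length <= 30.0


def test_fixed_step_contract_on_curved_field():
    # circular field in the xy plane: every consecutive pair must still be
    # exactly step_mm apart
    shape = (41, 41, 3)
    affine = np.eye(4)
    affine[:3, 3] = [-20.0, -20.0, -1.0]
    ii = np.arange(shape[0])[:, None, None] - 20.0
    jj = np.arange(shape[1])[None, :, None] - 20.0
    r = np.sqrt(ii**2 + jj**2) + 1e-9
    direction = np.zeros(shape + (3,))
    direction[..., 0] = (-jj / r) * np.ones(shape)
    direction[..., 1] = (ii / r) * np.ones(shape)
    aniso = np.broadcast_to(r >= 0.5, shape).astype(float)
    field = OrientationField(shape, affine, direction, aniso)
    tg = track_streamlines(field, np.array([[10.0, 0.0, 0.0]]),
                           step_mm=0.5, angular_limit_deg=60.0,
                           min_len_mm=2.0, max_len_mm=40.0)
    assert tg.n_streamlines == 1
    steps = np.linalg.norm(np.diff(tg.streamlines[0], axis=0), axis=1)
    np.testing.assert_allclose(steps, 0.5, rtol=1e-12)


def test_non_positive_step_rejected():
    with pytest.raises(ParameterError):
        track_streamlines(_uniform_field(), np.zeros((1, 3)), step_mm=0.0)


def test_seed_jitter_is_reproducible():
    field = _uniform_field()
    seeds = np.zeros((5, 3))
    a = track_streamlines(field, seeds, step_mm=1.0, min_len_mm=5.0,
                          max_len_mm=20.0, seed=7)
    b = track_streamlines(field, seeds, step_mm=1.0, min_len_mm=5.0,
                          max_len_mm=20.0, seed=7)
    assert a.n_streamlines == b.n_streamlines
    for x, y in zip(a.streamlines, b.streamlines):
        np.testing.assert_array_equal(x, y)


def test_tracked_streamlines_through_slab_hit_mask(small_dataset):
    # a left-right field spanning the CC slab: every kept streamline
    # must intersect the mask
    from transcallosal import segment_cc, streamline_segments

    mask = small_dataset.mask
    shape = (81, 21, 11)
    affine = np.eye(4)
    affine[:3, 3] = [-40.0, -10.0, -5.0]
    direction = np.zeros(shape + (3,))
    direction[..., 0] = 1.0
    field = OrientationField(shape, affine, direction, np.ones(shape))
    rng = np.random.default_rng(31)
    seeds = np.column_stack([
        np.zeros(20), rng.uniform(-9, 9, 20), rng.uniform(-4, 4, 20)
    ])
    tg = track_streamlines(field, seeds, step_mm=0.5, min_len_mm=10.0,
                           max_len_mm=300.0)
    assert tg.n_streamlines > 0
    seg = segment_cc(mask)
    out = streamline_segments(tg, seg, mask)
    assert out.n_non_callosal == 0
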