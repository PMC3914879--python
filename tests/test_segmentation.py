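"""Sequential nine-boundary segmentation and the anchor-correction API."""

import numpy as np
import pytest

from octlayers.errors import DetectionFailureError, InvalidAnchorError
from octlayers.graphsearch import Boundary
from octlayers.phantom import low_contrast_fixture, make_truth, render_bscan
from octlayers.preprocess import DARK_TO_BRIGHT, BScan, CostImage, denoise, directional_gradient
from octlayers.segmentation import (
    BOUNDARY_NAMES,
    SegmentationParams,
    correct_boundary,
    init_ilm,
    init_rpe,
    refine,
    segment_boundaries,
)


def bscan(pixels):
    return BScan(pixels=pixels, axial_um_per_pixel=1.0, lateral_um_per_pixel=1.0)


def mae(bounds, truth):
    return np.abs(bounds.trace_array() - truth.trace_array()).mean(axis=1)


@pytest.fixture(scope="module")
def mini_run(mini_config, mini_geometry):
    """One noise-free mini phantom segmented with derived defaults."""
    truth = make_truth(mini_config, mini_geometry, seed=1)
    img = render_bscan(truth, mini_config, noise=0.0, seed=0)
    params = SegmentationParams.defaults_for(img, mini_config)
    return truth, img, params, segment_boundaries(img, params)


def test_init_ilm_single_impulse():
    px = np.zeros((64, 16))
    px[40, :] = 1.0
    out = init_ilm(bscan(px), peak_threshold=0.3)
    np.testing.assert_array_equal(out.rows, 40)


def test_init_ilm_takes_first_of_two_peaks():
    px = np.zeros((100, 16))
    px[30, :] = 1.0
    px[80, :] = 1.0
    out = init_ilm(bscan(px), peak_threshold=0.3)
    np.testing.assert_array_equal(out.rows, 30)


def test_init_ilm_no_peak_errors():
    px = np.full((32, 16), 0.5)
    with pytest.raises(DetectionFailureError):
        init_ilm(bscan(px), peak_threshold=0.3)


def test_init_ilm_near_truth_on_phantom(mini_run, mini_config):
    """Noise-free phantom: init within the PSF half-width at >= 99% of cols."""
    truth, img, params, _ = mini_run
    den = denoise(img, params.median_window, params.gaussian_sigma_px)
    init = init_ilm(den, params.peak_threshold)
    tol = mini_config.axial_resolution_um / 2 / mini_config.axial_um_per_pixel + 1.0
    frac = np.mean(np.abs(init.rows - truth.boundaries["ILM"]) <= tol)
    assert frac >= 0.99


def test_init_rpe_below_ilm_only():
    px = np.zeros((64, 16))
    px[10, :] = 1.0  # global max above the ILM: must be ignored
    px[50, :] = 0.9
    ilm = Boundary(rows=np.full(16, 20))
    out = init_rpe(bscan(px), ilm, margin_px=2)
    np.testing.assert_array_equal(out.rows, 50)


def test_init_rpe_inside_true_band_on_phantom(mini_run):
    truth, img, params, _ = mini_run
    den = denoise(img, params.median_window, params.gaussian_sigma_px)
    init = init_rpe(den, init_ilm(den, params.peak_threshold), params.rpe_margin_px)
    lo = truth.boundaries["OS/RPE"] - 2
    hi = truth.boundaries["RPE/choroid"] + 2
    assert np.all((init.rows >= lo) & (init.rows <= hi))


def test_init_rpe_empty_range_errors():
    px = np.zeros((32, 16))
    ilm = Boundary(rows=np.full(16, 31))
    with pytest.raises(DetectionFailureError):
        init_rpe(bscan(px), ilm, margin_px=4)


def test_refine_halfwidth_zero_is_identity(rng):
    cost = CostImage(rng.random((32, 10)), DARK_TO_BRIGHT)
    init = Boundary(rows=np.full(10, 15))
    out = refine(init, cost, half_width_px=0, max_jump=1)
    np.testing.assert_array_equal(out.rows, init.rows)


def test_refine_keeps_minimal_init():
    costs = np.ones((32, 10))
    costs[12, :] = 0.0
    init = Boundary(rows=np.full(10, 12))
    out = refine(init, CostImage(costs, DARK_TO_BRIGHT), half_width_px=4, max_jump=1)
    np.testing.assert_array_equal(out.rows, 12)


def test_refine_improves_ilm_over_init(mini_config, mini_geometry):
    """Refinement never degrades the ILM fit across seeded phantoms."""
    worse = 0
    for seed in range(10):
        truth = make_truth(mini_config, mini_geometry, seed=seed)
        img = render_bscan(truth, mini_config, noise=0.1, seed=seed)
        params = SegmentationParams.defaults_for(img, mini_config)
        den = denoise(img, params.median_window, params.gaussian_sigma_px)
        init = init_ilm(den, params.peak_threshold)
        cost = directional_gradient(den, DARK_TO_BRIGHT)
        out = refine(init, cost, params.ilm_half_width_px, params.max_jump, params.step_penalty)
        t = truth.boundaries["ILM"]
        if np.abs(out.rows - t).mean() > np.abs(init.rows - t).mean():
            worse += 1
    assert worse == 0


def test_full_segmentation_recovers_mini_phantom(mini_run, mini_config):
    truth, _, _, bounds = mini_run
    errors = mae(bounds, truth)
    assert errors.max() <= 1.0
    stack = bounds.trace_array()
    assert np.all(np.diff(stack, axis=0) >= 0)
    assert len(bounds.log) == 9


def test_segmentation_deterministic(mini_config, mini_geometry):
    truth = make_truth(mini_config, mini_geometry, seed=2)
    img = render_bscan(truth, mini_config, noise=0.2, seed=7)
    params = SegmentationParams.defaults_for(img, mini_config)
    a = segment_boundaries(img, params)
    b = segment_boundaries(img, params)
    np.testing.assert_array_equal(a.trace_array(), b.trace_array())


def test_ordering_invariant_under_speckle(mini_config, mini_geometry):
    for seed in range(6):
        truth = make_truth(mini_config, mini_geometry, seed=seed)
        img = render_bscan(truth, mini_config, noise=0.25, seed=seed + 50)
        bounds = segment_boundaries(img, SegmentationParams.defaults_for(img, mini_config))
        assert np.all(np.diff(bounds.trace_array(), axis=0) >= 0)


def test_correction_anchor_on_trace_is_noop(mini_run, mini_config):
    truth, img, params, bounds = mini_run
    c = 40
    anchor = (c, int(round(bounds.boundaries["OPL/ONL"][c])))
    fixed = correct_boundary(img, bounds, "OPL/ONL", [anchor], params)
    np.testing.assert_allclose(
        fixed.boundaries["OPL/ONL"], bounds.boundaries["OPL/ONL"], atol=1e-9
    )


def test_correction_full_anchor_polyline(mini_run, mini_config):
    truth, img, params, bounds = mini_run
    rows = np.round(truth.boundaries["OPL/ONL"]).astype(int)
    anchors = [(c, int(rows[c])) for c in range(img.shape[1])]
    fixed = correct_boundary(img, bounds, "OPL/ONL", anchors, params)
    np.testing.assert_array_equal(fixed.boundaries["OPL/ONL"], rows.astype(float))


def test_correction_rejects_bad_anchor(mini_run):
    truth, img, params, bounds = mini_run
    ilm = bounds.boundaries["ILM"]
    with pytest.raises(InvalidAnchorError):
        # row above the enclosing INL/OPL boundary region: use row 0
        correct_boundary(img, bounds, "OPL/ONL", [(10, 0)], params)
    with pytest.raises(InvalidAnchorError):
        correct_boundary(img, bounds, "OPL/ONL", [(5, 50), (3, 50)], params)


def test_correction_does_not_mutate_input(mini_run):
    truth, img, params, bounds = mini_run
    before = bounds.trace_array().copy()
    c = 30
    anchor = (c, int(round(truth.boundaries["OPL/ONL"][c])))
    correct_boundary(img, bounds, "OPL/ONL", [anchor], params)
    np.testing.assert_array_equal(bounds.trace_array(), before)


def test_low_contrast_failure_and_single_anchor_recovery():
    """Signal-dropout region: the tracker locks onto the wrong interface;
    one correct anchor restores sub-pixel regional accuracy."""
    img, truth, (c0, c1) = low_contrast_fixture("uhr")
    from octlayers.instruments import get_config

    params = SegmentationParams.defaults_for(img, get_config("uhr"))
    bounds = segment_boundaries(img, params)
    t = truth.boundaries["OPL/ONL"]
    region = slice(c0, c1)
    before = np.abs(bounds.boundaries["OPL/ONL"][region] - t[region]).mean()
    assert before > 10.0  # genuine failure
    mid = (c0 + c1) // 2
    fixed = correct_boundary(img, bounds, "OPL/ONL", [(mid, int(round(t[mid])))], params)
    after = np.abs(fixed.boundaries["OPL/ONL"][region] - t[region]).mean()
    assert after <= 1.0
    assert np.all(np.diff(fixed.trace_array(), axis=0) >= 0)
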