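"""Bead localization: template extraction, ZNCC matching, sub-pixel
refinement and sequence tracking."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from conftest import BG, FG, BEAD_RADIUS_PX, make_sequence, render_disc_frame
from leaftrack.render import disc_coverage
from leaftrack.tracking import (BoundaryError, ConfigurationError, Frame,
                                FrameSequence, SearchPolicy, SearchRegion,
                                extract_template, match_template,
                                refine_subpixel, track_sequence)

TS = datetime(2014, 4, 22, 10, 0, 0)


def region_at(x, y, hx=45.0, hy=90.0):
    return SearchRegion(center=(x, y), half_extent=(hx, hy))


def brute_force_zncc(image, template):
    """Direct-summation zero-normalized cross-correlation at every offset
    (independent oracle for the FFT-based matcher)."""
    th, tw = template.shape
    H, W = image.shape
    t = template - template.mean()
    tnorm = np.sqrt((t ** 2).sum())
    out = np.full((H - th + 1, W - tw + 1), -1.0)
    for i in range(H - th + 1):
        for j in range(W - tw + 1):
            w = image[i:i + th, j:j + tw]
            wc = w - w.mean()
            denom = tnorm * np.sqrt((wc ** 2).sum())
            out[i, j] = (t * wc).sum() / denom if denom > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# extract_template
# ---------------------------------------------------------------------------

def test_extract_uniform_frame_constant_patch():
    frame = Frame(np.full((60, 60), 0.3), TS)
    tmpl = extract_template(frame, (30, 30), 21)
    assert tmpl.patch.shape == (21, 21)
    assert np.all(tmpl.patch == 0.3)
    assert tmpl.anchor == (10.0, 10.0)


def test_extract_centroid_matches_anchor_for_centered_bead():
    frame = render_disc_frame((80.0, 80.0))
    tmpl = extract_template(frame, (80, 80), 41)
    ys, xs = np.mgrid[0:41, 0:41]
    m = tmpl.patch - BG
    cx = (xs * m).sum() / m.sum()
    cy = (ys * m).sum() / m.sum()
    assert cx == pytest.approx(tmpl.anchor[0], abs=0.05)
    assert cy == pytest.approx(tmpl.anchor[1], abs=0.05)


def test_extract_near_edge_raises_boundary_error():
    frame = render_disc_frame((80.0, 80.0))
    with pytest.raises(BoundaryError):
        extract_template(frame, (5, 80), 41)


def test_extract_requires_odd_size():
    frame = render_disc_frame((80.0, 80.0))
    with pytest.raises(ValueError):
        extract_template(frame, (80, 80), 40)


# ---------------------------------------------------------------------------
# match_template
# ---------------------------------------------------------------------------

def test_self_match_is_exact_with_cc_one():
    rng = np.random.default_rng(3)
    frame = render_disc_frame((80.0, 80.0), noise_sd=0.02, rng=rng)
    tmpl = extract_template(frame, (80, 80), 43)
    pos, cc = match_template(frame, tmpl, region_at(80, 80))
    assert cc == pytest.approx(1.0, abs=1e-9)
    assert pos[0] == pytest.approx(80.0, abs=1e-6)
    assert pos[1] == pytest.approx(80.0, abs=1e-6)


@pytest.mark.parametrize("method,tol", [("fourier", 0.02),
                                        ("parabolic", 0.05)])
def test_half_pixel_offset_recovered(method, tol):
    """A disc rendered +0.5 px in x from the template position must be
    localized within the stated sub-pixel tolerance."""
    base = render_disc_frame((80.0, 80.0))
    tmpl = extract_template(base, (80, 80), 43)
    shifted = render_disc_frame((80.5, 80.0))
    pos, cc = match_template(shifted, tmpl, region_at(80, 80), method=method)
    assert pos[0] == pytest.approx(80.5, abs=tol)
    assert pos[1] == pytest.approx(80.0, abs=tol)
    # cc is taken at the integer peak: a half-pixel phase mismatch is the
    # worst case for a fixed template, still well above the loss threshold
    assert cc > 0.95


def test_day_regime_cc_above_095(rng):
    base = render_disc_frame((80.0, 80.0), noise_sd=0.01, rng=rng)
    tmpl = extract_template(base, (80, 80), 43)
    ccs = []
    for _ in range(10):
        frame = render_disc_frame((80.3, 79.6), noise_sd=0.01, rng=rng)
        _, cc = match_template(frame, tmpl, region_at(80, 80))
        ccs.append(cc)
    assert np.mean(ccs) > 0.95


def test_integer_peak_equals_brute_force_oracle(rng):
    """FFT-based ZNCC peak equals direct-summation correlation on a small
    region, at every offset."""
    img = rng.random((48, 48))
    img += disc_coverage((48, 48), (23.4, 25.1), 8.0)
    frame = Frame(img, TS)
    tmpl = extract_template(frame, (23, 25), 17)
    from skimage.feature import match_template as zncc
    cc_fft = zncc(img, tmpl.patch, pad_input=False)
    cc_direct = brute_force_zncc(img, tmpl.patch)
    assert np.abs(cc_fft - cc_direct).max() < 1e-8
    assert np.unravel_index(np.argmax(cc_fft), cc_fft.shape) == \
        np.unravel_index(np.argmax(cc_direct), cc_direct.shape)


def test_shift_equivariance_integer_translation():
    base = render_disc_frame((70.0, 75.0), shape=(200, 200))
    tmpl = extract_template(base, (70, 75), 43)
    shifted = Frame(np.roll(base.pixels, (7, 11), axis=(0, 1)), TS)
    pos0, _ = match_template(base, tmpl, region_at(70, 75))
    pos1, _ = match_template(shifted, tmpl, region_at(81, 82))
    assert pos1[0] - pos0[0] == pytest.approx(11.0, abs=1e-6)
    assert pos1[1] - pos0[1] == pytest.approx(7.0, abs=1e-6)


def test_cc_non_increasing_with_noise():
    base = render_disc_frame((80.0, 80.0))
    tmpl = extract_template(base, (80, 80), 43)
    means = []
    for sd in (0.0, 0.02, 0.05, 0.10):
        rng = np.random.default_rng(11)
        ccs = []
        for _ in range(8):
            f = render_disc_frame((80.0, 80.0), noise_sd=sd, rng=rng)
            _, cc = match_template(f, tmpl, region_at(80, 80))
            ccs.append(cc)
        means.append(np.mean(ccs))
    assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


def test_region_too_small_raises():
    frame = render_disc_frame((80.0, 80.0))
    tmpl = extract_template(frame, (80, 80), 43)
    with pytest.raises(ConfigurationError):
        match_template(frame, tmpl, SearchRegion((80, 80), (10, 10)))


# ---------------------------------------------------------------------------
# refine_subpixel
# ---------------------------------------------------------------------------

def test_symmetric_patch_gives_zero_offset():
    patch = np.array([[0.5, 0.8, 0.5], [0.8, 1.0, 0.8], [0.5, 0.8, 0.5]])
    off = refine_subpixel(patch)
    assert off.dx == 0.0 and off.dy == 0.0 and not off.degenerate


def test_quadratic_patch_exact_recovery():
    """The paraboloid model is exact on quadratic data: a peak at
    (+0.3, -0.2) is recovered to machine precision."""
    px, py = 0.3, -0.2
    xs = np.array([-1.0, 0.0, 1.0])
    c = 1.0 - (xs[None, :] - px) ** 2 - (xs[:, None] - py) ** 2
    off = refine_subpixel(c)
    assert off.dx == pytest.approx(px, abs=1e-12)
    assert off.dy == pytest.approx(py, abs=1e-12)


def test_disc_quarter_pixel_shift_within_tolerance():
    """ZNCC 3x3 neighborhood of a disc shifted +0.25 px, against the
    dense-shift rendering oracle."""
    from skimage.feature import match_template as zncc
    base = render_disc_frame((80.0, 80.0))
    tmpl = extract_template(base, (80, 80), 43)
    shifted = render_disc_frame((80.25, 80.0))
    cc = zncc(shifted.pixels, tmpl.patch, pad_input=False)
    py, px = np.unravel_index(np.argmax(cc), cc.shape)
    off = refine_subpixel(cc[py - 1:py + 2, px - 1:px + 2])
    est = px + off.dx + 21 - 80
    assert est == pytest.approx(0.25, abs=0.05)


def test_flat_patch_flagged_degenerate():
    off = refine_subpixel(np.full((3, 3), 0.7))
    assert off.degenerate and off.dx == 0.0 and off.dy == 0.0


def test_offsets_clamped_to_half_pixel():
    patch = np.array([[0.0, 0.0, 0.9], [0.0, 1.0, 0.999], [0.0, 0.0, 0.9]])
    off = refine_subpixel(patch)
    assert abs(off.dx) <= 0.5 and abs(off.dy) <= 0.5


def test_center_not_maximum_rejected():
    patch = np.array([[2.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
    with pytest.raises(ValueError):
        refine_subpixel(patch)


# ---------------------------------------------------------------------------
# track_sequence
# ---------------------------------------------------------------------------

def seeded_templates_and_seeds(frames, center=(80, 80), size=43):
    tmpl = extract_template(frames[0], center, size, bead_id="b1")
    return [tmpl], {"b1": (float(center[0]), float(center[1]))}


def test_static_noiseless_scene_zero_displacement():
    frames = make_sequence([(80.0, 80.0)] * 20)
    templates, seeds = seeded_templates_and_seeds(frames)
    tracks = track_sequence(frames, templates, seeds=seeds)
    pts = tracks["b1"]
    assert not any(tp.lost for tp in pts)
    pos = np.array([tp.position_px for tp in pts])
    assert np.abs(pos - pos[0]).max() < 1e-6


def test_smooth_subpixel_ramp_rmse_below_005_px():
    """Vertical ramp of 30 px over 200 frames (0.15 px/frame): per-frame
    position error against the renderer ground truth stays < 0.05 px RMSE."""
    n = 200
    ys = 120.0 - 30.0 * np.arange(n) / (n - 1)
    frames = make_sequence([(80.0, y) for y in ys], shape=(200, 160),
                           noise_sd=0.005, seed=5)
    tmpl = extract_template(frames[0], (80, 120), 43, bead_id="b1")
    tracks = track_sequence(frames, [tmpl], seeds={"b1": (80.0, 120.0)})
    pos = np.array([tp.position_px for tp in tracks["b1"]])
    rmse = np.sqrt(np.mean((pos[:, 1] - ys) ** 2 + (pos[:, 0] - 80.0) ** 2))
    assert rmse < 0.05


def test_occluded_frame_lost_and_recovered():
    frames = make_sequence([(80.0, 80.0)] * 5)
    blank = frames[2].pixels.copy()
    blank[55:105, 55:105] = BG    # occlude the bead
    frames[2] = Frame(blank, frames[2].timestamp, 2)
    templates, seeds = seeded_templates_and_seeds(frames)
    tracks = track_sequence(frames, templates, cc_min=0.5, seeds=seeds)
    pts = tracks["b1"]
    assert pts[2].lost and pts[2].cc < 0.5
    assert pts[2].position_px is None
    assert not pts[3].lost and not pts[4].lost


def test_lost_point_hygiene_no_position_below_threshold():
    frames = make_sequence([(80.0, 80.0)] * 6, noise_sd=0.3, seed=9)
    templates, seeds = seeded_templates_and_seeds(frames)
    tracks = track_sequence(frames, templates, cc_min=0.9, seeds=seeds)
    for tp in tracks["b1"]:
        if tp.cc < 0.9:
            assert tp.lost and tp.position_px is None


def test_abandoned_after_max_consecutive_losses():
    frames = make_sequence([(80.0, 80.0)] * 10)
    # occlude from frame 2 onward
    for k in range(2, 10):
        px = frames[k].pixels.copy()
        px[40:120, 40:120] = BG
        frames[k] = Frame(px, frames[k].timestamp, k)
    templates, seeds = seeded_templates_and_seeds(frames)
    policy = SearchPolicy(max_consecutive_lost=3)
    tracks = track_sequence(frames, templates, search=policy, seeds=seeds)
    assert tracks["b1"][-1].abandoned


def test_frame_sequence_rejects_nonincreasing_timestamps():
    f1 = render_disc_frame((80, 80), timestamp=TS)
    f2 = render_disc_frame((80, 80), timestamp=TS)
    with pytest.raises(ValueError):
        FrameSequence([f1, f2])
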