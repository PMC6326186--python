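"""Metric correctness against independent brute-force implementations."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsunet.errors import ConfigError, UndefinedMetricError
from bsunet.metrics import (boundary_dice, dice, evaluate_pair,
                            extract_boundary, mhd)


# ---------------------------------------------------------------------------
# brute-force oracles (set arithmetic and double loops only)

def brute_dice(a, b):
    sa = {tuple(p) for p in np.argwhere(np.asarray(a) > 0)}
    sb = {tuple(p) for p in np.argwhere(np.asarray(b) > 0)}
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def brute_boundary(mask, t):
    """Pixel is in the t-band iff it is foreground and some pixel within
    Chebyshev distance t (including out-of-image) is background."""
    m = np.asarray(mask) > 0
    h, w = m.shape
    band = np.zeros_like(m)
    for r, c in np.argwhere(m):
        for dr in range(-t, t + 1):
            for dc in range(-t, t + 1):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not m[rr, cc]:
                    band[r, c] = True
    return band


def brute_mhd(a, b, spacing):
    pa = [tuple(p) for p in np.argwhere(brute_boundary(a, 1))]
    pb = [tuple(p) for p in np.argwhere(brute_boundary(b, 1))]
    def directed(ps, qs):
        return sum(min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in qs)
                   for p in ps) / len(ps)
    return max(directed(pa, pb), directed(pb, pa)) * spacing


def _window_masks(max_px=8):
    """All masks on a 6x6 grid whose foreground lies in the central 3x3
    window, up to max_px pixels — an exhaustive small-shape family."""
    cells = [(r, c) for r in range(1, 4) for c in range(1, 4)]
    masks = []
    for bits in range(1, 2 ** 9):
        if bin(bits).count("1") > max_px:
            continue
        m = np.zeros((6, 6), np.uint8)
        for i, (r, c) in enumerate(cells):
            if bits >> i & 1:
                m[r, c] = 1
        masks.append(m)
    return masks


# ---------------------------------------------------------------------------
# worked examples

def test_dice_examples():
    a = np.zeros((4, 4), np.uint8); a[0, :4] = 1            # |A| = 4
    b = np.zeros((4, 4), np.uint8); b[0, 1:4] = 1; b[1, :3] = 1  # |B| = 6
    # intersection = 3 -> 2*3/(4+6)
    assert dice(a, b) == pytest.approx(0.6)
    assert dice(a, a) == 1.0
    c = np.zeros((4, 4), np.uint8); c[3, :] = 1
    assert dice(a, c) == 0.0
    with pytest.raises(UndefinedMetricError):
        dice(np.zeros((4, 4)), np.zeros((4, 4)))


def test_boundary_band_examples():
    single = np.zeros((5, 5), np.uint8); single[2, 2] = 1
    assert np.array_equal(extract_boundary(single, 1), single.astype(bool))
    sq3 = np.zeros((5, 5), np.uint8); sq3[1:4, 1:4] = 1
    band = extract_boundary(sq3, 1)
    assert band.sum() == 8 and not band[2, 2]
    sq4 = np.zeros((6, 6), np.uint8); sq4[1:5, 1:5] = 1
    assert extract_boundary(sq4, 2).sum() == 16  # double erosion empties it
    with pytest.raises(ConfigError):
        extract_boundary(sq3, 0)


def test_boundary_dice_identity_and_shift():
    sq = np.zeros((8, 8), np.uint8); sq[1:4, 1:4] = 1
    for t in (1, 2):
        assert boundary_dice(sq, sq, t) == 1.0
    shifted = np.roll(sq, 2, axis=1)
    assert boundary_dice(sq, shifted, 1) == pytest.approx(
        brute_dice(brute_boundary(sq, 1), brute_boundary(shifted, 1)))


def test_dilated_prediction_has_high_whole_but_low_boundary_dice():
    """The motivating gap: a 1-px dilation of a large disc keeps whole-area
    Dice high while 1-px boundary Dice collapses."""
    from scipy import ndimage
    yy, xx = np.mgrid[0:40, 0:40]
    ellipse = (((xx - 20) / 18.0) ** 2 + ((yy - 20) / 8.0) ** 2 <= 1).astype(np.uint8)
    pred = ndimage.binary_dilation(ellipse, np.ones((3, 3), bool)).astype(np.uint8)
    assert dice(pred, ellipse) > 0.85
    assert boundary_dice(pred, ellipse, 1) < 0.2
    assert boundary_dice(pred, ellipse, 1) < dice(pred, ellipse)


def test_mhd_examples():
    a = np.zeros((4, 4), np.uint8); a[0, 0] = 1
    b = np.zeros((4, 4), np.uint8); b[0, 2] = 1
    assert mhd(a, b, spacing_mm=1.5) == pytest.approx(3.0)
    c = np.zeros((4, 4), np.uint8); c[0, 0] = 1; c[1, 0] = 1
    d = np.zeros((4, 4), np.uint8); d[0, 0] = 1
    assert mhd(c, d, spacing_mm=1.0) == pytest.approx(0.5)
    assert mhd(a, a) == 0.0
    with pytest.raises(UndefinedMetricError):
        mhd(a, np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# exhaustive oracle agreement on small masks

def test_band_matches_erosion_oracle_exhaustively():
    for m in _window_masks():
        for t in (1, 2):
            assert np.array_equal(extract_boundary(m, t), brute_boundary(m, t))


def test_dice_matches_brute_force_exhaustively():
    masks = _window_masks()
    # every mask against a deterministic systematic selection of partners
    for i, a in enumerate(masks):
        for j in range(i, min(i + 40, len(masks)), 7):
            assert dice(a, masks[j]) == brute_dice(a, masks[j])


def test_mhd_matches_brute_force():
    masks = _window_masks()
    rng = np.random.default_rng(99)
    idx = rng.integers(0, len(masks), size=(400, 2))
    for i, j in idx:
        got = mhd(masks[i], masks[j], spacing_mm=1.5)
        want = brute_mhd(masks[i], masks[j], 1.5)
        assert got == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# properties

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 36 - 1), st.integers(0, 2 ** 36 - 1))
def test_symmetry_and_bounds(bits_a, bits_b):
    a = np.array([(bits_a >> i) & 1 for i in range(36)], np.uint8).reshape(6, 6)
    b = np.array([(bits_b >> i) & 1 for i in range(36)], np.uint8).reshape(6, 6)
    if a.sum() + b.sum() == 0:
        return
    assert dice(a, b) == dice(b, a)
    assert 0.0 <= dice(a, b) <= 1.0
    if a.sum() and b.sum():
        assert mhd(a, b) == mhd(b, a)
        assert mhd(a, b) >= 0.0
        same_boundary = np.array_equal(extract_boundary(a, 1),
                                       extract_boundary(b, 1))
        assert (mhd(a, b) == 0.0) == same_boundary


def test_band_nesting(small_cohort):
    _pid, _cid, _img, mask = next(small_cohort.cases())
    b1 = extract_boundary(mask, 1)
    b2 = extract_boundary(mask, 2)
    assert np.all(b1 <= b2) and np.all(b2 <= (mask > 0))


def test_monotone_degradation_under_shift():
    """Whole-area Dice never increases as a convex mask is shifted
    further."""
    yy, xx = np.mgrid[0:64, 0:64]
    ellipse = (((xx - 32) / 20.0) ** 2 + ((yy - 32) / 9.0) ** 2 <= 1).astype(np.uint8)
    prev = 1.0
    for k in range(1, 7):
        d = dice(np.roll(ellipse, k, axis=0), ellipse)
        assert d <= prev + 1e-12
        prev = d


def test_evaluate_pair_report(small_cohort):
    _pid, _cid, _img, mask = next(small_cohort.cases())
    r = evaluate_pair(mask, mask, spacing_mm=1.5)
    assert r.dsc_whole == 1.0 and r.mhd_mm == 0.0
    assert r.dsc_boundary_1px == 1.0 and r.dsc_boundary_2px == 1.0
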