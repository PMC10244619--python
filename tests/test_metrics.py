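"""Aeration metrics: analytic cases, brute-force oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neoeit.errors import DegenerateSignalWarning, UndefinedRatioError
from neoeit.io import EitRecording
from neoeit.metrics import (
    MetricsConfig,
    PixelMaps,
    compute_aer_pct,
    compute_ahr,
    compute_cov_row,
    compute_cv,
    compute_pixel_maps,
    compute_silent_spaces,
    metrics_from_maps,
    summarize,
)
from neoeit.preprocess import BreathTable, LungRoiMask, detect_breaths, select_segment, apply_mask, normalize_by_weight
from neoeit.simulate import RecordingScenario, make_recording


def maps_on(mask: LungRoiMask, eeli, tv) -> PixelMaps:
    e = np.where(mask.in_lung, np.asarray(eeli, float), np.nan)
    t = np.where(mask.in_lung, np.asarray(tv, float), np.nan)
    return PixelMaps(eeli=e, tv=t)


def random_mask(rng) -> LungRoiMask:
    rows = int(rng.integers(4, 9))
    cols = 4
    in_lung = np.zeros((rows, cols), bool)
    while in_lung.sum() < 4 or not in_lung[:, :2].any() or not in_lung[:, 2:].any():
        in_lung = rng.random((rows, cols)) < 0.7
    side = np.where(np.arange(cols) < 2, 1, 2) * in_lung
    lung_rows = np.where(in_lung.any(axis=1))[0]
    r0, r1 = int(lung_rows[0]), int(lung_rows[-1])
    h = r1 - r0 + 1
    w = np.zeros(rows)
    for r in range(r0, r1 + 1):
        k = r - r0
        if h % 2 == 0:
            w[r] = 1.0 if k < h // 2 else 0.0
        else:
            w[r] = 1.0 if k < h // 2 else (0.5 if k == h // 2 else 0.0)
    return LungRoiMask(in_lung, side.astype(np.int8), w, r0, r1)


# --- pixel maps ------------------------------------------------------------


def test_pixel_maps_analytic_raised_cosine(tiny_mask):
    # baseline 4, amplitude 2, period 20 frames: eeli = 4, tv = 2 exactly
    n, p = 61, 20
    wave = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / p))
    frames = np.empty((n, 4, 4), dtype=np.float32)
    frames[:] = (4.0 + 2.0 * wave)[:, None, None]
    frames[:, 3, 3] = 4.0  # a silent pixel: no tidal swing
    rec = EitRecording(frames=frames, frame_rate_hz=10.0, subject_id="t",
                       body_weight_g=1000.0, normalized=True)
    breaths = BreathTable(
        np.array([0, 20, 40]), np.array([10, 30, 50]), np.array([20, 40, 60])
    )
    maps = compute_pixel_maps(rec, breaths, tiny_mask)
    assert maps.eeli[0, 0] == pytest.approx(4.0)
    assert maps.tv[0, 0] == pytest.approx(2.0)
    assert maps.tv[3, 3] == 0.0


def test_negative_tidal_differences_clamped(tiny_mask):
    breaths = BreathTable(np.array([0, 2]), np.array([1, 3]), np.array([2, 4]))
    frames = np.zeros((5, 4, 4), dtype=np.float32)
    frames[1] = -1.0  # "inspiration" below end-expiration
    frames[3] = 2.0
    rec = EitRecording(frames=frames, frame_rate_hz=10.0, subject_id="t",
                       body_weight_g=1000.0, normalized=True)
    maps = compute_pixel_maps(rec, breaths, tiny_mask)
    # breath 1 contributes max(-1, 0) = 0, breath 2 contributes 2
    assert maps.tv[0, 0] == pytest.approx(1.0)


def test_pixel_maps_require_two_breaths(tiny_mask):
    from neoeit.errors import InsufficientBreathsError

    one = BreathTable(np.array([0]), np.array([1]), np.array([2]))
    rec = EitRecording(frames=np.zeros((3, 4, 4), np.float32), frame_rate_hz=10.0,
                       subject_id="t", body_weight_g=1000.0, normalized=True)
    with pytest.raises(InsufficientBreathsError):
        compute_pixel_maps(rec, one, tiny_mask)


# --- Aer% ------------------------------------------------------------------


def test_aer_pct_examples(tiny_mask):
    uniform = maps_on(tiny_mask, np.full((4, 4), 3.0), np.ones((4, 4)))
    assert compute_aer_pct(uniform, tiny_mask) == 100.0
    half = np.zeros((4, 4))
    half[:2] = 1.0
    assert compute_aer_pct(maps_on(tiny_mask, half, half), tiny_mask) == 50.0


def test_aer_pct_degenerate_warns(tiny_mask):
    zero = maps_on(tiny_mask, np.zeros((4, 4)), np.zeros((4, 4)))
    with pytest.warns(DegenerateSignalWarning):
        assert compute_aer_pct(zero, tiny_mask) == 0.0


# --- AHR -------------------------------------------------------------------


def test_ahr_symmetric_integer_map_exactly_one(atlas_mask32):
    eeli = np.zeros((32, 32))
    eeli[atlas_mask32.in_lung] = 2.0  # mirror symmetric about the split
    maps = maps_on(atlas_mask32, eeli, eeli)
    assert compute_ahr(maps, atlas_mask32) == 1.0


def test_ahr_arithmetic(tiny_mask):
    eeli = np.zeros((4, 4))
    eeli[:2] = 30.0 / 8.0  # ventral half sums to 30
    eeli[2:] = 20.0 / 8.0  # dorsal half sums to 20
    assert compute_ahr(maps_on(tiny_mask, eeli, eeli), tiny_mask) == pytest.approx(1.5)


def test_ahr_zero_dorsal_is_error(tiny_mask):
    eeli = np.zeros((4, 4))
    eeli[:2] = 1.0
    with pytest.raises(UndefinedRatioError):
        compute_ahr(maps_on(tiny_mask, eeli, eeli), tiny_mask)


def test_ahr_matches_bruteforce_on_random_maps():
    rng = np.random.default_rng(7)
    for _ in range(20):
        mask = random_mask(rng)
        eeli = rng.uniform(0.1, 5.0, mask.in_lung.shape)
        maps = maps_on(mask, eeli, eeli)
        num = den = 0.0
        for r, c in zip(*np.nonzero(mask.in_lung)):
            wv = mask.ventral_weight[r]
            num += eeli[r, c] * wv
            den += eeli[r, c] * (1 - wv)
        assert compute_ahr(maps, mask) == pytest.approx(num / den, abs=1e-12)


# --- CV --------------------------------------------------------------------


def test_cv_examples(tiny_mask):
    uniform = maps_on(tiny_mask, np.ones((4, 4)), np.full((4, 4), 2.0))
    assert compute_cv(uniform, tiny_mask) == 0.0
    two = np.ones((4, 4))
    two[:2] = 1.0
    two[2:] = 3.0  # values {1, 3}: mean 2, population SD 1
    assert compute_cv(maps_on(tiny_mask, two, two), tiny_mask) == pytest.approx(0.5)
    # sample-SD convention uses ddof=1
    vals = two[tiny_mask.in_lung]
    expected = np.std(vals, ddof=1) / vals.mean()
    assert compute_cv(
        maps_on(tiny_mask, two, two), tiny_mask, "sample"
    ) == pytest.approx(expected)


def test_cv_matches_bruteforce_pixel_loop():
    rng = np.random.default_rng(8)
    for _ in range(20):
        mask = random_mask(rng)
        tv = rng.uniform(0, 4.0, mask.in_lung.shape)
        vals = [tv[r, c] for r, c in zip(*np.nonzero(mask.in_lung))]
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
        got = compute_cv(maps_on(mask, tv, tv), mask)
        assert got == pytest.approx(sd / mean, abs=1e-12)


# --- center of ventilation -------------------------------------------------


def test_cov_row_symmetric_is_half(tiny_mask):
    maps = maps_on(tiny_mask, np.ones((4, 4)), np.ones((4, 4)))
    assert compute_cov_row(maps, tiny_mask) == pytest.approx(0.5)


def test_cov_row_dorsal_row_of_20_row_lung():
    in_lung = np.ones((20, 4), bool)
    side = np.where(np.arange(4) < 2, 1, 2) * np.ones((20, 4), int)
    w = np.concatenate([np.ones(10), np.zeros(10)])
    mask = LungRoiMask(in_lung, side.astype(np.int8), w, 0, 19)
    tv = np.zeros((20, 4))
    tv[19] = 1.0
    maps = maps_on(mask, np.ones((20, 4)), tv)
    assert compute_cov_row(maps, mask) == pytest.approx(0.975)


def test_cov_row_matches_bruteforce():
    rng = np.random.default_rng(9)
    for _ in range(20):
        mask = random_mask(rng)
        tv = rng.uniform(0, 2.0, mask.in_lung.shape)
        num = den = 0.0
        for r, c in zip(*np.nonzero(mask.in_lung)):
            pos = (r - mask.row_min + 0.5) / mask.lung_height
            num += tv[r, c] * pos
            den += tv[r, c]
        got = compute_cov_row(maps_on(mask, tv, tv), mask)
        assert got == pytest.approx(num / den, abs=1e-12)


# --- silent spaces ---------------------------------------------------------


def test_silent_spaces_none_below_threshold(tiny_mask):
    tv = np.full((4, 4), 5.0)
    assert compute_silent_spaces(maps_on(tiny_mask, tv, tv), tiny_mask) == (
        0.0, 0.0, 0.0,
    )


def test_silent_spaces_scale_invariant(tiny_mask):
    rng = np.random.default_rng(3)
    tv = rng.uniform(0, 1, (4, 4))
    base = compute_silent_spaces(maps_on(tiny_mask, tv, tv), tiny_mask)
    for c in (1e-6, 3.0, 1e8):
        scaled = compute_silent_spaces(maps_on(tiny_mask, tv, c * tv), tiny_mask)
        assert scaled == base


@given(st.integers(0, 10_000))
def test_silent_partition_conserved(seed):
    rng = np.random.default_rng(seed)
    mask = random_mask(rng)
    tv = rng.uniform(0, 1, mask.in_lung.shape) ** 3
    total, ngd, gd = compute_silent_spaces(maps_on(mask, tv, tv), mask)
    assert abs(ngd + gd - total) <= 1e-9


def test_all_silent_degenerate(tiny_mask):
    zero = maps_on(tiny_mask, np.ones((4, 4)), np.zeros((4, 4)))
    with pytest.warns(DegenerateSignalWarning):
        total, ngd, gd = compute_silent_spaces(zero, tiny_mask)
    assert total == 100.0 and ngd + gd == total


# --- summarize / compound --------------------------------------------------


def test_summarize_compound_identity():
    scn = RecordingScenario(gradient_g=1.0, silent_fraction=0.0, noise_sd=0.0)
    rec, mask, _ = make_recording(scn)
    seg = select_segment(normalize_by_weight(apply_mask(rec, mask)), 0.0, 30.0)
    m = summarize(seg, detect_breaths(seg), mask, MetricsConfig())
    assert m.aer_pct == 100.0
    assert m.ahr == pytest.approx(1.0, rel=1e-6)
    assert m.cv == pytest.approx(0.0, abs=1e-6)
    assert (m.ss_total_pct, m.ss_ngd_pct, m.ss_gd_pct) == (0.0, 0.0, 0.0)


def test_small_noise_perturbs_metrics_below_2pct():
    base = dict(gradient_g=1.5, aerated_fraction=0.9, silent_fraction=0.2,
                tidal_dispersion=0.3, seed=6)
    _, _, truth = make_recording(RecordingScenario(**base))
    noisy = RecordingScenario(**base, noise_sd=0.01 * 2.0)  # 1% of tidal amp
    rec, mask, _ = make_recording(noisy)
    seg = select_segment(normalize_by_weight(apply_mask(rec, mask)), 0.0, 30.0)
    m = summarize(seg, detect_breaths(seg), mask, MetricsConfig())
    t = truth.as_metrics().as_row()
    for key, value in m.as_row().items():
        assert abs(value - t[key]) / max(abs(t[key]), 1e-9) < 0.02, key


def test_rescaling_only_scales_eeli(tiny_mask):
    rng = np.random.default_rng(12)
    eeli = rng.uniform(0.5, 2.0, (4, 4))
    tv = rng.uniform(0.0, 1.0, (4, 4))
    m1 = metrics_from_maps(maps_on(tiny_mask, eeli, tv), tiny_mask)
    c = 7.5
    m2 = metrics_from_maps(maps_on(tiny_mask, c * eeli, c * tv), tiny_mask)
    assert m2.eeli_au_per_kg == pytest.approx(c * m1.eeli_au_per_kg, rel=1e-12)
    for key in ("aer_pct", "ahr", "cv", "ss_ngd_pct", "ss_gd_pct"):
        assert getattr(m2, key) == pytest.approx(getattr(m1, key), rel=1e-12)
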