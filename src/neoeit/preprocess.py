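"""Lung-ROI projection, weight normalization, segment selection, breaths.

The vendor chest atlas used clinically is proprietary; it is replaced here by
a parametric two-ellipse atlas that preserves the analysis semantics: signal
restricted to lung pixels, and a ventral (non-gravity-dependent, row 0 side
in supine) / dorsal (gravity-dependent) split of the lung bounding box at its
horizontal midline, with a row straddling the midline weighted 0.5/0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import (
    ArtefactError,
    ArtefactWarning,
    BoundsError,
    GeometryError,
    InsufficientBreathsError,
    StateError,
    ValidationError,
)
from .io import EitRecording

SIDE_NONE, SIDE_LEFT, SIDE_RIGHT = 0, 1, 2


@dataclass
class AtlasParams:
    """Two mirror-symmetric ellipses in pixel-center coordinates.

    Defaults are fractions of the grid so the atlas scales with grid size;
    on the device's 32x32 lattice they give a lung bounding box spanning
    rows 6-25 (20 rows, even ventral/dorsal split).
    """

    row_center_frac: float = 0.5        # of (rows - 1)
    row_semi_frac: float = 10.0 / 32.0  # of rows
    col_offset_frac: float = 7.0 / 32.0  # of cols, center offset from midline
    col_semi_frac: float = 5.5 / 32.0   # of cols

    def resolve(self, grid_shape: tuple[int, int]):
        rows, cols = grid_shape
        r0 = self.row_center_frac * (rows - 1)
        a = self.row_semi_frac * rows
        b = self.col_semi_frac * cols
        mid = (cols - 1) / 2.0
        off = self.col_offset_frac * cols
        return [(r0, mid - off, a, b), (r0, mid + off, a, b)]


@dataclass
class LungRoiMask:
    """Boolean lung mask with left/right labels and a ventral/dorsal split.

    ``ventral_weight[r]`` is the fraction of row *r* (within the lung
    bounding box) belonging to the ventral half; the dorsal weight is its
    complement, so half-weights always sum to 1 per row.
    """

    in_lung: np.ndarray
    side: np.ndarray
    ventral_weight: np.ndarray
    row_min: int
    row_max: int

    def __post_init__(self) -> None:
        self.in_lung = np.asarray(self.in_lung, dtype=bool)
        self.side = np.asarray(self.side, dtype=np.int8)
        self.ventral_weight = np.asarray(self.ventral_weight, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.in_lung.shape != self.side.shape:
            raise ValidationError("mask: in_lung and side shapes differ")
        if not self.in_lung.any():
            raise ValidationError("mask: no lung pixels")
        if not ((self.side == SIDE_LEFT) & self.in_lung).any():
            raise ValidationError("mask: left lung has no pixels")
        if not ((self.side == SIDE_RIGHT) & self.in_lung).any():
            raise ValidationError("mask: right lung has no pixels")
        if (self.side[self.in_lung] == SIDE_NONE).any():
            raise ValidationError("mask: in-lung pixel without side label")
        w = self.ventral_weight
        if ((w < 0) | (w > 1)).any():
            raise ValidationError("mask: ventral weights outside [0, 1]")

    @property
    def n_lung_pixels(self) -> int:
        return int(self.in_lung.sum())

    @property
    def lung_height(self) -> int:
        return self.row_max - self.row_min + 1

    def row_positions(self) -> np.ndarray:
        """Per-row pixel-center position in the lung, 0=ventral edge .. 1=dorsal."""
        rows = np.arange(self.in_lung.shape[0], dtype=float)
        return (rows - self.row_min + 0.5) / self.lung_height

    def dorsal_weight(self) -> np.ndarray:
        w = np.zeros_like(self.ventral_weight)
        rows = np.arange(len(w))
        inside = (rows >= self.row_min) & (rows <= self.row_max)
        w[inside] = 1.0 - self.ventral_weight[inside]
        return w


def build_atlas_mask(
    grid_shape: tuple[int, int], atlas_params: Optional[AtlasParams] = None
) -> LungRoiMask:
    """Project the parametric two-ellipse lung atlas onto a pixel grid."""
    rows, cols = grid_shape
    if rows < 8 or cols < 8:
        raise GeometryError("grid must be at least (8, 8) for the atlas")
    params = atlas_params or AtlasParams()
    ellipses = params.resolve(grid_shape)

    in_lung = np.zeros((rows, cols), dtype=bool)
    side = np.zeros((rows, cols), dtype=np.int8)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    for label, (r0, c0, a, b) in zip((SIDE_LEFT, SIDE_RIGHT), ellipses):
        if r0 - a < -0.5 or r0 + a > rows - 0.5 or c0 - b < -0.5 or c0 + b > cols - 0.5:
            raise GeometryError("lung ellipse extends outside the grid")
        member = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
        if (member & in_lung).any():
            raise GeometryError("lung ellipses overlap")
        in_lung |= member
        side[member] = label

    lung_rows = np.where(in_lung.any(axis=1))[0]
    row_min, row_max = int(lung_rows[0]), int(lung_rows[-1])
    ventral_weight = np.zeros(rows, dtype=float)
    height = row_max - row_min + 1
    # midline of the bounding box; a straddling row splits 0.5/0.5
    for r in range(row_min, row_max + 1):
        k = r - row_min
        if height % 2 == 0:
            ventral_weight[r] = 1.0 if k < height // 2 else 0.0
        else:
            mid = height // 2
            ventral_weight[r] = 1.0 if k < mid else (0.5 if k == mid else 0.0)
    return LungRoiMask(in_lung, side, ventral_weight, row_min, row_max)


def apply_mask(rec: EitRecording, mask: LungRoiMask) -> EitRecording:
    """Set out-of-lung pixels to NaN (excluded, never treated as zero)."""
    mask.validate()
    if rec.frame_shape != mask.in_lung.shape:
        raise ValidationError(
            f"mask shape {mask.in_lung.shape} != frame shape {rec.frame_shape}"
        )
    frames = rec.frames.copy()
    frames[:, ~mask.in_lung] = np.nan
    return rec.copy_with(frames=frames)


def normalize_by_weight(rec: EitRecording) -> EitRecording:
    """Divide every pixel by body weight in kg; units become AU/kg."""
    if rec.normalized:
        raise StateError("recording already weight-normalized")
    frames = rec.frames / np.float32(rec.body_weight_kg)
    return rec.copy_with(frames=frames, normalized=True)


def global_lung_signal(rec: EitRecording) -> np.ndarray:
    """Per-frame sum over included (non-NaN) pixels."""
    flat = rec.frames.reshape(rec.n_frames, -1)
    return np.nansum(flat, axis=1)


def select_segment(
    rec: EitRecording,
    t_start_s: float,
    duration_s: float = 30.0,
    *,
    z_limit: float = 6.0,
    min_frac_within: float = 0.99,
    artefact_hard_fail: bool = False,
) -> EitRecording:
    """Extract a contiguous analysis window and run the artefact screen.

    The window spans ``floor(duration*fs) + 1`` frames (both endpoints
    included) so a window aligned with end-expiration holds a whole number of
    breaths.  The artefact screen requires the robust z-score of the global
    lung-sum signal (median/MAD of the window itself) to stay within
    ``z_limit`` for at least ``min_frac_within`` of the frames; otherwise the
    segment is flagged (or rejected when ``artefact_hard_fail``).
    """
    fs = rec.frame_rate_hz
    i0 = int(round(t_start_s * fs))
    n = int(np.floor(duration_s * fs)) + 1
    if t_start_s < 0 or i0 < 0 or i0 + n > rec.n_frames:
        raise BoundsError(
            f"window [{t_start_s}, {t_start_s + duration_s}] s outside "
            f"recording of {rec.duration_s:.2f} s"
        )
    seg = rec.copy_with(frames=rec.frames[i0 : i0 + n].copy())

    x = global_lung_signal(seg)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    sigma = 1.4826 * mad
    if sigma == 0:
        frac_ok = 1.0 if np.allclose(x, med) else 0.0
    else:
        frac_ok = float(np.mean(np.abs(x - med) / sigma <= z_limit))
    if frac_ok < min_frac_within:
        if artefact_hard_fail:
            raise ArtefactError(
                f"artefact screen failed: {100 * frac_ok:.1f}% of frames "
                f"within +/-{z_limit} robust z"
            )
        warnings.warn(
            "segment flagged artefactual by robust-z screen", ArtefactWarning
        )
        seg.artefact_flag = True
    return seg


@dataclass
class BreathTable:
    """Per-breath end-expiration/end-inspiration frame indices."""

    index_end_exp_start: np.ndarray
    index_end_insp: np.ndarray
    index_end_exp_end: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.index_end_exp_start, dtype=int)
        b = np.asarray(self.index_end_insp, dtype=int)
        c = np.asarray(self.index_end_exp_end, dtype=int)
        self.index_end_exp_start, self.index_end_insp, self.index_end_exp_end = a, b, c
        if not (len(a) == len(b) == len(c)):
            raise ValidationError("breath table: column lengths differ")
        # consecutive breaths share (or at least respect) bounding troughs
        if len(a) and not (
            np.all(a < b) and np.all(b < c) and np.all(a[1:] >= c[:-1])
        ):
            raise ValidationError("breath table: indices not increasing")

    @property
    def n_breaths(self) -> int:
        return len(self.index_end_exp_start)

    def end_expiration_indices(self) -> np.ndarray:
        """Unique sorted end-expiration frame indices across all breaths."""
        return np.unique(
            np.concatenate([self.index_end_exp_start, self.index_end_exp_end])
        )


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return x.copy()
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _subtract_cardiac_tone(
    x: np.ndarray, fs: float, cutoff_hz: float, order: int, k_edge: int
) -> np.ndarray:
    """Estimate and remove the dominant supra-cutoff sinusoid (cardiac).

    The residual above the respiratory low-pass band is fitted with a single
    sinusoid (frequency by FFT peak plus local refinement, amplitude/phase by
    least squares on the trusted interior of the segment) and subtracted over
    the whole segment.  A sinusoid extrapolates exactly, so this cleans the
    filter-transient zones at the segment boundaries where zero-phase
    filtering is unreliable.  Nothing is subtracted unless the tone dominates
    the residual, so noise-only residuals are left untouched.
    """
    from scipy.optimize import minimize_scalar

    sl = slice(k_edge, len(x) - k_edge) if len(x) > 3 * k_edge else slice(None)
    t_all = np.arange(len(x)) / fs
    t_r = t_all[sl]
    x_clean = x
    # iterate: near the cutoff the low-pass keeps part of the tone, so one
    # fit on the residual under-subtracts; each pass removes the dominant
    # leftover until the residual is noise-like
    for _ in range(4):
        resid = x_clean - _lowpass(x_clean, fs, cutoff_hz, order)
        r = resid[sl]
        var = float(np.var(r))
        if var <= 0 or len(r) < 16:
            break
        freqs = np.fft.rfftfreq(len(r), 1.0 / fs)
        spec = np.abs(np.fft.rfft(r - r.mean()))
        band = freqs > 0.8 * cutoff_hz
        if not band.any():
            break
        f0 = float(freqs[band][np.argmax(spec[band])])

        def tone_fit(f: float, _r=r):
            design = np.column_stack(
                [np.sin(2 * np.pi * f * t_r), np.cos(2 * np.pi * f * t_r)]
            )
            coef, *_ = np.linalg.lstsq(design, _r, rcond=None)
            sse = float(np.sum((_r - design @ coef) ** 2))
            return sse, coef

        df = fs / len(r)
        best = minimize_scalar(
            lambda f: tone_fit(f)[0],
            bounds=(max(f0 - 2 * df, 0.8 * cutoff_hz), min(f0 + 2 * df, fs / 2)),
            method="bounded",
            options={"xatol": 1e-4},
        )
        _, coef = tone_fit(float(best.x))
        if coef[0] ** 2 + coef[1] ** 2 < 0.5 * var:
            break  # no dominant tone: residual is noise, leave it alone
        design_all = np.column_stack(
            [np.sin(2 * np.pi * best.x * t_all), np.cos(2 * np.pi * best.x * t_all)]
        )
        x_clean = x_clean - design_all @ coef
    return x_clean


def detect_breaths(
    segment: EitRecording,
    mask: Optional[LungRoiMask] = None,
    *,
    lowpass_hz: float = 2.0,
    lowpass_order: int = 8,
    prominence_frac: float = 0.25,
) -> BreathTable:
    """Segment the global lung waveform into min-max-min breaths.

    The lung-sum signal is zero-phase low-pass filtered (cuts the cardiac
    component), extrema are detected with a prominence threshold of
    ``prominence_frac`` times the median peak-to-trough excursion, and
    breaths are the trough-peak-trough triples.  The signal is mirror-padded
    before filtering so end-expirations falling exactly on the segment
    boundary are detectable; a boundary extremum only counts as a trough if
    it sits at interior-trough level.
    """
    seg = apply_mask(segment, mask) if mask is not None else segment
    x = global_lung_signal(seg)
    n = len(x)
    if n < 8:
        raise InsufficientBreathsError("segment too short")
    x = x - np.mean(x)
    k_edge = int(round(2.0 * segment.frame_rate_hz / max(lowpass_hz, 1e-9)))
    x = _subtract_cardiac_tone(
        x, segment.frame_rate_hz, lowpass_hz, lowpass_order, k_edge
    )

    pad = min(n - 1, max(8, int(round(4.0 * segment.frame_rate_hz))))
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -2 - pad : -1]])
    y = _lowpass(xp, segment.frame_rate_hz, lowpass_hz, lowpass_order)

    peaks0, _ = sps.find_peaks(y)
    troughs0, _ = sps.find_peaks(-y)
    ext = np.sort(np.concatenate([peaks0, troughs0]))
    if len(ext) < 2:
        raise InsufficientBreathsError("no oscillation detected")
    excursions = np.abs(np.diff(y[ext]))
    excursions = excursions[excursions > 0]
    if len(excursions) == 0:
        raise InsufficientBreathsError("flat signal")
    med_exc = float(np.median(excursions))
    prom = prominence_frac * med_exc

    peaks, _ = sps.find_peaks(y, prominence=prom)
    troughs, _ = sps.find_peaks(-y, prominence=prom)
    lo, hi = pad, pad + n - 1
    peaks = peaks[(peaks >= lo) & (peaks <= hi)] - pad
    troughs = troughs[(troughs >= lo) & (troughs <= hi)] - pad
    yin = y[lo : hi + 1]

    # the zero-phase filter cannot be trusted within ~2 cutoff periods of the
    # segment boundaries (reflection padding leaves a transient there);
    # troughs in that zone are re-localized from the cleaned signal below
    interior_mask = (troughs >= k_edge) & (troughs <= n - 1 - k_edge)
    interior = troughs[interior_mask]
    if len(interior) >= 2 and n > 3 * k_edge:
        spacing = float(np.median(np.diff(interior)))
        raw_level = float(np.median(x[interior])) + 0.35 * med_exc
        ts = sorted(interior)
        # extrapolate one breath period at a time beyond the outermost
        # trusted troughs; refine each predicted end-expiration on the
        # fold-averaged breath template (averaging across breaths cancels
        # the cardiac component, which is incommensurate with the breath
        # period), and accept it only at trough level — a partial-phase
        # segment start is not a breath boundary
        s_int = int(round(spacing))
        m = n // s_int
        tmpl = x[: m * s_int].reshape(m, s_int).mean(axis=0) if m >= 2 else None
        for direction in (+1, -1):
            anchor = ts[-1] if direction > 0 else ts[0]
            while tmpl is not None:
                t_exp = int(round(anchor + direction * spacing))
                # the predicted end-expiration itself must fall inside the
                # segment; a trough just past the boundary is not claimed
                if t_exp < 0 or t_exp > n - 1:
                    break
                deltas = np.arange(-3, 4)
                phases = (t_exp + deltas) % s_int
                t_star = int(t_exp + deltas[np.argmin(tmpl[phases])])
                t_star = min(max(t_star, 0), n - 1)
                if x[t_star] > raw_level or any(
                    abs(t_star - a) < 0.5 * spacing for a in ts
                ):
                    break
                ts.append(t_star)
                ts.sort()
                anchor = t_star
        troughs = np.array(ts, dtype=int)

    # enforce trough-peak alternation: one peak (the largest) between troughs
    starts, insps, ends = [], [], []
    for t0, t1 in zip(troughs[:-1], troughs[1:]):
        between = peaks[(peaks > t0) & (peaks < t1)]
        if len(between) == 0:
            continue
        p = between[np.argmax(yin[between])]
        starts.append(t0)
        insps.append(p)
        ends.append(t1)
    if len(starts) < 2:
        raise InsufficientBreathsError(
            f"only {len(starts)} breath(s) detected; need at least 2"
        )
    return BreathTable(
        np.array(starts, dtype=int),
        np.array(insps, dtype=int),
        np.array(ends, dtype=int),
    )
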