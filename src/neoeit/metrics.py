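"""The five pre-specified aeration/ventilation predictors plus EELI.

From a preprocessed 30-s segment two pixel maps are distilled:

* ``eeli_map`` — end-expiratory lung impedance per pixel, the breath-averaged
  value at end-expiration (resting aeration, functional-residual-capacity
  proxy);
* ``tv_map`` — tidal variation per pixel, the breath-averaged end-inspiration
  minus end-expiration difference (regional tidal ventilation).

All reported metrics are functions of these maps:

* ``eeli_au_per_kg``  — sum of eeli_map over the lung, per kg body weight;
* ``aer_pct``         — % of lung pixels with EELI above 10% of the maximum;
* ``ahr``             — row-weighted ventral(non-gravity-dependent)/dorsal
  (gravity-dependent) EELI ratio; >1 means ventral predominance;
* ``cv``              — population SD / mean of tidal variation over pixels;
* ``ss_ngd/ss_gd``    — silent spaces (% of lung pixels with tidal variation
  below 10% of the maximum) split at the center-of-ventilation line into
  non-gravity-dependent (overdistension) and gravity-dependent (atelectasis)
  compartments.

Everything except EELI/kg is invariant to a global positive rescaling of the
signal, so body-weight normalization does not affect the percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateSignalWarning,
    InsufficientBreathsError,
    UndefinedRatioError,
)
from .io import EitRecording
from .preprocess import BreathTable, LungRoiMask


@dataclass
class MetricsConfig:
    """Thresholds and conventions for the metric computations."""

    aeration_threshold_frac: float = 0.10
    silent_threshold_frac: float = 0.10
    sd_convention: str = "population"  # or "sample"

    def __post_init__(self) -> None:
        if self.sd_convention not in ("population", "sample"):
            raise ValueError("sd_convention must be 'population' or 'sample'")

    def as_dict(self) -> dict:
        return {
            "aeration_threshold_frac": self.aeration_threshold_frac,
            "silent_threshold_frac": self.silent_threshold_frac,
            "sd_convention": self.sd_convention,
        }


@dataclass
class PixelMaps:
    """Per-pixel EELI and tidal-variation maps (NaN outside the lung)."""

    eeli: np.ndarray
    tv: np.ndarray


@dataclass
class AerationMetrics:
    """One infant's predictor vector."""

    eeli_au_per_kg: float
    aer_pct: float
    ahr: float
    cv: float
    ss_total_pct: float
    ss_ngd_pct: float
    ss_gd_pct: float
    cov_row: float
    config: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "aer_pct": self.aer_pct,
            "ahr": self.ahr,
            "cv": self.cv,
            "ss_ngd_pct": self.ss_ngd_pct,
            "ss_gd_pct": self.ss_gd_pct,
            "eeli_au_per_kg": self.eeli_au_per_kg,
        }


def compute_pixel_maps(
    segment: EitRecording, breaths: BreathTable, mask: LungRoiMask
) -> PixelMaps:
    """Breath-averaged EELI and tidal-variation maps on lung pixels.

    EELI averages the pixel value over the unique end-expiration frames of
    the segment.  Tidal variation averages, over breaths, the end-inspiration
    minus preceding end-expiration difference with negative per-breath
    differences (possible under noise) clamped to zero.
    """
    if breaths.n_breaths < 2:
        raise InsufficientBreathsError("need at least 2 breaths for pixel maps")
    frames = segment.frames.astype(np.float64)
    ee_idx = breaths.end_expiration_indices()
    eeli = frames[ee_idx].mean(axis=0)

    diffs = (
        frames[breaths.index_end_insp] - frames[breaths.index_end_exp_start]
    )
    tv = np.clip(diffs, 0.0, None).mean(axis=0)

    out = ~mask.in_lung
    eeli[out] = np.nan
    tv[out] = np.nan
    return PixelMaps(eeli=eeli, tv=tv)


def compute_aer_pct(
    maps: PixelMaps, mask: LungRoiMask, aeration_threshold_frac: float = 0.10
) -> float:
    """Percentage of lung pixels with EELI above the aeration threshold."""
    vals = maps.eeli[mask.in_lung]
    vmax = np.max(vals)
    if vmax <= 0:
        warnings.warn("all-zero EELI map; Aer% = 0", DegenerateSignalWarning)
        return 0.0
    aerated = np.count_nonzero(vals > aeration_threshold_frac * vmax)
    return 100.0 * aerated / vals.size


def compute_ahr(maps: PixelMaps, mask: LungRoiMask) -> float:
    """Aeration homogeneity ratio: ventral/dorsal row-weighted EELI sums."""
    eeli = np.where(mask.in_lung, maps.eeli, 0.0)
    row_sum = eeli.sum(axis=1)
    wv = np.zeros_like(mask.ventral_weight)
    rows = np.arange(len(wv))
    inside = (rows >= mask.row_min) & (rows <= mask.row_max)
    wv[inside] = mask.ventral_weight[inside]
    ventral = float(np.dot(row_sum, wv))
    dorsal = float(np.dot(row_sum, mask.dorsal_weight()))
    if dorsal == 0:
        raise UndefinedRatioError("dorsal EELI sum is zero; AHR undefined")
    return ventral / dorsal


def compute_cv(
    maps: PixelMaps, mask: LungRoiMask, sd_convention: str = "population"
) -> float:
    """Coefficient of variation of tidal variation over lung pixels."""
    vals = maps.tv[mask.in_lung]
    mean = float(np.mean(vals))
    if mean == 0:
        raise UndefinedRatioError("mean tidal variation is zero; CV undefined")
    ddof = 0 if sd_convention == "population" else 1
    return float(np.std(vals, ddof=ddof)) / mean


def compute_cov_row(maps: PixelMaps, mask: LungRoiMask) -> float:
    """Center of ventilation along the gravity axis, as a fraction of lung
    height (0 = ventral edge, 1 = dorsal edge)."""
    tv = np.where(mask.in_lung, maps.tv, 0.0)
    total = tv.sum()
    if total == 0:
        raise UndefinedRatioError("zero total ventilation; CoV undefined")
    pos = mask.row_positions()
    return float((tv.sum(axis=1) * pos).sum() / total)


def compute_silent_spaces(
    maps: PixelMaps,
    mask: LungRoiMask,
    silent_threshold_frac: float = 0.10,
) -> tuple[float, float, float]:
    """Silent spaces split at the center-of-ventilation line.

    Returns ``(ss_total_pct, ss_ngd_pct, ss_gd_pct)``.  A silent pixel whose
    row center lies ventral to the CoV line counts as non-gravity-dependent,
    dorsal as gravity-dependent; exactly on the line splits 0.5/0.5.
    """
    tv = maps.tv[mask.in_lung]
    n = tv.size
    vmax = np.max(tv)
    if vmax == 0:
        warnings.warn(
            "all-silent tidal map; SS_total = 100", DegenerateSignalWarning
        )
        return 100.0, 50.0, 50.0
    silent = tv < silent_threshold_frac * vmax
    cov = compute_cov_row(maps, mask)
    rr = np.nonzero(mask.in_lung)[0]
    pos = (rr - mask.row_min + 0.5) / mask.lung_height
    ngd = np.where(pos < cov, 1.0, np.where(pos > cov, 0.0, 0.5))
    ss_ngd = 100.0 * float(np.sum(silent * ngd)) / n
    ss_gd = 100.0 * float(np.sum(silent * (1.0 - ngd))) / n
    ss_total = 100.0 * float(np.count_nonzero(silent)) / n
    return ss_total, ss_ngd, ss_gd


def metrics_from_maps(
    maps: PixelMaps,
    mask: LungRoiMask,
    *,
    body_weight_kg: float | None = None,
    normalized: bool = True,
    config: MetricsConfig | None = None,
) -> AerationMetrics:
    """Assemble the predictor vector directly from pixel maps.

    This closed-form path is shared by the measurement pipeline and by the
    synthetic generator's ground truth, so the two agree by construction on
    noiseless maps.
    """
    cfg = config or MetricsConfig()
    total_eeli = float(np.nansum(np.where(mask.in_lung, maps.eeli, np.nan)))
    if normalized:
        eeli_per_kg = total_eeli
    else:
        if body_weight_kg is None or body_weight_kg <= 0:
            raise ValueError("body_weight_kg required for unnormalized maps")
        eeli_per_kg = total_eeli / body_weight_kg
    aer = compute_aer_pct(maps, mask, cfg.aeration_threshold_frac)
    ahr = compute_ahr(maps, mask)
    cv = compute_cv(maps, mask, cfg.sd_convention)
    ss_total, ss_ngd, ss_gd = compute_silent_spaces(
        maps, mask, cfg.silent_threshold_frac
    )
    try:
        cov = compute_cov_row(maps, mask)
    except UndefinedRatioError:
        cov = float("nan")
    return AerationMetrics(
        eeli_au_per_kg=eeli_per_kg,
        aer_pct=aer,
        ahr=ahr,
        cv=cv,
        ss_total_pct=ss_total,
        ss_ngd_pct=ss_ngd,
        ss_gd_pct=ss_gd,
        cov_row=cov,
        config=cfg.as_dict(),
    )


def summarize(
    segment: EitRecording,
    breaths: BreathTable,
    mask: LungRoiMask,
    config: MetricsConfig | None = None,
) -> AerationMetrics:
    """Full predictor vector for one preprocessed segment."""
    maps = compute_pixel_maps(segment, breaths, mask)
    return metrics_from_maps(
        maps,
        mask,
        body_weight_kg=segment.body_weight_kg,
        normalized=segment.normalized,
        config=config,
    )
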