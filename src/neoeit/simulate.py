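"""Synthetic EIT recordings and cohorts with analytically known truth.

Recordings are synthesized directly in image space (no electrode-level
forward/inverse reconstruction): each lung pixel follows

    value(t) = EELI + TV/2 * (1 - cos(2*pi*f_resp*t)) + cardiac + noise

so its minimum over a breath is exactly its end-expiratory level.  The breath
period is snapped to a whole number of frames, which puts every
end-expiration exactly on a frame index and makes breath-detection and
metric-recovery tests exact.  Ground truth for every metric is computed in
closed form from the noiseless pixel maps through the same formulas the
measurement path uses, so the generator is a true oracle for the
signal-processing pipeline.

Cohorts pair predictor vectors drawn from a multivariate normal with binary
outcomes drawn from a known logistic model, enabling recovery tests for the
regression stage.  One global seed drives a counter-based substream per
subject, so each row is reproducible independently of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import GeometryError, ParameterError
from .io import (
    COHORT_REQUIRED_COLUMNS,
    EitRecording,
    OUTCOME_COLUMNS,
)
from .metrics import AerationMetrics, MetricsConfig, PixelMaps, metrics_from_maps
from .preprocess import AtlasParams, LungRoiMask, build_atlas_mask

PREDICTOR_NAMES = ["aer_pct", "ahr", "cv", "ss_ngd_pct", "ss_gd_pct", "eeli_au_per_kg"]

SILENT_PLACEMENTS = ("dorsal", "ventral", "random")

#: silent pixels oscillate at this fraction of tidal_amp — below the 10%
#: silent threshold but not degenerate zero
SILENT_AMP_FRAC = 0.05


@dataclass
class RecordingScenario:
    """Parameters of one synthetic recording."""

    grid_shape: tuple[int, int] = (32, 32)
    atlas: AtlasParams = field(default_factory=AtlasParams)
    eeli_base: float = 10.0
    gradient_g: float = 1.0
    aerated_fraction: float = 1.0
    tidal_amp: float = 2.0
    tidal_dispersion: float = 0.0
    silent_fraction: float = 0.0
    silent_placement: str = "dorsal"
    resp_rate_per_min: float = 60.0
    cardiac_rate_per_min: float = 150.0
    cardiac_amp: float = 0.0
    noise_sd: float = 0.0
    duration_s: float = 40.0
    frame_rate_hz: float = 51.0
    body_weight_g: float = 1140.0
    subject_id: str = "synthetic"
    eeli_total_target_au: Optional[float] = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("aerated_fraction", "silent_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.silent_placement not in SILENT_PLACEMENTS:
            raise ParameterError(
                f"silent_placement must be one of {SILENT_PLACEMENTS}"
            )
        if not (0.0 <= self.tidal_dispersion <= 0.8):
            # above 0.8 dispersed pixels would cross the 10% silent threshold
            raise ParameterError("tidal_dispersion must lie in [0, 0.8]")
        if self.gradient_g <= 0:
            raise ParameterError("gradient_g must be > 0")
        for name in ("eeli_base", "tidal_amp", "cardiac_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.resp_rate_per_min <= 0 or self.frame_rate_hz <= 0:
            raise ParameterError("rates must be > 0")
        if self.cardiac_rate_per_min < 0:
            raise ParameterError("cardiac_rate_per_min must be >= 0")
        if self.duration_s <= 0 or self.body_weight_g <= 0:
            raise ParameterError("duration_s and body_weight_g must be > 0")

    @property
    def period_frames(self) -> int:
        """Breath period snapped to a whole number of frames."""
        p = int(round(self.frame_rate_hz * 60.0 / self.resp_rate_per_min))
        return max(p, 2)

    @property
    def effective_resp_rate_per_min(self) -> float:
        return 60.0 * self.frame_rate_hz / self.period_frames


@dataclass
class ScenarioTruth:
    """Closed-form ground truth for one scenario (from noiseless maps)."""

    true_aer_pct: float
    true_ahr: float
    true_cv: float
    true_ss_total_pct: float
    true_ss_ngd_pct: float
    true_ss_gd_pct: float
    true_eeli_au_per_kg: float
    cov_row: float
    period_frames: int
    effective_resp_rate_per_min: float
    n_breaths: int
    end_exp_frames: np.ndarray
    maps: PixelMaps

    def as_metrics(self) -> AerationMetrics:
        return AerationMetrics(
            eeli_au_per_kg=self.true_eeli_au_per_kg,
            aer_pct=self.true_aer_pct,
            ahr=self.true_ahr,
            cv=self.true_cv,
            ss_total_pct=self.true_ss_total_pct,
            ss_ngd_pct=self.true_ss_ngd_pct,
            ss_gd_pct=self.true_ss_gd_pct,
            cov_row=self.cov_row,
        )


def _solve_gradient_tilt(
    eeli_flat: np.ndarray,
    x: np.ndarray,
    wv: np.ndarray,
    target: float,
) -> float:
    """Find the exponential row-tilt gamma with ventral/dorsal ratio = target.

    Pixel EELI is multiplied by exp(gamma * x) where x runs 1 (ventral-most
    lung row) to 0 (dorsal-most); the weighted ventral/dorsal sum ratio is
    strictly increasing in gamma.
    """

    def ratio(gamma: float) -> float:
        m = eeli_flat * np.exp(gamma * x)
        ventral = float(np.sum(m * wv))
        dorsal = float(np.sum(m * (1.0 - wv)))
        return ventral / dorsal

    lo, hi = -60.0, 60.0
    rlo, rhi = ratio(lo), ratio(hi)
    if not (rlo < target < rhi):
        raise ParameterError(
            f"gradient_g={target} unreachable for this lung geometry"
        )
    gamma = brentq(
        lambda g: math.log(ratio(g)) - math.log(target),
        lo,
        hi,
        xtol=1e-13,
        rtol=8.9e-16,
        maxiter=200,
    )
    return float(gamma)


def make_recording(
    scn: RecordingScenario,
) -> tuple[EitRecording, LungRoiMask, ScenarioTruth]:
    """Synthesize one recording plus its lung mask and metric ground truth."""
    scn.validate()
    try:
        mask = build_atlas_mask(scn.grid_shape, scn.atlas)
    except GeometryError:
        raise
    rng = np.random.default_rng(np.random.SeedSequence(scn.seed))
    lung_r, lung_c = np.nonzero(mask.in_lung)
    n_lung = lung_r.size

    # --- aeration: which lung pixels carry nonzero EELI
    n_aer = int(round(scn.aerated_fraction * n_lung))
    if n_aer < 2:
        raise ParameterError("aerated_fraction leaves fewer than 2 aerated pixels")
    aer_idx = np.sort(rng.choice(n_lung, size=n_aer, replace=False))
    aerated = np.zeros(n_lung, dtype=bool)
    aerated[aer_idx] = True

    # --- EELI map with the ventral/dorsal gradient
    pos_x = (mask.row_max - lung_r) / max(mask.row_max - mask.row_min, 1)
    wv_pix = mask.ventral_weight[lung_r]
    base = np.where(aerated, 1.0, 0.0)
    if (base * wv_pix).sum() == 0 or (base * (1 - wv_pix)).sum() == 0:
        raise ParameterError(
            "aerated pixels must occur in both ventral and dorsal halves"
        )
    gamma = _solve_gradient_tilt(base, pos_x, wv_pix, scn.gradient_g)
    eeli_flat = scn.eeli_base * base * np.exp(gamma * pos_x)
    if scn.eeli_total_target_au is not None:
        total = eeli_flat.sum()
        if total <= 0:
            raise ParameterError("cannot rescale an all-zero EELI map")
        eeli_flat *= scn.eeli_total_target_au / total

    # --- tidal-variation map: silent pixels, dispersion
    n_silent = int(math.ceil(scn.silent_fraction * n_lung))
    if n_silent > n_aer:
        raise ParameterError(
            "silent_fraction exceeds aerated_fraction: silent pixels are "
            "drawn from aerated pixels only"
        )
    silent = np.zeros(n_lung, dtype=bool)
    if n_silent > 0:
        if scn.silent_placement == "dorsal":
            order = aer_idx[np.argsort(lung_r[aer_idx], kind="stable")[::-1]]
        elif scn.silent_placement == "ventral":
            order = aer_idx[np.argsort(lung_r[aer_idx], kind="stable")]
        else:
            order = rng.permutation(aer_idx)
        silent[order[:n_silent]] = True

    amp_flat = np.zeros(n_lung)
    vented = aerated & ~silent
    if scn.tidal_dispersion > 0 and vented.sum() > 1:
        z = rng.standard_normal(int(vented.sum()))
        z = z - z.mean()
        zmax = np.max(np.abs(z))
        if zmax > 0:
            z = z / zmax
        amp_flat[vented] = scn.tidal_amp * (1.0 + scn.tidal_dispersion * z)
    else:
        amp_flat[vented] = scn.tidal_amp
    amp_flat[silent] = SILENT_AMP_FRAC * scn.tidal_amp

    # --- ground truth straight from the noiseless maps
    rows, cols = scn.grid_shape
    eeli_map = np.full((rows, cols), np.nan)
    tv_map = np.full((rows, cols), np.nan)
    eeli_map[lung_r, lung_c] = eeli_flat
    tv_map[lung_r, lung_c] = amp_flat
    maps = PixelMaps(eeli=eeli_map, tv=tv_map)
    weight_kg = scn.body_weight_g / 1000.0
    truth_metrics = metrics_from_maps(
        maps, mask, body_weight_kg=weight_kg, normalized=False,
        config=MetricsConfig(),
    )

    # --- frame synthesis
    n_frames = int(round(scn.duration_s * scn.frame_rate_hz))
    p = scn.period_frames
    i = np.arange(n_frames)
    waveform = 0.5 * (1.0 - np.cos(2.0 * np.pi * i / p))
    frames = np.zeros((n_frames, rows, cols))
    frames[:, lung_r, lung_c] = (
        eeli_flat[None, :] + amp_flat[None, :] * waveform[:, None]
    )
    if scn.cardiac_amp > 0 and scn.cardiac_rate_per_min > 0:
        f_card = scn.cardiac_rate_per_min / 60.0
        cardiac = scn.cardiac_amp * np.sin(
            2.0 * np.pi * f_card * i / scn.frame_rate_hz
        )
        frames[:, lung_r, lung_c] += cardiac[:, None]
    if scn.noise_sd > 0:
        frames += rng.normal(0.0, scn.noise_sd, size=frames.shape)

    rec = EitRecording(
        frames=frames.astype(np.float32),
        frame_rate_hz=scn.frame_rate_hz,
        subject_id=scn.subject_id,
        body_weight_g=scn.body_weight_g,
    )
    end_exp = np.arange(0, n_frames, p)
    truth = ScenarioTruth(
        true_aer_pct=truth_metrics.aer_pct,
        true_ahr=truth_metrics.ahr,
        true_cv=truth_metrics.cv,
        true_ss_total_pct=truth_metrics.ss_total_pct,
        true_ss_ngd_pct=truth_metrics.ss_ngd_pct,
        true_ss_gd_pct=truth_metrics.ss_gd_pct,
        true_eeli_au_per_kg=truth_metrics.eeli_au_per_kg,
        cov_row=truth_metrics.cov_row,
        period_frames=p,
        effective_resp_rate_per_min=scn.effective_resp_rate_per_min,
        n_breaths=(n_frames - 1) // p,
        end_exp_frames=end_exp,
        maps=maps,
    )
    return rec, mask, truth


def sample_recording_scenario(seed: int) -> RecordingScenario:
    """Draw a random noiseless scenario for oracle/recovery testing.

    Tidal amplitude is drawn as 20-50% of the EELI baseline — the
    physiological regime — which also keeps float32 container quantization
    of the tidal-difference maps two orders of magnitude below the 1e-6
    oracle tolerance.
    """
    rng = np.random.default_rng(seed)
    aerated = float(rng.uniform(0.6, 1.0))
    eeli_base = float(rng.uniform(5.0, 20.0))
    return RecordingScenario(
        gradient_g=float(rng.uniform(0.5, 2.5)),
        aerated_fraction=aerated,
        silent_fraction=float(rng.uniform(0.0, aerated - 0.35)),
        silent_placement=str(rng.choice(["dorsal", "ventral", "random"])),
        tidal_dispersion=float(rng.uniform(0.0, 0.6)),
        eeli_base=eeli_base,
        tidal_amp=eeli_base * float(rng.uniform(0.2, 0.5)),
        resp_rate_per_min=float(rng.uniform(40.0, 80.0)),
        duration_s=float(rng.uniform(31.0, 35.0)),
        body_weight_g=float(rng.uniform(700.0, 1800.0)),
        noise_sd=0.0,
        cardiac_amp=0.0,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# cohorts


def _default_predictor_means() -> dict[str, float]:
    return {
        "aer_pct": 60.0,
        "ahr": 1.0,
        "cv": 0.5,
        "ss_ngd_pct": 8.0,
        "ss_gd_pct": 12.0,
        "eeli_au_per_kg": 30.0,
    }


def _default_predictor_sds() -> dict[str, float]:
    return {
        "aer_pct": 15.0,
        "ahr": 0.3,
        "cv": 0.15,
        "ss_ngd_pct": 5.0,
        "ss_gd_pct": 6.0,
        "eeli_au_per_kg": 10.0,
    }


def default_coefficients(
    predictor_means: dict[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Log-odds models for the three outcomes.

    Oxygen dependency at 28 days uses effect sizes of 0.8 per Aer% point and
    9.58 per AHR unit (odds-ratio scale) with the intercept balancing
    prevalence at 0.5 for an average infant; early failure is a weak Aer%
    effect at ~22% prevalence; moderate/severe BPD is a rare null outcome.
    """
    m = predictor_means or _default_predictor_means()
    b_aer_o2 = math.log(0.8)
    b_ahr_o2 = math.log(9.58)
    b_aer_ef = math.log(0.86)
    return {
        "outcome_early_failure_24h": {
            "intercept": float(logit(7.0 / 32.0) - b_aer_ef * m["aer_pct"]),
            "aer_pct": b_aer_ef,
        },
        "outcome_oxygen_28d": {
            "intercept": float(-(b_aer_o2 * m["aer_pct"] + b_ahr_o2 * m["ahr"])),
            "aer_pct": b_aer_o2,
            "ahr": b_ahr_o2,
        },
        "outcome_bpd_mod_severe": {
            "intercept": float(logit(1.0 / 32.0)),
        },
    }


@dataclass
class CohortScenario:
    """Parameters of one synthetic cohort."""

    n_subjects: int = 32
    predictor_means: dict[str, float] = field(default_factory=_default_predictor_means)
    predictor_sds: dict[str, float] = field(default_factory=_default_predictor_sds)
    correlation: Optional[np.ndarray] = None
    coefficients: Optional[dict[str, dict[str, float]]] = None
    ga_mean_weeks: float = 29.6
    ga_sd_weeks: float = 1.8
    bw_mean_g: float = 1140.0
    bw_sd_g: float = 355.0
    p_male: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        missing = [k for k in PREDICTOR_NAMES if k not in self.predictor_means]
        if missing:
            raise ParameterError(f"predictor_means missing: {missing}")
        missing = [k for k in PREDICTOR_NAMES if k not in self.predictor_sds]
        if missing:
            raise ParameterError(f"predictor_sds missing: {missing}")
        if not (0.0 <= self.p_male <= 1.0):
            raise ParameterError("p_male must lie in [0, 1]")

    def resolved_coefficients(self) -> dict[str, dict[str, float]]:
        return self.coefficients or default_coefficients(self.predictor_means)

    def cholesky(self) -> np.ndarray:
        k = len(PREDICTOR_NAMES)
        corr = self.correlation if self.correlation is not None else np.eye(k)
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (k, k):
            raise ParameterError(f"correlation must be {k}x{k}")
        try:
            return np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("correlation matrix not positive definite") from exc


_CLIP_BOUNDS = {
    "aer_pct": (0.0, 100.0),
    "ahr": (0.01, None),
    "cv": (0.0, None),
    "ss_ngd_pct": (0.0, 100.0),
    "ss_gd_pct": (0.0, 100.0),
    "eeli_au_per_kg": (0.0, None),
}


def subject_rng(seed: int, subject_index: int, stream: int = 0) -> np.random.Generator:
    """Independent, order-free substream for one subject."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_index, stream))
    )


def make_cohort(cs: CohortScenario):
    """Generate a cohort table plus a truth record of the generating model.

    Outcomes are Bernoulli(logistic(eta)) with eta evaluated on the clipped
    predictor values actually written to the table, so the logistic model
    holds exactly for the emitted data.
    """
    import pandas as pd

    cs.validate()
    chol = cs.cholesky()
    coeffs = cs.resolved_coefficients()
    means = np.array([cs.predictor_means[k] for k in PREDICTOR_NAMES])
    sds = np.array([cs.predictor_sds[k] for k in PREDICTOR_NAMES])

    rows = []
    for i in range(cs.n_subjects):
        rng = subject_rng(cs.seed, i)
        z = chol @ rng.standard_normal(len(PREDICTOR_NAMES))
        vals = means + sds * z
        rec: dict[str, object] = {"subject_id": f"S{i:04d}"}
        for name, v in zip(PREDICTOR_NAMES, vals):
            lo, hi = _CLIP_BOUNDS[name]
            v = max(v, lo) if lo is not None else v
            v = min(v, hi) if hi is not None else v
            rec[name] = float(v)
        ga = max(float(rng.normal(cs.ga_mean_weeks, cs.ga_sd_weeks)), 23.0)
        bw = max(float(rng.normal(cs.bw_mean_g, cs.bw_sd_g)), 400.0)
        sex = "male" if rng.random() < cs.p_male else "female"
        rec.update(
            gestational_age_weeks=ga, birth_weight_g=bw, sex=sex
        )
        u = rng.random(len(OUTCOME_COLUMNS))
        for j, outcome in enumerate(OUTCOME_COLUMNS):
            beta = coeffs.get(outcome, {"intercept": 0.0})
            eta = beta.get("intercept", 0.0)
            for term, slope in beta.items():
                if term == "intercept":
                    continue
                if term == "sex":
                    eta += slope * (1.0 if sex == "male" else 0.0)
                else:
                    eta += slope * float(rec[term])
            rec[outcome] = int(u[j] < expit(eta))
        rows.append(rec)

    table = pd.DataFrame(rows)[COHORT_REQUIRED_COLUMNS]
    truth = {
        "coefficients": coeffs,
        "seed": cs.seed,
        "n_subjects": cs.n_subjects,
        "prevalence": {
            o: float(table[o].mean()) for o in OUTCOME_COLUMNS
        },
    }
    return table, truth
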