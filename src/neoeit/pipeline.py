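"""Pipeline orchestration: simulate -> extract -> fit.

Each stage is a plain function consumed by the CLI.  ``simulate`` writes one
recording container per subject plus the cohort CSV (clinical covariates,
outcomes, and the generator-truth metric columns); ``extract`` re-measures
the metric columns from the frames, isolating per-subject failures; ``fit``
produces the univariate odds-ratio table and the three-model ROC comparison.
Every output carries a provenance block (config hash, seed, version) and no
timestamps, so a fixed config+seed reproduces outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import NeoEitError, ParameterError
from .io import (
    EIT_PREDICTORS,
    OUTCOME_COLUMNS,
    read_cohort,
    read_recording,
    write_cohort,
    write_recording,
)
from .metrics import summarize
from .models import compare_models, univariate_screen
from .preprocess import (
    apply_mask,
    build_atlas_mask,
    detect_breaths,
    normalize_by_weight,
    select_segment,
)
from .simulate import RecordingScenario, make_cohort, subject_rng

log = logging.getLogger("neoeit")

METRIC_COLUMNS = ["aer_pct", "ahr", "cv", "ss_ngd_pct", "ss_gd_pct", "eeli_au_per_kg"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _check_overwrite(path: Path, overwrite: bool) -> None:
    if path.exists() and not overwrite:
        raise NeoEitError(
            f"{path} exists; pass --overwrite to replace existing outputs"
        )


def scenario_for_subject(
    row: pd.Series, index: int, config: PipelineConfig
) -> RecordingScenario:
    """Derive a recording scenario that realizes one cohort row's metrics.

    The mapping is heuristic: AHR becomes the EELI gradient, Aer% the
    aerated fraction, the silent-space total (minus the unaerated part,
    which is silent anyway) the planted silent fraction placed toward the
    heavier silent side, CV the tidal-amplitude dispersion, and the EELI/kg
    target a post-hoc map rescale.  ``extract`` then measures what the frames
    actually contain.
    """
    aerated = float(np.clip(row["aer_pct"] / 100.0, 0.2, 1.0))
    ss_total = (float(row["ss_ngd_pct"]) + float(row["ss_gd_pct"])) / 100.0
    planted = max(0.0, ss_total - (1.0 - aerated))
    silent = float(np.clip(planted, 0.0, max(aerated - 0.05, 0.0)))
    placement = "dorsal" if row["ss_gd_pct"] >= row["ss_ngd_pct"] else "ventral"
    rng = subject_rng(config.seed, index, stream=1)
    resp_rate = float(rng.uniform(40.0, 80.0))
    sub_seed = int(
        np.random.SeedSequence(
            entropy=config.seed, spawn_key=(index, 2)
        ).generate_state(1)[0]
        % (2**31)
    )
    weight_kg = float(row["birth_weight_g"]) / 1000.0
    return config.recording_scenario(
        gradient_g=float(np.clip(row["ahr"], 0.2, 5.0)),
        aerated_fraction=aerated,
        silent_fraction=silent,
        silent_placement=placement,
        tidal_dispersion=float(np.clip(row["cv"], 0.0, 0.8)),
        eeli_total_target_au=float(row["eeli_au_per_kg"]) * weight_kg,
        body_weight_g=float(row["birth_weight_g"]),
        resp_rate_per_min=resp_rate,
        subject_id=str(row["subject_id"]),
        seed=sub_seed,
    )


def run_simulate(config: PipelineConfig, overwrite: bool = False) -> dict:
    """Generate the cohort and one recording container per subject."""
    out = Path(config.output_dir)
    rec_dir = out / "recordings"
    cohort_path = out / "cohort.csv"
    _check_overwrite(cohort_path, overwrite)
    if not out.exists():
        log.info("creating output directory %s", out)
    rec_dir.mkdir(parents=True, exist_ok=True)

    cohort, truth = make_cohort(config.cohort_scenario())
    manifest: dict = {
        "provenance": config.provenance(),
        "cohort_truth": truth,
        "subjects": [],
    }
    for i, (_, row) in enumerate(cohort.iterrows()):
        try:
            scn = scenario_for_subject(row, i, config)
        except ParameterError as exc:
            raise ParameterError(
                f"subject {row['subject_id']} (row {i}): {exc}"
            ) from exc
        from .simulate import make_recording

        rec, _, _ = make_recording(scn)
        sidecar = write_recording(rec, rec_dir / str(row["subject_id"]))
        framefile = sidecar.with_suffix(".eitf")
        manifest["subjects"].append(
            {
                "subject_id": str(row["subject_id"]),
                "scenario_seed": scn.seed,
                "files": {
                    sidecar.name: _sha256(sidecar),
                    framefile.name: _sha256(framefile),
                },
            }
        )
    write_cohort(cohort, cohort_path, provenance=config.provenance())
    manifest["cohort_csv"] = _sha256(cohort_path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    log.info("simulated %d subjects into %s", len(cohort), out)
    return manifest


def process_recording(rec, config: PipelineConfig):
    """Preprocess one recording and return its AerationMetrics."""
    mask = build_atlas_mask(rec.frame_shape)
    masked = apply_mask(rec, mask)
    norm = normalize_by_weight(masked)
    seg = select_segment(
        norm,
        config.segment.t_start_s,
        config.segment.duration_s,
        z_limit=config.segment.z_limit,
        min_frac_within=config.segment.min_frac_within,
        artefact_hard_fail=config.segment.artefact_hard_fail,
    )
    if seg.artefact_flag:
        raise NeoEitError("segment flagged artefactual")
    breaths = detect_breaths(
        seg,
        lowpass_hz=config.segment.lowpass_hz,
        lowpass_order=config.segment.lowpass_order,
        prominence_frac=config.segment.prominence_frac,
    )
    return summarize(seg, breaths, mask, config.metrics)


def run_extract(config: PipelineConfig, overwrite: bool = False) -> pd.DataFrame:
    """Measure metric columns from the recordings; isolate failures."""
    out = Path(config.output_dir)
    rec_dir = Path(config.input_dir) if config.input_dir else out / "recordings"
    cohort = read_cohort(out / "cohort.csv")
    measured_path = out / "cohort_measured.csv"
    _check_overwrite(measured_path, overwrite)

    rows, failures = [], {}
    for _, row in cohort.iterrows():
        sid = str(row["subject_id"])
        try:
            rec = read_recording(rec_dir / sid)
            metrics = process_recording(rec, config)
        except NeoEitError as exc:
            failures[sid] = f"{type(exc).__name__}: {exc}"
            log.warning("subject %s failed: %s", sid, exc)
            continue
        new = row.copy()
        for k, v in metrics.as_row().items():
            new[k] = v
        rows.append(new)
    if not rows:
        raise NeoEitError("no subject processed successfully")
    measured = pd.DataFrame(rows).reset_index(drop=True)
    write_cohort(measured, measured_path, provenance=config.provenance())
    (out / "extract_failures.json").write_text(
        json.dumps(
            {"provenance": config.provenance(), "failures": failures},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    log.info("extracted %d subjects (%d failures)", len(rows), len(failures))
    return measured


def run_fit(config: PipelineConfig, overwrite: bool = False) -> dict:
    """Univariate odds-ratio table plus the three-model ROC comparison."""
    out = Path(config.output_dir)
    cohort_path = out / "cohort_measured.csv"
    if not cohort_path.exists():
        cohort_path = out / "cohort.csv"
    cohort = read_cohort(cohort_path)
    table_path = out / "or_table.csv"
    _check_overwrite(table_path, overwrite)

    screen = univariate_screen(
        cohort,
        EIT_PREDICTORS,
        alpha=config.models.alpha,
        standardize=config.models.standardize,
    )
    prov = config.provenance()
    header = "".join(f"# {k}={prov[k]}\n" for k in sorted(prov))
    table_path.write_text(header + screen.to_csv(index=False))

    comparisons: dict = {"provenance": prov, "outcomes": {}}
    for outcome in OUTCOME_COLUMNS:
        events = int(cohort[outcome].sum())
        non_events = int(len(cohort) - events)
        if min(events, non_events) < config.models.min_events_comparison:
            comparisons["outcomes"][outcome] = {
                "skipped": True,
                "reason": f"only {min(events, non_events)} events in the "
                "smaller class; model comparison requires "
                f">= {config.models.min_events_comparison}",
            }
            log.warning(
                "skipping model comparison for %s (%d events)", outcome, events
            )
            continue
        comparisons["outcomes"][outcome] = compare_models(
            cohort,
            outcome,
            standardize=config.models.standardize,
            cross_validate=config.models.cross_validate,
            seed=config.seed,
        )
    (out / "model_comparison.json").write_text(
        json.dumps(comparisons, indent=2, sort_keys=True) + "\n"
    )
    log.info("fit stage complete: %s", out)
    return {"screen": screen, "comparisons": comparisons}


def run_all(config: PipelineConfig, overwrite: bool = False) -> dict:
    run_simulate(config, overwrite)
    run_extract(config, overwrite)
    return run_fit(config, overwrite)
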