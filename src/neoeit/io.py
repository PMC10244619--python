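"""Containers and on-disk formats for EIT recordings and cohort tables.

A recording is stored as two files sharing a stem: ``<stem>.json`` (metadata
sidecar) and ``<stem>.eitf`` (raw little-endian float32 frames, frame-major,
row-major within a frame).  The format is deliberately minimal: bit-exact,
language agnostic and streamable.  Cohorts are plain UTF-8 CSV with a fixed
set of required columns; lines starting with ``#`` are provenance comments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import CorruptionError, SchemaError, ValidationError

PathLike = Union[str, Path]

POSITIONS = ("supine",)
ROW_ORIENTATIONS = ("ventral_first",)

#: columns every cohort table must carry, in canonical order
COHORT_REQUIRED_COLUMNS = [
    "subject_id",
    "gestational_age_weeks",
    "sex",
    "birth_weight_g",
    "aer_pct",
    "ahr",
    "cv",
    "ss_ngd_pct",
    "ss_gd_pct",
    "eeli_au_per_kg",
    "outcome_early_failure_24h",
    "outcome_oxygen_28d",
    "outcome_bpd_mod_severe",
]

OUTCOME_COLUMNS = [
    "outcome_early_failure_24h",
    "outcome_oxygen_28d",
    "outcome_bpd_mod_severe",
]

EIT_PREDICTORS = ["aer_pct", "ahr", "cv", "ss_ngd_pct", "ss_gd_pct"]
CLINICAL_PREDICTORS = ["gestational_age_weeks", "sex", "birth_weight_g"]

_PCT_COLUMNS = ("aer_pct", "ss_ngd_pct", "ss_gd_pct")
_NONNEG_COLUMNS = ("ahr", "cv", "eeli_au_per_kg")


@dataclass
class EitRecording:
    """A time-ordered stack of 2D impedance frames plus subject metadata.

    ``frames`` is indexed ``(time, row, column)`` in arbitrary units (AU);
    row 0 is ventral (non-gravity-dependent in supine), the last row dorsal.
    """

    frames: np.ndarray
    frame_rate_hz: float
    subject_id: str
    body_weight_g: float
    position: str = "supine"
    row_orientation: str = "ventral_first"
    normalized: bool = False
    artefact_flag: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.validate()

    def validate(self) -> None:
        if self.frames.ndim != 3:
            raise ValidationError("frames: expected (time, row, column) array")
        if self.frames.shape[1] < 2 or self.frames.shape[2] < 2:
            raise ValidationError("frames: frame shape must be at least (2, 2)")
        if not (self.frame_rate_hz > 0):
            raise ValidationError("frame_rate_hz: must be > 0")
        if not (self.body_weight_g > 0):
            raise ValidationError("body_weight_g: must be > 0")
        if self.position not in POSITIONS:
            raise ValidationError(f"position: must be one of {POSITIONS}")
        if self.row_orientation not in ROW_ORIENTATIONS:
            raise ValidationError(
                f"row_orientation: must be one of {ROW_ORIENTATIONS}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def body_weight_kg(self) -> float:
        return self.body_weight_g / 1000.0

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def copy_with(self, **changes) -> "EitRecording":
        return replace(self, **changes)


def _paths(path: PathLike) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".json", ".eitf"):
        base = base.with_suffix("")
    return base.with_suffix(".json"), base.with_suffix(".eitf")


def write_recording(rec: EitRecording, path: PathLike) -> Path:
    """Write ``<stem>.json`` + ``<stem>.eitf``; returns the sidecar path."""
    rec.validate()
    sidecar, framefile = _paths(path)
    meta = {
        "format": "neoeit-frames",
        "format_version": 1,
        "dtype": "float32",
        "byte_order": "little",
        "n_frames": int(rec.n_frames),
        "n_rows": int(rec.frames.shape[1]),
        "n_cols": int(rec.frames.shape[2]),
        "frame_rate_hz": float(rec.frame_rate_hz),
        "subject_id": str(rec.subject_id),
        "body_weight_g": float(rec.body_weight_g),
        "position": rec.position,
        "row_orientation": rec.row_orientation,
        "normalized": bool(rec.normalized),
    }
    sidecar.parent.mkdir(parents=True, exist_ok=True)
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    framefile.write_bytes(
        np.ascontiguousarray(rec.frames, dtype="<f4").tobytes()
    )
    return sidecar


_SIDECAR_REQUIRED = (
    "n_frames",
    "n_rows",
    "n_cols",
    "frame_rate_hz",
    "subject_id",
    "body_weight_g",
)


def read_recording(path: PathLike) -> EitRecording:
    """Read a sidecar + frame-file pair written by :func:`write_recording`."""
    sidecar, framefile = _paths(path)
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar {sidecar}")
    if not framefile.exists():
        raise CorruptionError(f"missing frame file {framefile}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise SchemaError(f"sidecar missing fields: {', '.join(missing)}")
    n, r, c = int(meta["n_frames"]), int(meta["n_rows"]), int(meta["n_cols"])
    payload = framefile.read_bytes()
    expected = 4 * n * r * c
    if len(payload) != expected:
        raise CorruptionError(
            f"frame file has {len(payload)} bytes, sidecar implies {expected}"
        )
    frames = np.frombuffer(payload, dtype="<f4").reshape(n, r, c)
    return EitRecording(
        frames=frames.copy(),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        subject_id=str(meta["subject_id"]),
        body_weight_g=float(meta["body_weight_g"]),
        position=meta.get("position", "supine"),
        row_orientation=meta.get("row_orientation", "ventral_first"),
        normalized=bool(meta.get("normalized", False)),
    )


def validate_cohort(table: pd.DataFrame) -> None:
    """Check required columns and domain invariants of a cohort table."""
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort missing columns: {', '.join(missing)}")
    if len(table) == 0:
        return
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"subject_id: duplicate value {dup!r}")
    bad_sex = set(table["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValidationError(f"sex: invalid values {sorted(bad_sex)}")
    for col in OUTCOME_COLUMNS:
        vals = table[col]
        if not vals.isin([0, 1]).all():
            raise ValidationError(f"{col}: outcomes must be 0 or 1")
    for col in _PCT_COLUMNS:
        v = table[col].astype(float)
        if ((v < 0) | (v > 100)).any():
            raise ValidationError(f"{col}: percentages must lie in [0, 100]")
    for col in _NONNEG_COLUMNS:
        if (table[col].astype(float) < 0).any():
            raise ValidationError(f"{col}: must be non-negative")
    for col in ("gestational_age_weeks", "birth_weight_g"):
        if (table[col].astype(float) <= 0).any():
            raise ValidationError(f"{col}: must be positive")


def read_cohort(path: PathLike) -> pd.DataFrame:
    """Read and validate a cohort CSV (``#`` lines are comments)."""
    table = pd.read_csv(path, comment="#")
    validate_cohort(table)
    for col in OUTCOME_COLUMNS:
        if len(table):
            table[col] = table[col].astype(int)
    return table


def write_cohort(
    table: pd.DataFrame, path: PathLike, provenance: dict | None = None
) -> Path:
    """Write a validated cohort CSV, optionally with a provenance header."""
    validate_cohort(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # canonical order first, unknown columns preserved after
    extra = [c for c in table.columns if c not in COHORT_REQUIRED_COLUMNS]
    ordered = table[COHORT_REQUIRED_COLUMNS + extra]
    header = ""
    if provenance:
        header = "".join(
            f"# {k}={provenance[k]}\n" for k in sorted(provenance)
        )
    csv = ordered.to_csv(index=False)
    path.write_text(header + csv)
    return path


def frame_file_n_bytes(rec: EitRecording) -> int:
    """Exact byte size of the frame payload for *rec*."""
    return 4 * int(math.prod(rec.frames.shape))
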