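"""CSV readers/writers, run configuration and provenance records.

All tables are comma-separated UTF-8 with a header row; an empty field
means missing.  Day indices are 1-based integers per participant; calendar
dates (ISO-8601) in the ``day`` column are converted to indices on read,
counted from each participant's first date.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .preprocessing import Episode

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_behavior_log",
    "write_behavior_log",
    "read_surveys",
    "write_surveys",
    "read_episodes",
    "load_run_config",
    "provenance_record",
]

LOG_COLUMNS = ["participant_id", "day", "beh", "cue", "rem", "lab"]
SURVEY_COLUMNS = [
    "participant_id", "day", "srbai", "att_instrumental", "att_affective",
    "self_report_rate",
]


class ValidationError(ValueError):
    """A malformed or out-of-range field in an input table."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _to_day_index(df: pd.DataFrame) -> pd.DataFrame:
    """Accept integer day indices or ISO dates; normalize to 1-based ints."""
    try:
        df["day"] = df["day"].astype(int)
        return df
    except (ValueError, TypeError):
        pass
    dates = pd.to_datetime(df["day"], format="ISO8601")
    first = dates.groupby(df["participant_id"]).transform("min")
    df["day"] = (dates - first).dt.days + 1
    return df


def _validate_binary(df: pd.DataFrame, col: str, path, allow_missing: bool = False) -> None:
    vals = df[col]
    bad = ~(vals.isin([0, 1]) | (vals.isna() if allow_missing else False))
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValidationError(
            f"{path}: line {line}: column {col!r} must be 0 or 1"
            f"{' or empty' if allow_missing else ''}, got {vals[bad].iloc[0]!r}"
        )


def read_behavior_log(path) -> pd.DataFrame:
    """Read a day-level behavior log.

    Expected header: ``participant_id, day, beh, cue, rem, lab`` (``cue``
    optional, defaulting to 1 under the constant-context assumption; empty
    ``beh`` marks a missing day).
    """
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id", "day", "beh", "rem", "lab"], path)
    df = _to_day_index(df)
    if "cue" not in df.columns:
        df["cue"] = 1
    df["cue"] = df["cue"].fillna(1)
    for col in ("beh",):
        _validate_binary(df, col, path, allow_missing=True)
    for col in ("cue", "rem", "lab"):
        _validate_binary(df, col, path)
    return df[LOG_COLUMNS]


def write_behavior_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=LOG_COLUMNS, float_format="%.10g")


def read_surveys(path) -> pd.DataFrame:
    """Read weekly survey records; scale bounds are enforced on read."""
    df = pd.read_csv(path)
    _check_columns(df, SURVEY_COLUMNS, path)
    df = _to_day_index(df)
    for col in ("srbai", "att_instrumental", "att_affective"):
        vals = df[col]
        bad = vals.notna() & ((vals < 1) | (vals > 7))
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValidationError(
                f"{path}: line {line}: {col!r} must lie in [1, 7], got {vals[bad].iloc[0]!r}"
            )
    rate = df["self_report_rate"]
    bad = rate.notna() & ((rate < 0) | (rate > 1))
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValidationError(
            f"{path}: line {line}: 'self_report_rate' must lie in [0, 1], "
            f"got {rate[bad].iloc[0]!r}"
        )
    return df[SURVEY_COLUMNS]


def write_surveys(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SURVEY_COLUMNS, float_format="%.10g")


def read_episodes(path) -> list[Episode]:
    """Read timestamped brushing episodes (``participant_id, start_iso8601``)."""
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id", "start_iso8601"], path)
    episodes = []
    for idx, row in df.iterrows():
        try:
            start = dt.datetime.fromisoformat(str(row["start_iso8601"]))
        except ValueError as exc:
            raise ValidationError(
                f"{path}: line {int(idx) + 2}: bad timestamp {row['start_iso8601']!r}"
            ) from exc
        episodes.append(Episode(str(row["participant_id"]), start))
    return episodes


class RunConfig(BaseModel):
    """Validated configuration for an evaluation run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    logs: str
    surveys: str | None = None
    output_dir: str = "habitdyn_out"
    models: list[str] = Field(
        default_factory=lambda: ["survey", "past_br", "past_br7", "weighted_br", "theory"]
    )
    k: int = 5
    seed: int = 0
    random_search_steps: int = 1000
    grid_search_steps: int = 100
    ridge: float = 0.0

    @field_validator("models")
    @classmethod
    def _known_models(cls, v: list[str]) -> list[str]:
        from .features import MODEL_NAMES

        unknown = [m for m in v if m not in MODEL_NAMES]
        if unknown:
            raise ValueError(f"unknown model(s) {unknown}; expected {list(MODEL_NAMES)}")
        return v

    @field_validator("k")
    @classmethod
    def _k_min(cls, v: int) -> int:
        if v < 2:
            raise ValueError("k must be at least 2")
        return v


def load_run_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    return RunConfig(**data)


def provenance_record(command: str, config: dict[str, Any]) -> dict[str, Any]:
    """Machine-readable record sufficient to re-execute a run exactly."""
    import sklearn

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "command": command,
        "config": json.loads(blob),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {
            "habitdyn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
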