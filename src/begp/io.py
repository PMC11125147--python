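"""Reading long-format HR tables and validating run configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import DayRecord, ModelConfig

__all__ = ["read_timeseries", "RunConfig", "load_config", "SchemaError"]

logger = logging.getLogger("begp")

REQUIRED_COLUMNS = ("subject_id", "day", "time_hours", "hr_bpm")

#: physiological plausibility window applied on ingest (bpm)
HR_RANGE = (20.0, 260.0)


class SchemaError(ValueError):
    """Input table or config violates the expected schema."""


def read_timeseries(
    path: str | Path, hr_range: tuple[float, float] | None = HR_RANGE
) -> dict[str, list[DayRecord]]:
    """Read a long-format HR CSV into per-subject lists of day records.

    Expects header ``subject_id,day,time_hours,hr_bpm`` with decimal hours
    in [0, 24]; missing periods are simply absent rows. Non-finite values
    and HR outside the plausibility window are dropped with a logged count
    (pass ``hr_range=None`` to disable the filter).
    """
    path = Path(path)
    # exact float parsing: the default fast parser is off by ~1 ulp
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise SchemaError(f"{path}: empty input file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    n_before = len(df)
    finite = np.isfinite(df["hr_bpm"]) & np.isfinite(df["time_hours"])
    df = df[finite]
    if hr_range is not None:
        lo, hi = hr_range
        df = df[(df["hr_bpm"] >= lo) & (df["hr_bpm"] <= hi)]
    dropped = n_before - len(df)
    if dropped:
        logger.info(
            "%s: dropped %d row(s) with non-finite or implausible values",
            path,
            dropped,
        )
    out: dict[str, list[DayRecord]] = {}
    for (subject, day), group in df.groupby(["subject_id", "day"], sort=True):
        out.setdefault(str(subject), []).append(
            DayRecord(
                day_index=int(day),
                timestamps=group["time_hours"].to_numpy(dtype=float),
                values=group["hr_bpm"].to_numpy(dtype=float),
            )
        )
    return out


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: model, simulate and evaluate blocks."""

    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    simulate: dict = dataclasses.field(default_factory=dict)
    evaluate: dict = dataclasses.field(default_factory=dict)
    io: dict = dataclasses.field(default_factory=dict)
    seed: int = 0


_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}
_SIM_KEYS = {
    "n_days",
    "samples_per_day",
    "noise_sd",
    "artifact_rate",
    "artifact_sd",
    "artifact_positive_bias",
    "missing_rate",
    "missing_block_hours",
    "missing_mode",
    "ecg_noise_sd",
    "ecg_missing_rate",
    "n_subjects",
}
_EVAL_KEYS = {"max_gap_hours", "min_days", "population_weighting"}
_TOP_KEYS = {"model", "simulate", "evaluate", "io", "seed"}


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise SchemaError(f"unknown {where} config key(s): {sorted(unknown)}")


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected rather than silently ignored. A missing path
    yields all defaults.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    doc = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    ) or {}
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    _check_keys(doc, _TOP_KEYS, "top-level")
    model_block = doc.get("model", {}) or {}
    _check_keys(model_block, _MODEL_KEYS, "model")
    sim_block = doc.get("simulate", {}) or {}
    _check_keys(sim_block, _SIM_KEYS, "simulate")
    eval_block = doc.get("evaluate", {}) or {}
    _check_keys(eval_block, _EVAL_KEYS, "evaluate")
    return RunConfig(
        model=ModelConfig(**model_block),
        simulate=dict(sim_block),
        evaluate=dict(eval_block),
        io=dict(doc.get("io", {}) or {}),
        seed=int(doc.get("seed", 0)),
    )
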