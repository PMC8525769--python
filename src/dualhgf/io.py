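"""File schemas and validated readers/writers.

The trial table is a long-format CSV: one row per participant, phase, and
trial. Solo-phase (C1) rows must have empty bet fields; betting-phase (C2)
rows must have them filled. Choices are stored as the strings "scene" /
"face" for auditability.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .task import CONDITIONS, FACE, SCENE

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "participant_id",
    "phase",
    "trial_idx",
    "scene_pct",
    "bet_direction",
    "bet_correct",
    "choice",
    "confidence",
    "condition",
    "gpts_persecution",
    "bai",
    "bdi",
]

CONFIG_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Raised when a data file violates the expected schema."""


def _fail(messages: List[str]) -> None:
    if messages:
        raise SchemaError("; ".join(messages[:20]))


def read_trials(path: Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Checks columns, value domains, bet-field emptiness per phase, and
    uniqueness of (participant, phase, trial_idx). Offending rows are
    reported with their (0-based, header-excluded) line numbers.
    """
    df = pd.read_csv(path, dtype={"bet_direction": "string", "bet_correct": "string"})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")

    problems: List[str] = []

    def check(mask: pd.Series, what: str) -> None:
        bad = df.index[mask]
        if len(bad):
            problems.append(f"{what} (rows {list(bad[:5])})")

    check(~df["phase"].isin(["C1", "C2"]), "phase must be C1 or C2")
    check(~df["choice"].isin([SCENE, FACE]), "choice must be 'scene' or 'face'")
    check(~df["condition"].isin(CONDITIONS), "unknown condition")
    check((df["scene_pct"] < 0) | (df["scene_pct"] > 100), "scene_pct outside [0, 100]")
    check(
        (df["confidence"] < 1) | (df["confidence"] > 7) | (df["confidence"] % 1 != 0),
        "confidence must be an integer in 1..7",
    )

    bet_dir = df["bet_direction"].fillna("")
    bet_corr = df["bet_correct"].fillna("")
    is_c1 = df["phase"] == "C1"
    check(is_c1 & ((bet_dir != "") | (bet_corr != "")), "C1 rows must have empty bet fields")
    check(~is_c1 & ~bet_dir.isin([SCENE, FACE]), "C2 rows need bet_direction scene/face")
    check(~is_c1 & ~bet_corr.isin(["0", "1"]), "C2 rows need bet_correct 0/1")

    dup = df.duplicated(subset=["participant_id", "phase", "trial_idx"], keep=False)
    check(dup, "duplicated (participant, phase, trial_idx) key")

    _fail(problems)
    return df


def write_trials(df: pd.DataFrame, path: Path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def agree_choices(c2: pd.DataFrame) -> np.ndarray:
    """Map C2 scene/face choices to the bet-agreement coordinate (1 = agree)."""
    return (c2["choice"].to_numpy() == c2["bet_direction"].to_numpy()).astype(int)


def fits_to_frame(fit_rows: List[Dict]) -> pd.DataFrame:
    """Flatten FitResult-like dicts (one per participant x model) to a table."""
    return pd.DataFrame(fit_rows)


def read_fits(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("participant_id", "model", "log_evidence"):
        if col not in df.columns:
            raise SchemaError(f"fits table missing column {col!r}")
    return df


def load_config(path: Path) -> Dict:
    """Load a JSON run configuration; tolerate a missing version field."""
    cfg = json.loads(Path(path).read_text())
    version = cfg.get("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise SchemaError(f"unsupported config schema_version {version}")
    return cfg
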