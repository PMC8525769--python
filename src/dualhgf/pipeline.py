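"""End-to-end pipeline: simulate -> fit -> select -> metrics.

Every stage persists its artifacts before the next one runs, so a failure
leaves the completed outputs on disk. All randomness derives from the
single top-level seed in the configuration.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import __version__
from .bms import BmsReport, EvidenceMatrix, family_bms, rfx_bms
from .cohort import CohortConfig, sample_cohort, write_cohort
from .inference import (
    ModelSpec,
    default_model_space,
    fit_map,
    perceptual_families,
    response_families,
)
from .io import agree_choices, read_trials
from .metrics import motivational_bias, participant_metrics
from .task import TrialSequence

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict = {
    "schema_version": 1,
    "seed": 0,
    "cohort": {"n_participants": 20},
    "models": ["P1R1", "RWR1"],
    "n_restarts": 3,
}


def model_space_from_names(names: List[str]) -> List[ModelSpec]:
    by_name = {m.name: m for m in default_model_space()}
    unknown = [n for n in names if n not in by_name]
    if unknown:
        raise ValueError(f"unknown models: {unknown}; available: {sorted(by_name)}")
    return [by_name[n] for n in names]


def c2_sequence(c2: pd.DataFrame) -> TrialSequence:
    """Rebuild the betting-phase TrialSequence from validated table rows.

    The stored bet_correct flag is authoritative: the true category is
    derived from it (coin-flip truths at 50% scene are not recoverable
    from scene_pct alone).
    """
    scene_pct = c2["scene_pct"].to_numpy(dtype=float)
    bet_dir = (c2["bet_direction"].to_numpy() == "scene").astype(int)
    bet_corr = c2["bet_correct"].to_numpy(dtype=int)
    true_cat = np.where(bet_corr == 1, bet_dir, 1 - bet_dir)
    return TrialSequence(
        scene_pct=scene_pct,
        true_category=true_cat,
        ambiguous_truth=(scene_pct == 50.0),
        bet_direction=bet_dir,
        bet_correct=bet_corr,
    )


def fit_cohort(
    trials: pd.DataFrame,
    space: List[ModelSpec],
    n_restarts: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every model in the space to every participant's C2 choices."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid, g in trials.groupby("participant_id", sort=True):
        c2 = g[g["phase"] == "C2"].sort_values("trial_idx")
        seq = c2_sequence(c2)
        y = agree_choices(c2)
        for spec in space:
            fit = fit_map(
                seq, y, spec, n_restarts=n_restarts, seed=int(rng.integers(2**31))
            )
            row = {
                "participant_id": pid,
                "model": spec.name,
                "log_joint": fit.log_joint,
                "log_likelihood": fit.log_likelihood,
                "log_evidence": fit.log_evidence,
                "evidence_method": fit.evidence_method,
                "converged": fit.converged,
                "n_restarts": fit.n_restarts,
            }
            row.update(fit.params)
            rows.append(row)
    return pd.DataFrame(rows)


def evidence_matrix(fits: pd.DataFrame) -> EvidenceMatrix:
    wide = fits.pivot(index="participant_id", columns="model", values="log_evidence")
    return EvidenceMatrix(
        log_evidence=wide.to_numpy(dtype=float),
        model_labels=tuple(wide.columns),
    )


def select_models(fits: pd.DataFrame, seed: int = 0) -> Dict[str, BmsReport]:
    """Model-wise plus family-wise (perceptual/response) random-effects BMS."""
    ev = evidence_matrix(fits)
    if ev.n_models < 2:
        logger.info("select: single model in space, skipping BMS")
        return {}
    space = model_space_from_names(list(ev.model_labels))
    reports = {"models": rfx_bms(ev, seed=seed)}
    pf = perceptual_families(space)
    if len(pf) >= 2:
        reports["perceptual_families"] = family_bms(ev, pf, seed=seed)
    rf = response_families(space)
    if len(rf) >= 2:
        reports["response_families"] = family_bms(ev, rf, seed=seed)
    return reports


def run_pipeline(config: Dict, out_dir: Path) -> Dict[str, Path]:
    """Execute simulate -> fit -> select -> metrics, persisting artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    artifacts: Dict[str, Path] = {}
    timings: Dict[str, float] = {}

    stage = "simulate"
    try:
        t0 = time.monotonic()
        cohort_cfg = CohortConfig(**config.get("cohort", {}), seed=seed)
        cohort = sample_cohort(cohort_cfg)
        paths = write_cohort(cohort, out_dir, cohort_cfg)
        artifacts.update(paths)
        timings[stage] = time.monotonic() - t0

        stage = "fit"
        t0 = time.monotonic()
        trials = read_trials(paths["trials"])
        space = model_space_from_names(config.get("models", ["P1R1", "RWR1"]))
        fits = fit_cohort(
            trials, space, n_restarts=int(config.get("n_restarts", 3)), seed=seed + 1
        )
        artifacts["fits"] = out_dir / "fits.csv"
        fits.to_csv(artifacts["fits"], index=False)
        timings[stage] = time.monotonic() - t0

        stage = "select"
        t0 = time.monotonic()
        reports = select_models(fits, seed=seed + 2)
        artifacts["bms"] = out_dir / "bms.json"
        artifacts["bms"].write_text(
            json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2)
        )
        timings[stage] = time.monotonic() - t0

        stage = "metrics"
        t0 = time.monotonic()
        winner = config.get("metrics_model", "P1R1")
        fits_w = fits[fits["model"] == winner]
        per_part = participant_metrics(
            trials, fits_w if "omega_ns" in fits_w.columns else None
        )
        artifacts["metrics"] = out_dir / "metrics.csv"
        per_part.to_csv(artifacts["metrics"], index=False)

        summary: Dict = {"group_counts": per_part["paranoia_group"].value_counts().to_dict()}
        if per_part["condition"].nunique() >= 2:
            mb = motivational_bias(trials)
            summary["motivational_bias"] = {
                "coefficient": mb.coefficient,
                "z": mb.z,
                "ci": [mb.ci_low, mb.ci_high],
            }
        artifacts["summary"] = out_dir / "summary.json"
        artifacts["summary"].write_text(json.dumps(summary, indent=2))
        timings[stage] = time.monotonic() - t0
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from None
    finally:
        log = {
            "seed": seed,
            "version": __version__,
            "timings_s": timings,
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))

    return artifacts
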