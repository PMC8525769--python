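"""Behavioral statistics: self-deception classification and scores,
questionnaire grouping, motivational bias, rank-difference insight, and
correlation comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .task import CONDITIONS, COOPERATION, FACE, SCENE

logger = logging.getLogger(__name__)

PARANOIA_CUTOFF = 11  # R-GPTS persecution: >= 11 is high paranoia
ANXIETY_CUTOFF = 16  # BAI: > 16 is high anxiety


def classify_self_deception(
    condition: str, c1_choice: str, bet_direction: str, c2_choice: str
) -> bool:
    """A trial is self-deceptive when the classification changed between
    phases toward the bet (cooperation) or away from it (competition)."""
    for name, val in (
        ("c1_choice", c1_choice),
        ("bet_direction", bet_direction),
        ("c2_choice", c2_choice),
    ):
        if val not in (SCENE, FACE):
            raise ValueError(f"{name} must be 'scene' or 'face', got {val!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    changed = c2_choice != c1_choice
    if condition == COOPERATION:
        return changed and c2_choice == bet_direction
    return changed and c2_choice != bet_direction


def raw_self_deception_score(sd_flags: Sequence[bool]) -> float:
    """Fraction of self-deceptive trials out of all betting-phase trials."""
    flags = np.asarray(sd_flags, dtype=bool)
    if len(flags) == 0:
        raise ValueError("need at least one trial")
    return float(flags.mean())


def cwsd(
    sd_flags: Sequence[bool],
    c1_confidence: Sequence[float],
    c2_confidence: Sequence[float],
) -> float:
    """Confidence-weighted self-deception.

    raw score times the mean betting-phase confidence on self-deceptive
    trials, normalized by the mean confidence over all solo-phase trials.
    Zero when there are no self-deceptive trials.
    """
    flags = np.asarray(sd_flags, dtype=bool)
    c1 = np.asarray(c1_confidence, dtype=float)
    c2 = np.asarray(c2_confidence, dtype=float)
    if len(c1) == 0:
        raise ValueError("need at least one C1 confidence rating")
    if len(flags) != len(c2):
        raise ValueError("sd_flags and c2_confidence length mismatch")
    raw = raw_self_deception_score(flags)
    if not flags.any():
        return 0.0
    return raw * float(c2[flags].mean() / c1.mean())


def classify_groups(gpts_persecution: float, bai: float) -> Tuple[str, str]:
    """(paranoia_group, anxiety_group): high paranoia at R-GPTS persecution
    >= 11, high anxiety at BAI > 16."""
    if gpts_persecution < 0 or bai < 0:
        raise ValueError("questionnaire scores must be nonnegative")
    paranoia = "high" if gpts_persecution >= PARANOIA_CUTOFF else "low"
    anxiety = "high" if bai > ANXIETY_CUTOFF else "low"
    return paranoia, anxiety


@dataclass
class MotivationalBiasResult:
    coefficient: float  # bet x condition interaction (log-odds)
    z: float
    ci_low: float
    ci_high: float
    n_obs: int
    n_participants: int


def motivational_bias(trials: pd.DataFrame) -> MotivationalBiasResult:
    """Bet-by-condition interaction in a logistic mixed-effects regression.

    Betting-phase scene responses are regressed on scene percentage, bet
    direction, condition, and the bet x condition interaction, with
    per-participant random intercepts (variational Bayes fit). A positive
    interaction means conformity under cooperation and defection under
    competition. Requires columns: participant_id, phase, scene_pct,
    bet_direction, choice, condition.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    c2 = trials[trials["phase"] == "C2"].copy()
    conditions = set(c2["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("both conditions must be represented")
    c2["scene_resp"] = (c2["choice"] == SCENE).astype(float)
    c2["bet_scene"] = (c2["bet_direction"] == SCENE).astype(float)
    c2["coop"] = (c2["condition"] == COOPERATION).astype(float)
    c2["scene_z"] = (c2["scene_pct"] - 50.0) / 50.0

    model = BinomialBayesMixedGLM.from_formula(
        "scene_resp ~ scene_z + bet_scene + coop + bet_scene:coop",
        {"participant": "0 + C(participant_id)"},
        c2,
    )
    fit = model.fit_vb()
    names = model.fep_names
    k = names.index("bet_scene:coop")
    coef = float(fit.fe_mean[k])
    sd = float(fit.fe_sd[k])
    z = coef / sd
    return MotivationalBiasResult(
        coefficient=coef,
        z=z,
        ci_low=coef - 1.96 * sd,
        ci_high=coef + 1.96 * sd,
        n_obs=len(c2),
        n_participants=c2["participant_id"].nunique(),
    )


def insight_rank_difference(
    omega_ns: Sequence[float], c1_accuracy: Sequence[float]
) -> np.ndarray:
    """Per-participant insight score: rank of perceived choice unreliability
    minus rank of objective solo-phase accuracy.

    omega_ns is ranked ascending (highest rank = least perceived
    reliability); accuracy is ranked descending (rank 1 = best performer);
    ties get average ranks. Large positive scores mean good performance
    paired with a pessimistic self-view.
    """
    w = np.asarray(omega_ns, dtype=float)
    acc = np.asarray(c1_accuracy, dtype=float)
    if len(w) != len(acc):
        raise ValueError("omega_ns and c1_accuracy length mismatch")
    if len(w) < 2:
        raise ValueError("need at least two participants")
    rank_w = stats.rankdata(w)  # ascending: 1 = most stable self-view
    rank_acc = stats.rankdata(-acc)  # descending: 1 = best accuracy
    return rank_w - rank_acc


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> Tuple[float, float]:
    """Two-sided test for a difference between two independent Pearson
    correlations via Fisher's z transform. Returns (z, p)."""
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError(f"correlations must satisfy |r| < 1, got {r}")
    for n in (n1, n2):
        if n < 4:
            raise ValueError(f"need n >= 4, got {n}")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return z, 2.0 * stats.norm.sf(abs(z))


def group_anova(values: Sequence[float], labels: Sequence[str]) -> Dict[str, float]:
    """One-way ANOVA of a metric across groups with partial eta squared."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [v[lab == g] for g in np.unique(lab)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f, p = stats.f_oneway(*groups)
    grand = v.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return {
        "F": float(f),
        "p": float(p),
        "partial_eta_sq": float(ss_between / (ss_between + ss_within)),
    }


def participant_metrics(
    trials: pd.DataFrame, fits: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-participant derived metrics from a validated trial table.

    Returns one row per participant: raw_sd_score, cwsd, paranoia and
    anxiety groups, C1 accuracy (50/50 stimuli excluded), and — when a
    fits table with an ``omega_ns`` column is given — the rank-difference
    insight score. Participants missing from ``fits`` are excluded from
    the insight ranking with a log entry.
    """
    rows = []
    for pid, g in trials.groupby("participant_id", sort=True):
        c1 = g[g["phase"] == "C1"].sort_values("trial_idx")
        c2 = g[g["phase"] == "C2"].sort_values("trial_idx")
        if len(c1) != len(c2):
            raise ValueError(f"participant {pid}: C1/C2 trial counts differ")
        condition = g["condition"].iloc[0]
        sd_flags = np.array(
            [
                classify_self_deception(condition, a, b, c)
                for a, b, c in zip(
                    c1["choice"], c2["bet_direction"], c2["choice"]
                )
            ]
        )
        unambiguous = c1["scene_pct"] != 50.0
        truth = np.where(c1["scene_pct"] > 50.0, SCENE, FACE)
        acc = float((c1["choice"].to_numpy() == truth)[unambiguous].mean())
        paranoia, anxiety = classify_groups(
            float(g["gpts_persecution"].iloc[0]), float(g["bai"].iloc[0])
        )
        rows.append(
            {
                "participant_id": pid,
                "condition": condition,
                "raw_sd_score": raw_self_deception_score(sd_flags),
                "cwsd": cwsd(
                    sd_flags,
                    c1["confidence"].to_numpy(float),
                    c2["confidence"].to_numpy(float),
                ),
                "paranoia_group": paranoia,
                "anxiety_group": anxiety,
                "c1_accuracy": acc,
            }
        )
    out = pd.DataFrame(rows)

    if fits is not None and "omega_ns" in fits.columns:
        merged = out.merge(
            fits[["participant_id", "omega_ns"]], on="participant_id", how="left"
        )
        have = merged["omega_ns"].notna()
        if (~have).any():
            logger.info(
                "insight score: excluding %d participants without fits",
                int((~have).sum()),
            )
        out["insight_rank_diff"] = np.nan
        if have.sum() >= 2:
            out.loc[have, "insight_rank_diff"] = insight_rank_difference(
                merged.loc[have, "omega_ns"], merged.loc[have, "c1_accuracy"]
            )
    return out
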