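"""Synthetic cohort generation.

Builds complete datasets — participants with group structure, latent model
parameters, simulated solo (C1) and betting (C2) phase choices, and
confidence ratings — with the statistical structure the downstream
analysis assumes: elevated omega_ns and omega_s in the high-paranoia
group and an elevated social prior mean under cooperation.

C1 choices are simulated from the non-social stream alone (no bets exist
in that phase); C2 choices from the full dual-stream model. Confidence is
a monotone map of belief extremity plus Gaussian noise, discretized to
the 1-7 scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import hgf, responses
from .inference import make_model_spec, predict_probs
from .task import (
    COMPETITION,
    COOPERATION,
    FACE,
    SCENE,
    TrialSequence,
    experiment_config,
    generate_task,
)


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Parameter distributions are log-normal for omega_s, omega_ns, beta,
    eta and normal for mu2_0_s; group effects are additive shifts on the
    sampling scale (log scale for the omegas).
    """

    n_participants: int = 200
    frac_high_paranoia: float = 0.5
    frac_cooperation: float = 0.5
    experiment: int = 1
    n_trials: int = 80
    # sampling distributions (mean, sd) on the estimation scale
    log_omega_s: Tuple[float, float] = (-2.0, 1.0)
    log_omega_ns: Tuple[float, float] = (-2.0, 1.0)
    log_eta: Tuple[float, float] = (0.0, 0.5)
    log_beta: Tuple[float, float] = (0.7, 0.5)
    mu2_0_s: Tuple[float, float] = (0.0, 1.0)
    # group effects: additive shifts on the sampling scale. The omegas use
    # ~0.4 SD; the social prior mean needs a larger true shift because its
    # MAP estimate is strongly attenuated (it enters the likelihood only
    # through sigmoid(eta * omega_s * mu2_0_s) on early trials).
    omega_ns_shift_paranoia: float = 0.4
    omega_s_shift_paranoia: float = 0.4
    mu2_0_s_shift_cooperation: float = 1.2
    # confidence model: clip(round(1 + 6 (2|b - 0.5|)^gamma + eps), 1, 7)
    confidence_gamma: float = 1.0
    confidence_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("frac_high_paranoia", "frac_cooperation"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {f}")
        if self.experiment not in (1, 2):
            raise ValueError(f"experiment must be 1 or 2, got {self.experiment}")
        for name in (
            "omega_ns_shift_paranoia",
            "omega_s_shift_paranoia",
            "mu2_0_s_shift_cooperation",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.confidence_noise < 0:
            raise ValueError("confidence_noise must be >= 0")


@dataclass
class SyntheticParticipant:
    """One simulated participant: latent truth plus observable records."""

    participant_id: int
    condition: str
    paranoia_group: str
    anxiety_group: str
    gpts_persecution: int
    bai: int
    bdi: int
    true_params: Dict[str, float]
    c1_trials: TrialSequence
    c2_trials: TrialSequence
    c1_choice: np.ndarray  # 1 = scene
    c2_choice: np.ndarray  # 1 = scene
    c2_agree: np.ndarray  # 1 = agrees with bet
    c1_confidence: np.ndarray
    c2_confidence: np.ndarray


def _discretize_confidence(
    belief: np.ndarray, gamma: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    extremity = (2.0 * np.abs(belief - 0.5)) ** gamma
    raw = 1.0 + 6.0 * extremity + rng.normal(0.0, noise, size=belief.shape)
    return np.clip(np.round(raw), 1, 7).astype(int)


def _sample_questionnaires(
    paranoia_high: bool, rng: np.random.Generator
) -> Tuple[int, int, int, str]:
    """Scores drawn on the correct side of the published cutoffs."""
    if paranoia_high:
        gpts = int(rng.integers(11, 33))
    else:
        gpts = int(rng.integers(0, 11))
    bai = int(rng.integers(0, 40))
    anxiety = "high" if bai > 16 else "low"
    bdi = int(rng.integers(0, 40))
    return gpts, bai, bdi, anxiety


def _exact_split(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean assignment with an exact count of round(frac * n) Trues."""
    k = int(round(frac * n))
    out = np.zeros(n, dtype=bool)
    out[rng.choice(n, size=k, replace=False)] = True
    return out


def sample_cohort(config: CohortConfig) -> List[SyntheticParticipant]:
    """Draw a full synthetic cohort under the configured group structure."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    high_paranoia = _exact_split(n, config.frac_high_paranoia, rng)
    cooperation = _exact_split(n, config.frac_cooperation, rng)

    spec = make_model_spec("P1", "R1")
    participants: List[SyntheticParticipant] = []
    for i in range(n):
        condition = COOPERATION if cooperation[i] else COMPETITION
        m, s = config.log_omega_s
        log_omega_s = rng.normal(
            m + (config.omega_s_shift_paranoia if high_paranoia[i] else 0.0), s
        )
        m, s = config.log_omega_ns
        log_omega_ns = rng.normal(
            m + (config.omega_ns_shift_paranoia if high_paranoia[i] else 0.0), s
        )
        m, s = config.mu2_0_s
        mu2_0_s = rng.normal(
            m + (config.mu2_0_s_shift_cooperation if cooperation[i] else 0.0), s
        )
        params = {
            "omega_s": float(np.exp(log_omega_s)),
            "omega_ns": float(np.exp(log_omega_ns)),
            "eta": float(np.exp(rng.normal(*config.log_eta))),
            "mu2_0_s": float(mu2_0_s),
            "beta": float(np.exp(rng.normal(*config.log_beta))),
        }

        task_cfg = experiment_config(
            config.experiment,
            condition=condition,
            seed=int(rng.integers(2**31)),
            n_trials=config.n_trials,
        )
        c1, c2 = generate_task(task_cfg)

        # C1: non-social stream only, choices in scene space
        params_ns = hgf.StreamParameters(omega=params["omega_ns"], mu2_0=0.0)
        mu1_ns = hgf.filter_nonsocial_trajectory(params_ns, c1)
        p_scene_c1 = responses.softmax_prob(mu1_ns, params["beta"])
        c1_choice = responses.simulate_responses(p_scene_c1, rng)
        c1_conf = _discretize_confidence(
            mu1_ns, config.confidence_gamma, config.confidence_noise, rng
        )

        # C2: full dual-stream model, choices in agreement space
        p_agree = predict_probs(spec, params, c2)
        c2_agree = responses.simulate_responses(p_agree, rng)
        c2_choice = np.where(c2_agree == 1, c2.bet_direction, 1 - c2.bet_direction)
        params_s = hgf.StreamParameters(
            omega=params["omega_s"], mu2_0=params["mu2_0_s"], eta=params["eta"]
        )
        traj = hgf.filter_trajectory(params_s, params_ns, c2)
        c2_conf = _discretize_confidence(
            traj.b, config.confidence_gamma, config.confidence_noise, rng
        )

        gpts, bai, bdi, anxiety = _sample_questionnaires(bool(high_paranoia[i]), rng)
        participants.append(
            SyntheticParticipant(
                participant_id=i,
                condition=condition,
                paranoia_group="high" if high_paranoia[i] else "low",
                anxiety_group=anxiety,
                gpts_persecution=gpts,
                bai=bai,
                bdi=bdi,
                true_params=params,
                c1_trials=c1,
                c2_trials=c2,
                c1_choice=c1_choice,
                c2_choice=c2_choice,
                c2_agree=c2_agree,
                c1_confidence=c1_conf,
                c2_confidence=c2_conf,
            )
        )
    return participants


def cohort_trial_table(cohort: List[SyntheticParticipant]) -> pd.DataFrame:
    """Long-format trial table matching the validated file schema."""
    frames = []
    for p in cohort:
        common = {
            "participant_id": p.participant_id,
            "condition": p.condition,
            "gpts_persecution": p.gpts_persecution,
            "bai": p.bai,
            "bdi": p.bdi,
        }
        n = p.c1_trials.n_trials
        frames.append(
            pd.DataFrame(
                {
                    "phase": "C1",
                    "trial_idx": np.arange(n),
                    "scene_pct": p.c1_trials.scene_pct,
                    "bet_direction": "",
                    "bet_correct": "",
                    "choice": np.where(p.c1_choice == 1, SCENE, FACE),
                    "confidence": p.c1_confidence,
                    **common,
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "phase": "C2",
                    "trial_idx": np.arange(n),
                    "scene_pct": p.c2_trials.scene_pct,
                    "bet_direction": np.where(
                        p.c2_trials.bet_direction == 1, SCENE, FACE
                    ),
                    "bet_correct": p.c2_trials.bet_correct.astype(str),
                    "choice": np.where(p.c2_choice == 1, SCENE, FACE),
                    "confidence": p.c2_confidence,
                    **common,
                }
            )
        )
    cols = [
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
    return pd.concat(frames, ignore_index=True)[cols]


def cohort_participant_table(cohort: List[SyntheticParticipant]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {
            "participant_id": p.participant_id,
            "condition": p.condition,
            "paranoia_group": p.paranoia_group,
            "anxiety_group": p.anxiety_group,
            "gpts_persecution": p.gpts_persecution,
            "bai": p.bai,
            "bdi": p.bdi,
        }
        row.update({f"true_{k}": v for k, v in p.true_params.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    cohort: List[SyntheticParticipant],
    out_dir: Path,
    config: Optional[CohortConfig] = None,
) -> Dict[str, Path]:
    """Write trial-level and participant-level CSVs plus a provenance JSON."""
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out_dir / "trials.csv",
        "participants": out_dir / "participants.csv",
        "provenance": out_dir / "provenance.json",
    }
    cohort_trial_table(cohort).to_csv(paths["trials"], index=False)
    cohort_participant_table(cohort).to_csv(paths["participants"], index=False)
    provenance = {"n_participants": len(cohort)}
    if config is not None:
        provenance["config"] = asdict(config)
    paths["provenance"].write_text(json.dumps(provenance, indent=2))
    return paths
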