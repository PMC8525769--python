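"""Two-stream, two-level hierarchical Gaussian filter.

Each stream tracks a level-2 tendency (a Gaussian random walk with
variance ``omega`` on the natural scale) whose logistic transform yields
the level-1 prediction: the probability that the partner's bet is correct
(social stream) or that the image is a scene (non-social stream). Level-2
beliefs are updated by the precision-weighted level-1 prediction error.
The two level-1 predictions are combined into a single bet-agreement
belief by precision weighting.

A Rescorla-Wagner delta-rule filter with fixed learning rates is provided
as the non-Bayesian baseline; it shares the belief-combination step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .task import TrialSequence

#: Beliefs are clipped to [BELIEF_EPS, 1 - BELIEF_EPS] to keep precisions finite.
BELIEF_EPS = 1e-8

#: Social-link variants: how the level-2 social tendency maps to the level-1
#: prediction. "scaled" multiplies the exponent by eta * omega_s (winning
#: variant), "multiplicative" by a free eta alone, "additive" shifts the
#: exponent by a free bias.
SOCIAL_LINKS = ("scaled", "multiplicative", "additive")


@dataclass(frozen=True)
class StreamParameters:
    """Free parameters of one HGF stream.

    ``eta`` is the social-link parameter: the scaling factor of the
    exponent for the "scaled"/"multiplicative" links, or the additive
    shift for the "additive" link (where it may be any finite value).
    """

    omega: float
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    eta: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if not self.sigma2_0 > 0:
            raise ValueError(f"sigma2_0 must be > 0, got {self.sigma2_0}")


@dataclass(frozen=True)
class RwParameters:
    """Rescorla-Wagner baseline: fixed learning rates per stream."""

    alpha_s: float
    alpha_ns: float
    V0_s: float = 0.5
    V0_ns: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha_s", "alpha_ns"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {a}")
        for name in ("V0_s", "V0_ns"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class StreamState:
    """Latent quantities of one stream after one trial's update."""

    mu2: float
    sigma2: float
    mu1_hat: float
    pi1_hat: float
    pi2_hat: float
    pi2: float
    delta1: float


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial latent trajectories of both streams and the combined belief.

    ``mu2_*``/``sigma2_*`` are posterior (post-update) values; ``mu1_hat_*``
    are the pre-update predictions that drive the trial's response. ``a_ns``
    is the non-social belief mapped into bet-agreement space and ``b`` the
    precision-weighted combination used by the response model.
    """

    mu1_hat_s: np.ndarray
    mu1_hat_ns: np.ndarray
    a_ns: np.ndarray
    b: np.ndarray
    recency: np.ndarray
    mu2_s: np.ndarray
    sigma2_s: np.ndarray
    mu2_ns: np.ndarray
    sigma2_ns: np.ndarray
    delta1_s: np.ndarray
    delta1_ns: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.b)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_idx": np.arange(self.n_trials),
                "recency_bias": self.recency,
                "mu1_hat_s": self.mu1_hat_s,
                "mu1_hat_ns": self.mu1_hat_ns,
                "a_ns": self.a_ns,
                "b": self.b,
                "mu2_s": self.mu2_s,
                "sigma2_s": self.sigma2_s,
                "mu2_ns": self.mu2_ns,
                "sigma2_ns": self.sigma2_ns,
                "delta1_s": self.delta1_s,
                "delta1_ns": self.delta1_ns,
            }
        )


def sigmoid(x: float) -> float:
    """Numerically stable logistic function."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def clip_belief(p: float, eps: float = BELIEF_EPS) -> float:
    return min(max(p, eps), 1.0 - eps)


def recency_bias(scene_pct_prev: float) -> float:
    """Linear carry-over of the previous image's ambiguity onto the next
    non-social prediction: (pct - 50)/50, so 0% -> -1, 50% -> 0, 100% -> +1."""
    if not 0.0 <= scene_pct_prev <= 100.0:
        raise ValueError(
            f"scene percentage must lie in [0, 100], got {scene_pct_prev}"
        )
    return (scene_pct_prev - 50.0) / 50.0


def predict_social(mu2_s_prev: float, eta: float, omega_s: float) -> float:
    """Level-1 social prediction: sigmoid of eta * omega_s * mu2 (scaled link)."""
    if not eta > 0:
        raise ValueError(f"eta must be > 0, got {eta}")
    if not omega_s > 0:
        raise ValueError(f"omega_s must be > 0, got {omega_s}")
    return sigmoid(eta * omega_s * mu2_s_prev)


def predict_nonsocial(mu2_ns_prev: float, bias: float) -> float:
    """Level-1 non-social prediction: sigmoid of (mu2 + recency bias)."""
    if not -1.0 <= bias <= 1.0:
        raise ValueError(f"recency bias must lie in [-1, 1], got {bias}")
    return sigmoid(mu2_ns_prev + bias)


def update_level2(
    mu2_prev: float, sigma2_prev: float, mu1_hat: float, input_u: float, omega: float
) -> StreamState:
    """One precision-weighted level-2 update.

    pi2_hat = 1/(sigma2_prev + omega); pi1_hat = 1/(mu1_hat (1 - mu1_hat));
    delta1 = u - mu1_hat; pi2 = pi2_hat + 1/pi1_hat; mu2 += delta1 / pi2.
    """
    if not 0.0 <= input_u <= 1.0:
        raise ValueError(f"input must lie in [0, 1], got {input_u}")
    mu1 = clip_belief(mu1_hat)
    pi2_hat = 1.0 / (sigma2_prev + omega)
    pi1_hat = 1.0 / (mu1 * (1.0 - mu1))
    delta1 = input_u - mu1
    pi2 = pi2_hat + 1.0 / pi1_hat
    mu2 = mu2_prev + delta1 / pi2
    return StreamState(
        mu2=mu2,
        sigma2=1.0 / pi2,
        mu1_hat=mu1,
        pi1_hat=pi1_hat,
        pi2_hat=pi2_hat,
        pi2=pi2,
        delta1=delta1,
    )


def combine_beliefs(
    mu1_hat_s: float, mu1_hat_ns: float, bet_is_scene: int
) -> Tuple[float, float]:
    """Precision-weighted combination of the two level-1 predictions.

    The non-social (image) belief is first mapped into bet-agreement space:
    a_ns is the probability that the image category matches the bet. The
    returned ``b`` is a convex combination of the social belief and a_ns,
    weighted by their binomial precisions.
    """
    s = clip_belief(mu1_hat_s)
    a_ns = mu1_hat_ns if bet_is_scene else 1.0 - mu1_hat_ns
    a_ns = clip_belief(a_ns)
    pi_s = 1.0 / (s * (1.0 - s))
    pi_ns = 1.0 / (a_ns * (1.0 - a_ns))
    b = (pi_s * s + pi_ns * a_ns) / (pi_s + pi_ns)
    return b, a_ns


def _social_exponent(link: str, mu2_s: float, eta: float, omega_s: float) -> float:
    if link == "scaled":
        return eta * omega_s * mu2_s
    if link == "multiplicative":
        return eta * mu2_s
    if link == "additive":
        return mu2_s + eta
    raise ValueError(f"unknown social link {link!r}")


def filter_trajectory(
    params_s: StreamParameters,
    params_ns: StreamParameters,
    trials: TrialSequence,
    social_link: str = "scaled",
) -> BeliefTrajectory:
    """Run the full dual-stream filter over a betting-phase trial sequence.

    Per trial: recency bias from the previous stimulus (0 on the first
    trial), level-1 predictions from the previous level-2 posteriors,
    belief combination in agreement space, then level-2 updates from the
    trial's inputs (bet correctness for the social stream, scene fraction
    for the non-social stream).
    """
    if social_link not in SOCIAL_LINKS:
        raise ValueError(f"unknown social link {social_link!r}")
    if not trials.has_bets:
        raise ValueError("filter_trajectory requires a betting-phase sequence")
    if params_s.eta is None:
        raise ValueError("social stream parameters must define eta")

    n = trials.n_trials
    scene = trials.scene_pct
    bet_dir = trials.bet_direction
    bet_corr = trials.bet_correct

    out = {k: np.empty(n) for k in (
        "mu1_hat_s", "mu1_hat_ns", "a_ns", "b", "recency",
        "mu2_s", "sigma2_s", "mu2_ns", "sigma2_ns", "delta1_s", "delta1_ns",
    )}

    mu2_s, sigma2_s = params_s.mu2_0, params_s.sigma2_0
    mu2_ns, sigma2_ns = params_ns.mu2_0, params_ns.sigma2_0
    omega_s, omega_ns, eta = params_s.omega, params_ns.omega, params_s.eta

    for t in range(n):
        bias = 0.0 if t == 0 else (scene[t - 1] - 50.0) / 50.0
        mu1_s = clip_belief(sigmoid(_social_exponent(social_link, mu2_s, eta, omega_s)))
        mu1_ns = clip_belief(sigmoid(mu2_ns + bias))
        b, a_ns = combine_beliefs(mu1_s, mu1_ns, bet_dir[t])

        st_s = update_level2(mu2_s, sigma2_s, mu1_s, float(bet_corr[t]), omega_s)
        st_ns = update_level2(mu2_ns, sigma2_ns, mu1_ns, scene[t] / 100.0, omega_ns)
        mu2_s, sigma2_s = st_s.mu2, st_s.sigma2
        mu2_ns, sigma2_ns = st_ns.mu2, st_ns.sigma2

        out["recency"][t] = bias
        out["mu1_hat_s"][t] = mu1_s
        out["mu1_hat_ns"][t] = mu1_ns
        out["a_ns"][t] = a_ns
        out["b"][t] = b
        out["mu2_s"][t] = mu2_s
        out["sigma2_s"][t] = sigma2_s
        out["mu2_ns"][t] = mu2_ns
        out["sigma2_ns"][t] = sigma2_ns
        out["delta1_s"][t] = st_s.delta1
        out["delta1_ns"][t] = st_ns.delta1

    return BeliefTrajectory(**out)


def filter_nonsocial_trajectory(
    params_ns: StreamParameters, trials: TrialSequence
) -> np.ndarray:
    """Non-social stream alone (C1 phase: no bets). Returns mu1_hat_ns per trial."""
    n = trials.n_trials
    scene = trials.scene_pct
    mu2, sigma2 = params_ns.mu2_0, params_ns.sigma2_0
    mu1 = np.empty(n)
    for t in range(n):
        bias = 0.0 if t == 0 else (scene[t - 1] - 50.0) / 50.0
        mu1[t] = clip_belief(sigmoid(mu2 + bias))
        st = update_level2(mu2, sigma2, mu1[t], scene[t] / 100.0, params_ns.omega)
        mu2, sigma2 = st.mu2, st.sigma2
    return mu1


def rw_trajectory(params: RwParameters, trials: TrialSequence) -> BeliefTrajectory:
    """Rescorla-Wagner baseline: V(t) = V(t-1) + alpha (u - V(t-1)) per stream.

    The associative strengths play the role of the level-1 predictions and
    are combined exactly as in the HGF (precision weights from V(1-V)).
    Level-2 fields are filled with the V values and NaN variances.
    """
    if not trials.has_bets:
        raise ValueError("rw_trajectory requires a betting-phase sequence")
    n = trials.n_trials
    scene = trials.scene_pct
    bet_dir = trials.bet_direction
    bet_corr = trials.bet_correct

    out = {k: np.empty(n) for k in (
        "mu1_hat_s", "mu1_hat_ns", "a_ns", "b", "recency",
        "mu2_s", "sigma2_s", "mu2_ns", "sigma2_ns", "delta1_s", "delta1_ns",
    )}
    out["sigma2_s"].fill(np.nan)
    out["sigma2_ns"].fill(np.nan)

    v_s, v_ns = params.V0_s, params.V0_ns
    for t in range(n):
        mu1_s = clip_belief(v_s)
        mu1_ns = clip_belief(v_ns)
        b, a_ns = combine_beliefs(mu1_s, mu1_ns, bet_dir[t])

        d_s = float(bet_corr[t]) - v_s
        d_ns = scene[t] / 100.0 - v_ns
        v_s += params.alpha_s * d_s
        v_ns += params.alpha_ns * d_ns

        out["recency"][t] = 0.0
        out["mu1_hat_s"][t] = mu1_s
        out["mu1_hat_ns"][t] = mu1_ns
        out["a_ns"][t] = a_ns
        out["b"][t] = b
        out["mu2_s"][t] = v_s
        out["mu2_ns"][t] = v_ns
        out["delta1_s"][t] = d_s
        out["delta1_ns"][t] = d_ns

    return BeliefTrajectory(**out)
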