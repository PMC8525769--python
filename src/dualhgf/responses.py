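"""Response models: mapping combined beliefs to binary choice probabilities.

Choices are encoded in bet-agreement space: y = 1 means the participant's
classification agrees with the partner's bet.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

#: Probabilities are clipped to [LIK_EPS, 1 - LIK_EPS] inside the likelihood.
LIK_EPS = 1e-10

ArrayLike = Union[float, np.ndarray]


def softmax_prob(b: ArrayLike, beta: float) -> ArrayLike:
    """P(agree) = b^beta / (b^beta + (1-b)^beta), computed stably in log space."""
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    b_arr = np.clip(np.asarray(b, dtype=float), LIK_EPS, 1.0 - LIK_EPS)
    # b^B/(b^B + (1-b)^B) = 1/(1 + exp(B (log(1-b) - log b)))
    z = beta * (np.log1p(-b_arr) - np.log(b_arr))
    p = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return float(p) if np.isscalar(b) else p


def weighted_combination(
    mu1_hat_s: ArrayLike, a_ns: ArrayLike, zeta: float = 1.0
) -> ArrayLike:
    """Belief combination with a free social stream weight zeta.

    b = (zeta pi_s mu_s + pi_ns a_ns) / (zeta pi_s + pi_ns); zeta = 1
    reduces to the plain precision-weighted combination.
    """
    if not zeta > 0:
        raise ValueError(f"zeta must be > 0, got {zeta}")
    s = np.clip(np.asarray(mu1_hat_s, dtype=float), LIK_EPS, 1.0 - LIK_EPS)
    a = np.clip(np.asarray(a_ns, dtype=float), LIK_EPS, 1.0 - LIK_EPS)
    pi_s = 1.0 / (s * (1.0 - s))
    pi_ns = 1.0 / (a * (1.0 - a))
    b = (zeta * pi_s * s + pi_ns * a) / (zeta * pi_s + pi_ns)
    return float(b) if np.isscalar(mu1_hat_s) else b


def log_likelihood(choices: np.ndarray, probs: np.ndarray) -> float:
    """Bernoulli log-likelihood of binary agree-with-bet choices."""
    y = np.asarray(choices, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} choices vs {p.shape} probs")
    p = np.clip(p, LIK_EPS, 1.0 - LIK_EPS)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def simulate_responses(
    probs: np.ndarray, seed: Optional[Union[int, np.random.Generator]] = None
) -> np.ndarray:
    """Independent Bernoulli draws, one per trial probability."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(probs, dtype=float)
    return (rng.random(p.shape) < p).astype(int)
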