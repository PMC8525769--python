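"""Random-effects Bayesian model selection over a subjects-by-models
log-evidence matrix.

Variational Dirichlet scheme (uniform Dirichlet prior, alpha0 = 1):
posterior model assignments and concentration parameters are iterated to
convergence; exceedance probabilities come from seeded Dirichlet Monte
Carlo; the Bayes omnibus risk (BOR) compares the fitted model against the
null of equal model frequencies; protected exceedance probabilities are
PXP = (1 - BOR) * EP + BOR / K. Family-wise selection pools within-family
evidence under a uniform within-family prior before running the same
scheme over families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import special

_LOG_EPS = 1e-32


@dataclass(frozen=True)
class EvidenceMatrix:
    """Subjects x models log evidences with labels and optional families."""

    log_evidence: np.ndarray
    model_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        lme = np.asarray(self.log_evidence, dtype=float)
        if lme.ndim != 2:
            raise ValueError("log_evidence must be 2-D (subjects x models)")
        if lme.shape[1] != len(self.model_labels):
            raise ValueError("label count does not match number of models")
        bad = np.argwhere(~np.isfinite(lme))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-finite log evidence for subject {i}, model "
                f"{self.model_labels[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.log_evidence.shape[0]

    @property
    def n_models(self) -> int:
        return self.log_evidence.shape[1]


@dataclass(frozen=True)
class BmsReport:
    """Result of one random-effects comparison (over models or families)."""

    labels: Tuple[str, ...]
    alpha: np.ndarray  # posterior Dirichlet concentrations
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    bor: float
    protected_exceedance_prob: np.ndarray
    posterior_assignments: np.ndarray  # subjects x models
    n_iterations: int

    def winner(self) -> str:
        return self.labels[int(np.argmax(self.protected_exceedance_prob))]

    def to_dict(self) -> Dict[str, object]:
        return {
            "labels": list(self.labels),
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "exceedance_prob": self.exceedance_prob.tolist(),
            "bor": self.bor,
            "protected_exceedance_prob": self.protected_exceedance_prob.tolist(),
        }


def exceedance_probability(
    alpha: np.ndarray, n_draws: int = 100_000, seed: int = 0
) -> np.ndarray:
    """P(model k has the highest frequency) by Dirichlet Monte Carlo."""
    alpha = np.asarray(alpha, dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=len(alpha)) / n_draws


def exceedance_probability_two(alpha: np.ndarray) -> np.ndarray:
    """Closed form for K = 2: P(r1 > 1/2) with r1 ~ Beta(a1, a2) is the
    regularized incomplete beta function I_{1/2}(a2, a1)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (2,):
        raise ValueError("closed form applies to exactly two models")
    ep1 = float(special.betainc(alpha[1], alpha[0], 0.5))
    return np.array([ep1, 1.0 - ep1])


def _variational_dirichlet(
    lme: np.ndarray, alpha0: float, tol: float, max_iter: int
) -> Tuple[np.ndarray, np.ndarray, int]:
    n, k = lme.shape
    alpha = np.full(k, alpha0)
    g = np.full((n, k), 1.0 / k)
    for it in range(1, max_iter + 1):
        logu = lme + (special.digamma(alpha) - special.digamma(alpha.sum()))
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        g = u / u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            return alpha_new, g, it
        alpha = alpha_new
    return alpha, g, max_iter


def _free_energy(lme: np.ndarray, alpha: np.ndarray, g: np.ndarray, alpha0: float) -> float:
    """Variational free energy of the fitted random-effects model."""
    k = len(alpha)
    a0 = np.full(k, alpha0)
    elog_r = special.digamma(alpha) - special.digamma(alpha.sum())
    elj = (
        special.gammaln(a0.sum())
        - special.gammaln(a0).sum()
        + float(((a0 - 1.0) * elog_r).sum())
        + float((g * (lme + elog_r)).sum())
    )
    s_qf = (
        special.gammaln(alpha).sum()
        - special.gammaln(alpha.sum())
        - float(((alpha - 1.0) * elog_r).sum())
    )
    s_qm = -float((g * np.log(g + _LOG_EPS)).sum())
    return elj + s_qf + s_qm


def _null_free_energy(lme: np.ndarray) -> float:
    """Log evidence of the null model: all frequencies equal (r_k = 1/K)."""
    k = lme.shape[1]
    return float(np.sum(special.logsumexp(lme, axis=1) - math.log(k)))


def rfx_bms(
    evidence: EvidenceMatrix,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    ep_draws: int = 100_000,
    seed: int = 0,
) -> BmsReport:
    """Random-effects comparison of the models in ``evidence``."""
    lme = np.asarray(evidence.log_evidence, dtype=float)
    if evidence.n_subjects < 1:
        raise ValueError("need at least one subject")
    if evidence.n_models < 2:
        raise ValueError("need at least two models")

    alpha, g, n_iter = _variational_dirichlet(lme, alpha0, tol, max_iter)
    expected = alpha / alpha.sum()
    if evidence.n_models == 2:
        ep = exceedance_probability_two(alpha)
    else:
        ep = exceedance_probability(alpha, n_draws=ep_draws, seed=seed)

    f1 = _free_energy(lme, alpha, g, alpha0)
    f0 = _null_free_energy(lme)
    # BOR = posterior probability of the equal-frequency null
    bor = 1.0 / (1.0 + math.exp(min(700.0, max(-700.0, f1 - f0))))
    pxp = (1.0 - bor) * ep + bor / evidence.n_models

    return BmsReport(
        labels=evidence.model_labels,
        alpha=alpha,
        expected_freq=expected,
        exceedance_prob=ep,
        bor=bor,
        protected_exceedance_prob=pxp,
        posterior_assignments=g,
        n_iterations=n_iter,
    )


def pool_families(
    evidence: EvidenceMatrix, families: Mapping[str, Sequence[str]]
) -> EvidenceMatrix:
    """Collapse models into families: log-mean-exp of the member evidences
    (uniform within-family prior), so duplicating a member leaves the
    family evidence unchanged."""
    label_to_idx = {lab: i for i, lab in enumerate(evidence.model_labels)}
    seen: List[str] = []
    cols = []
    for fam, members in families.items():
        if len(members) == 0:
            raise ValueError(f"family {fam!r} has no members")
        idx = []
        for m in members:
            if m not in label_to_idx:
                raise ValueError(f"unknown model {m!r} in family {fam!r}")
            idx.append(label_to_idx[m])
        seen.extend(members)
        sub = evidence.log_evidence[:, idx]
        cols.append(special.logsumexp(sub, axis=1) - math.log(len(idx)))
    if sorted(seen) != sorted(evidence.model_labels):
        raise ValueError("families must partition the model set")
    return EvidenceMatrix(
        log_evidence=np.column_stack(cols), model_labels=tuple(families.keys())
    )


def family_bms(
    evidence: EvidenceMatrix,
    families: Mapping[str, Sequence[str]],
    **kwargs,
) -> BmsReport:
    """Family-wise random-effects comparison."""
    if len(families) < 2:
        raise ValueError("need at least two families")
    return rfx_bms(pool_families(evidence, families), **kwargs)
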