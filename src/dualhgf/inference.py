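"""Model inversion: MAP estimation, Laplace model evidence, and
simulate-and-refit parameter recovery.

Every model in the space pairs a perceptual family with a response family:

* perceptual P1 -- HGF, social exponent scaled by eta * omega_s (winner)
* perceptual P2 -- HGF, free additive bias on the social exponent
* perceptual P3 -- HGF, free multiplicative bias on the social exponent
* perceptual RW -- Rescorla-Wagner baseline with fixed learning rates
* response R1   -- softmax with decision noise beta only (winner)
* response R2   -- additional free weight zeta on the social stream

Free parameters are estimated in a transformed space (log for positive
parameters, log-odds for learning rates, identity for signed ones) with
independent Gaussian priors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from . import hgf, responses
from .task import TrialSequence

logger = logging.getLogger(__name__)

PERCEPTUAL_FAMILIES = ("P1", "P2", "P3", "RW")
RESPONSE_FAMILIES = ("R1", "R2")

_BOUND = 20.0  # transformed-space box constraint; prevents overflow


def to_natural(value: float, transform: str) -> float:
    if transform == "log":
        return math.exp(value)
    if transform == "logit":
        return 1.0 / (1.0 + math.exp(-value))
    if transform == "identity":
        return value
    raise ValueError(f"unknown transform {transform!r}")


def to_transformed(value: float, transform: str) -> float:
    if transform == "log":
        return math.log(value)
    if transform == "logit":
        return math.log(value / (1.0 - value))
    if transform == "identity":
        return value
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class ParamSpec:
    """One free parameter: its estimation transform and Gaussian prior
    (mean/variance on the transformed scale)."""

    name: str
    transform: str
    prior_mean: float
    prior_var: float

    def __post_init__(self) -> None:
        if self.transform not in ("log", "logit", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not self.prior_var > 0:
            raise ValueError("prior_var must be > 0")


# Default priors (transformed scale). sigma2_0 is fixed at 1 and mu2_0_ns at 0.
_PRIORS: Dict[str, ParamSpec] = {
    "omega_s": ParamSpec("omega_s", "log", -2.0, 4.0),
    "omega_ns": ParamSpec("omega_ns", "log", -2.0, 4.0),
    "eta": ParamSpec("eta", "log", 0.0, 1.0),
    "social_bias": ParamSpec("social_bias", "identity", 0.0, 1.0),
    "mu2_0_s": ParamSpec("mu2_0_s", "identity", 0.0, 1.0),
    "beta": ParamSpec("beta", "log", 0.0, 1.0),
    "zeta": ParamSpec("zeta", "log", 0.0, 1.0),
    "alpha_s": ParamSpec("alpha_s", "logit", 0.0, 1.0),
    "alpha_ns": ParamSpec("alpha_ns", "logit", 0.0, 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """A perceptual + response model variant with its free-parameter list."""

    name: str
    perceptual: str
    response: str
    params: Tuple[ParamSpec, ...]
    fixed: Mapping[str, float] = field(
        default_factory=lambda: {"sigma2_0": 1.0, "mu2_0_ns": 0.0}
    )

    def __post_init__(self) -> None:
        if self.perceptual not in PERCEPTUAL_FAMILIES:
            raise ValueError(f"unknown perceptual family {self.perceptual!r}")
        if self.response not in RESPONSE_FAMILIES:
            raise ValueError(f"unknown response family {self.response!r}")
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def param_names(self) -> Tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def n_params(self) -> int:
        return len(self.params)


def make_model_spec(
    perceptual: str,
    response: str,
    priors: Optional[Mapping[str, ParamSpec]] = None,
    **fixed_overrides: float,
) -> ModelSpec:
    """Assemble a ModelSpec with the default free-parameter layout."""
    table = dict(_PRIORS)
    if priors:
        table.update(priors)
    if perceptual == "RW":
        names = ["alpha_s", "alpha_ns"]
    else:
        names = ["omega_s", "omega_ns", "mu2_0_s"]
        if perceptual in ("P1", "P3"):
            names.append("eta")
        elif perceptual == "P2":
            names.append("social_bias")
    names.append("beta")
    if response == "R2":
        names.append("zeta")
    fixed = {"sigma2_0": 1.0, "mu2_0_ns": 0.0}
    fixed.update(fixed_overrides)
    return ModelSpec(
        name=f"{perceptual}{response}",
        perceptual=perceptual,
        response=response,
        params=tuple(table[n] for n in names),
        fixed=fixed,
    )


def default_model_space() -> List[ModelSpec]:
    """The comparison set: all perceptual families crossed with R1, plus the
    winning perceptual family with R2."""
    space = [make_model_spec(p, "R1") for p in PERCEPTUAL_FAMILIES]
    space.append(make_model_spec("P1", "R2"))
    return space


def perceptual_families(space: Sequence[ModelSpec]) -> Dict[str, List[str]]:
    fams: Dict[str, List[str]] = {}
    for m in space:
        fams.setdefault(m.perceptual, []).append(m.name)
    return fams


def response_families(space: Sequence[ModelSpec]) -> Dict[str, List[str]]:
    fams: Dict[str, List[str]] = {}
    for m in space:
        fams.setdefault(m.response, []).append(m.name)
    return fams


_LINK_BY_FAMILY = {"P1": "scaled", "P2": "additive", "P3": "multiplicative"}


def predict_probs(
    spec: ModelSpec, params: Mapping[str, float], trials: TrialSequence
) -> np.ndarray:
    """Per-trial P(agree with bet) for a model at natural-scale parameters."""
    if spec.perceptual == "RW":
        traj = hgf.rw_trajectory(
            hgf.RwParameters(alpha_s=params["alpha_s"], alpha_ns=params["alpha_ns"]),
            trials,
        )
    else:
        eta = params["eta"] if spec.perceptual in ("P1", "P3") else params["social_bias"]
        params_s = hgf.StreamParameters(
            omega=params["omega_s"],
            mu2_0=params["mu2_0_s"],
            sigma2_0=spec.fixed["sigma2_0"],
            eta=eta,
        )
        params_ns = hgf.StreamParameters(
            omega=params["omega_ns"],
            mu2_0=spec.fixed["mu2_0_ns"],
            sigma2_0=spec.fixed["sigma2_0"],
        )
        traj = hgf.filter_trajectory(
            params_s, params_ns, trials, social_link=_LINK_BY_FAMILY[spec.perceptual]
        )
    if spec.response == "R2":
        b = responses.weighted_combination(traj.mu1_hat_s, traj.a_ns, params["zeta"])
    else:
        b = traj.b
    return responses.softmax_prob(b, params["beta"])


def _natural(spec: ModelSpec, theta: np.ndarray) -> Dict[str, float]:
    return {
        p.name: to_natural(float(v), p.transform) for p, v in zip(spec.params, theta)
    }


def neg_log_joint(
    theta: np.ndarray,
    spec: ModelSpec,
    trials: TrialSequence,
    choices: np.ndarray,
) -> float:
    """Negative (log-likelihood + log-prior) in transformed parameter space."""
    lp = 0.0
    for p, v in zip(spec.params, theta):
        lp += -0.5 * ((v - p.prior_mean) ** 2 / p.prior_var) - 0.5 * math.log(
            2.0 * math.pi * p.prior_var
        )
    try:
        probs = predict_probs(spec, _natural(spec, theta), trials)
        ll = responses.log_likelihood(choices, probs)
    except (OverflowError, FloatingPointError, ValueError):
        return 1e10
    if not math.isfinite(ll):
        return 1e10
    return -(ll + lp)


@dataclass
class FitResult:
    """MAP fit of one model to one participant's betting-phase choices."""

    model: str
    params: Dict[str, float]  # natural scale
    params_transformed: Dict[str, float]
    log_joint: float
    log_likelihood: float
    log_evidence: float
    evidence_method: str  # "laplace" or "bic"
    hessian: Optional[np.ndarray]
    converged: bool
    n_restarts: int
    n_trials: int


def numeric_hessian(f, x: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    d = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    hess = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return hess


def laplace_log_evidence(
    log_joint: float, hessian: np.ndarray
) -> Tuple[Optional[float], bool]:
    """Laplace approximation: log joint + d/2 log 2pi - 1/2 log det(H).

    H is the Hessian of the *negative* log joint at the MAP. Returns
    (evidence, ok); ok is False when H is not positive definite.
    """
    d = hessian.shape[0]
    try:
        chol = np.linalg.cholesky(hessian)
    except np.linalg.LinAlgError:
        return None, False
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return log_joint + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet, True


def fit_map(
    trials: TrialSequence,
    choices: np.ndarray,
    spec: ModelSpec,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
) -> FitResult:
    """Invert one model against one participant's agree-with-bet choices.

    Quasi-Newton (L-BFGS-B) maximisation of the log joint in transformed
    space from the prior mean plus ``n_restarts - 1`` jittered starts.
    A failure of every restart is flagged, not raised.
    """
    choices = np.asarray(choices, dtype=int)
    if len(choices) != trials.n_trials:
        raise ValueError("choices and trials length mismatch")
    if len(choices) < 1:
        raise ValueError("need at least one trial")

    rng = np.random.default_rng(seed)
    means = np.array([p.prior_mean for p in spec.params])
    sds = np.sqrt([p.prior_var for p in spec.params])
    starts = [means]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(means + 0.5 * sds * rng.standard_normal(len(means)))

    obj = lambda th: neg_log_joint(th, spec, trials, choices)
    bounds = [(-_BOUND, _BOUND)] * spec.n_params

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            obj,
            np.clip(x0, -_BOUND, _BOUND),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "maxiter": 500},
        )
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not converged:
        logger.warning("fit_map: no restart converged for model %s", spec.name)

    theta = np.asarray(best.x, dtype=float)
    log_joint = -float(best.fun)
    natural = _natural(spec, theta)
    probs = predict_probs(spec, natural, trials)
    ll = responses.log_likelihood(choices, probs)

    hess = numeric_hessian(obj, theta)
    evidence, ok = laplace_log_evidence(log_joint, hess)
    if ok:
        method = "laplace"
    else:  # BIC fallback when the curvature is not positive definite
        logger.warning("fit_map: non-PD Hessian for %s; BIC fallback", spec.name)
        evidence = ll - 0.5 * spec.n_params * math.log(trials.n_trials)
        method = "bic"

    return FitResult(
        model=spec.name,
        params=natural,
        params_transformed={p.name: float(v) for p, v in zip(spec.params, theta)},
        log_joint=log_joint,
        log_likelihood=ll,
        log_evidence=float(evidence),
        evidence_method=method,
        hessian=hess,
        converged=converged,
        n_restarts=len(starts),
        n_trials=trials.n_trials,
    )


@dataclass
class RecoveryReport:
    """Simulate-and-refit outcome: per-parameter true-vs-recovered agreement.

    Correlations are computed on the transformed (estimation) scale.
    ``degenerate`` flags parameters whose true values have zero variance,
    for which a correlation is undefined.
    """

    model: str
    param_names: Tuple[str, ...]
    true_transformed: np.ndarray  # (n_agents, n_params)
    recovered_transformed: np.ndarray
    correlations: Dict[str, float]
    p_values: Dict[str, float]  # one-sided, H1: r > 0
    degenerate: Dict[str, bool]
    group_effects: Optional[Dict[str, float]] = None
    fits: Optional[List[FitResult]] = None


def recover(
    spec: ModelSpec,
    true_params: Sequence[Mapping[str, float]],
    trials: TrialSequence,
    seed: int = 0,
    n_restarts: int = 3,
    group_labels: Optional[Sequence[int]] = None,
) -> RecoveryReport:
    """Simulate choices from each true parameter set on a fixed task, refit,
    and report per-parameter Pearson correlations (transformed scale).

    When ``group_labels`` are supplied, the mean recovered difference
    (label 1 minus label 0) is reported per parameter.
    """
    if len(true_params) < 2:
        raise ValueError("need at least two parameter sets")
    rng = np.random.default_rng(seed)
    names = spec.param_names

    true_t = np.array(
        [
            [to_transformed(float(ps[n]), p.transform) for p, n in zip(spec.params, names)]
            for ps in true_params
        ]
    )
    rec_t = np.empty_like(true_t)
    fits: List[FitResult] = []
    for i, ps in enumerate(true_params):
        probs = predict_probs(spec, ps, trials)
        y = responses.simulate_responses(probs, rng)
        fit = fit_map(
            trials, y, spec, n_restarts=n_restarts, seed=int(rng.integers(2**31))
        )
        rec_t[i] = [fit.params_transformed[n] for n in names]
        fits.append(fit)

    corrs: Dict[str, float] = {}
    pvals: Dict[str, float] = {}
    degen: Dict[str, bool] = {}
    for j, n in enumerate(names):
        if np.var(true_t[:, j]) == 0.0 or np.var(rec_t[:, j]) == 0.0:
            degen[n] = True
            corrs[n] = float("nan")
            pvals[n] = float("nan")
            continue
        degen[n] = False
        r, p_two = stats.pearsonr(true_t[:, j], rec_t[:, j])
        corrs[n] = float(r)
        pvals[n] = float(p_two / 2.0 if r > 0 else 1.0 - p_two / 2.0)

    group_effects = None
    if group_labels is not None:
        lab = np.asarray(group_labels, dtype=int)
        group_effects = {
            n: float(rec_t[lab == 1, j].mean() - rec_t[lab == 0, j].mean())
            for j, n in enumerate(names)
        }

    return RecoveryReport(
        model=spec.name,
        param_names=names,
        true_transformed=true_t,
        recovered_transformed=rec_t,
        correlations=corrs,
        p_values=pvals,
        degenerate=degen,
        group_effects=group_effects,
        fits=fits,
    )
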