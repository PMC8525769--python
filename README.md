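# dualhgf

A tested, reusable implementation of a dual-stream (social / non-social)
hierarchical Gaussian filter for perceptual decisions under social
influence, together with everything needed to exercise it end-to-end on
synthetic cohorts:

- **Task design** (`dualhgf.task`) — chimeric face/scene trial sequences,
  exact-count bet assignment (50% or 75% accurate bets), and the
  cooperation/competition payoff lookup.
- **Perceptual models** (`dualhgf.hgf`) — two-level, two-stream HGF with
  precision-weighted updates, a recency-bias term on the non-social
  stream, three social-link variants (scaled / multiplicative / additive
  exponent), precision-weighted belief combination, and a
  Rescorla–Wagner baseline.
- **Response models** (`dualhgf.responses`) — power-softmax choice rule in
  bet-agreement space, an optional free stream weight, Bernoulli
  likelihood and simulation.
- **Inference** (`dualhgf.inference`) — MAP estimation in transformed
  space with Gaussian priors, Laplace approximation of log model
  evidence (BIC fallback for non-positive-definite curvature), and a
  simulate-and-refit parameter-recovery harness.
- **Model selection** (`dualhgf.bms`) — random-effects Bayesian model
  selection: variational Dirichlet scheme, exceedance probabilities
  (Monte Carlo, closed form for K = 2), Bayes omnibus risk, protected
  exceedance probabilities, and family-wise comparison.
- **Behavioral metrics** (`dualhgf.metrics`) — self-deception
  classification and confidence-weighted self-deception, questionnaire
  group cutoffs (paranoia ≥ 11, anxiety > 16), a mixed-effects
  motivational-bias regression, rank-difference insight scores, and
  Fisher-z correlation comparison.
- **Synthetic cohorts** (`dualhgf.cohort`) — full generative datasets with
  configurable group effects (elevated ω_ns / ω_s with high paranoia,
  elevated social prior mean under cooperation), simulated choices and
  1–7 confidence ratings.
- **IO / pipeline / CLI** (`dualhgf.io`, `dualhgf.pipeline`,
  `dualhgf.cli`) — schema-validated CSV readers, a simulate → fit →
  select → metrics pipeline, and a `dualhgf` command-line tool.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the acceptance criteria, including
the heavier simulate-and-refit checks (parameter recovery with 100
agents, model recovery with 50 agents, and a 200-participant full-circle
cohort test); the whole suite runs in a few minutes on one CPU.

## Command line

```bash
dualhgf simulate-task --experiment 1 --condition coop --seed 7 --out-dir task/
dualhgf simulate --seed 7 --out-dir cohort/          # synthetic cohort CSVs
dualhgf fit cohort/trials.csv --models P1R1,RWR1 --out fits.csv
dualhgf select fits.csv --out bms.json               # random-effects BMS
dualhgf metrics cohort/trials.csv --fits fits.csv --out metrics.csv
dualhgf recover --model P1R1 --n-agents 50 --out recovery.json
dualhgf run --seed 7 --out-dir run/                  # full pipeline
```

Model identifiers combine a perceptual family (`P1` scaled social
exponent — the winning variant; `P2` additive bias; `P3` free
multiplicative bias; `RW` Rescorla–Wagner) with a response family (`R1`
softmax only — the winning variant; `R2` adds a free stream weight).

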