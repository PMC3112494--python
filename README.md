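# bmr — post-hoc Bayesian model reduction

`bmr` scores large spaces of nested models from a **single** inversion of one
full model.  Under Gaussian (Laplace) assumptions, the log evidence of any
model whose priors are a restriction of the full model's priors has a closed
form in the full prior, the reduced prior and the full posterior — no refit
is needed.  Shutting a parameter off (prior variance → 0) is handled exactly
by a Savage–Dickey density ratio, so a model with a subset of parameters
enabled is scored in microseconds.  That turns "which of these 4096 models is
best?" from 4096 inversions into one inversion plus 4096 algebraic updates.

The package contains:

- `bmr.core` — the reduction primitive (`reduce`, `clamp`), model posteriors
  over a set of reductions, and fixed-effects pooling over subjects.
- `bmr.gaussian` — a Gaussian density type that tracks exact point masses
  (zero prior variances) explicitly rather than by ε-variance hacks.
- `bmr.search` — discrete model spaces defined by binary prior switches,
  with exhaustive and greedy block search and equality constraints
  (e.g. reciprocal connections that share one switch).
- `bmr.prior_opt` — continuous evidence maximization over prior
  hyperparameters (per-parameter variances / ARD, shared mean + variance).
- `bmr.glm` — a variational-Laplace inversion of a general linear model with
  unknown group noise precisions, plus the packaged dataset simulators.
- `bmr.network` — a 4-node linear stochastic network surrogate: simulation,
  coupling inversion and adjacency discovery.
- `bmr.experiments` / `bmr.cli` — end-to-end desk-scale experiments and a
  command-line surface (`bmr --help`).

## Worked example: needle in a haystack

Sixteen observations, twelve candidate regressors, of which four (indices
0–3) generated the data with unit coefficients.  Invert the full model once,
then score models post hoc:

```python
import numpy as np
from bmr import core, glm, search

data, truth = glm.simulate_selection_dataset(0)          # n=16, p=12
full = glm.invert(data, glm.default_priors(data.p, data.n_groups))
print(full.free_energy)                                  # -48.577

# Exact cost of shutting off one regressor (Savage-Dickey clamp):
core.clamp(full, [7], [0.0]).delta_f                     # +1.063  (decoy: evidence improves)
core.clamp(full, [0], [0.0]).delta_f                     # -16.923 (generating regressor)

# Score all 2^12 = 4096 on/off models from the same inversion:
space = search.SwitchSpace(base_prior=full.prior,
                           switchable=tuple(range(12)), gamma=8.0)
result = search.exhaustive_search(full, space)
result.best_switches          # (1, 1, 1, 1, 0, 0, 1, 1, 0, 0, 0, 0)
result.posterior_probs.max()  # 0.235
```

On this seed the maximum-posterior model keeps the four generating
regressors plus two decoys with posterior probability 0.235; the exact
generating support has probability 0.172.  With n = 16 and unit noise this
is genuinely ambiguous data — see `docs/methods.md` for how often the exact
support wins across seeds.

## Worked example: network discovery

A 4-node linear stochastic network with reciprocal chain coupling
1↔2↔3↔4 (strength 0.3, self-decay −0.6) observed for 256 bins:

```python
from bmr import experiments
out = experiments.run_network_experiment(seed=0)
out["found_pairs"]        # {(0, 1), (1, 2), (2, 3)}  — the generating chain
out["delta_f_by_size"]    # peaks at 3 connections: {0: -28.5, ..., 3: 14.2, 4: 10.3, ...}
```

The 64-model search (6 reciprocal pairs, each one switch) identifies the
chain, and the best evidence over models of each graph size peaks at the
generating size — the accuracy/complexity trade-off of the evidence.

## Command line

```sh
bmr simulate-glm --experiment selection --seed 0 --out data.csv
bmr invert-glm --data data.csv --out full.json
bmr search --full full.json --space space.json --out search.json
bmr simulate-network --seed 0 --out series.csv
bmr discover --series series.csv --out adjacency.json
bmr reproduce-figure 2 --out figs/
```

All commands write JSON/CSV artifacts with a provenance block; identical
invocations produce identical scientific content.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` encodes the replication claims one test per
criterion; three of them (selection confidence, reduction-vs-re-inversion
agreement, ARD variance collapse on the network) are known not to hold for
this implementation at desk scale and fail by design.  The remaining module
tests are the green suite.  `docs/methods.md` documents the model, the
generators and the limitations behind those failures.
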