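# predrigid

Prediction-rigidity diagnostics and dataset-construction tools for
additive regression models of molecular properties.

## The problem

Atomistic machine-learning models rarely predict a measurable quantity
directly: a total energy is a sum of per-atom local energies, a
body-ordered descriptor splits it across correlation orders, a
multi-scale model splits it between short- and long-range blocks.
These intermediate predictions have no reference values, so the
decomposition is partly arbitrary — and a model can look accurate
globally while its local or component-wise predictions are meaningless.
`predrigid` quantifies exactly how well-pinned each such prediction is.

## The metric

For a model with linear readout `w` trained by the weighted squared
loss `L(w) = Σᵢ λᵢ (gᵢ·w − yᵢ)² + ς²|w|²`, constrain one prediction
(weight-space gradient `g★`) to move by `Δε` and re-minimize.  The loss
rises by exactly

```
ΔL = R★ Δε²,     R★ = 1 / (g★ᵀ H⁻¹ g★),     H = Σᵢ λᵢ gᵢgᵢᵀ + ς²I
```

`R★` is the **prediction rigidity (PR)**.  Choosing `g★` selects what is
assessed:

| metric | `g★` | assesses |
|---|---|---|
| PR  | sum of a structure's environment feature rows | global prediction |
| LPR | one environment's feature row | a local (per-atom) prediction |
| CPR | global row masked to one feature block | one additive component (body order, SR/LR, ...) |

`H` is the generalized Gauss–Newton loss Hessian, so only first
derivatives of the model are needed; for deep networks with a linear
readout the same formulas apply to the last-layer latent features.
`1/R★` scaled by a noise variance is a posterior predictive variance,
and the exact increment theorem — adding a sample with loss weight λ
raises its own PR by exactly λ — underpins PR-guided active learning
and greedy dataset augmentation.

## Worked example

```python
import numpy as np
from predrigid import RigidityRegressor
from predrigid.synthetic import gen_linear_system

system = gen_linear_system(n_structures=50, envs_per_structure=3, d=6,
                           noise_sigma=0.05, seed=42)
X = np.stack([r.grad_w for r in system.rows])
y = np.array([r.value for r in system.rows])

model = RigidityRegressor(alpha=1e-6).fit(X, y)
print("global PR of first three structures:",
      np.round(model.rigidity(X[:3]), 2))
print("LPR of first three environments:   ",
      np.round(model.local_rigidity(system.featureset, env_ids=[0, 1, 2]), 2))
print("predictive variance (sigma^2/R):   ",
      model.predict_variance(X[:3], scale=system.noise_sigma**2))
```

prints

```
global PR of first three structures: [ 7.66 17.62  5.49]
LPR of first three environments:    [15.72 30.15  7.87]
predictive variance (sigma^2/R):    [0.00032632 0.0001419  0.00045522]
```

A PR of 7.66 means perturbing that structure's prediction by `Δε` costs
`7.66 Δε²` in loss — the training data pin it down that strongly; the
predictive variances are the inverse rigidities scaled by the noise
variance.  `GreedyAugmenter` then selects, from a candidate pool, the
samples that most increase the PR of chosen target predictions, and
`rank_by_lpr` / `lpr_enhancement` drive local active learning.

A CLI mirrors the library for file-based workflows:

```sh
predrigid synth --scenario linear --seed 7 --out system.h5
predrigid compute --container system.h5 --what lpr --out lpr.csv
predrigid rank --container system.h5
predrigid augment --container system.h5 --pool pool.h5 --targets 0,1 --k 5 --out trace.json
predrigid monitor --container system.h5 --frames traj.h5 --window 200 --out series.csv
```

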