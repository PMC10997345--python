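# larmex

Exogenous linear autoregressive mixed-effects (LARMEx) models for
**intraindividual affect networks** estimated from ecological momentary
assessment (EMA) data — a simulator, an ML/REML estimator with BLUP
prediction, and a parameter-recovery evaluation suite.

## The problem

EMA studies prompt one person for a handful of mood ratings per day over
days or weeks.  A natural model of the resulting dynamics is a network:
moods at time `t-1` drive moods at time `t` (auto- and cross-lagged edges),
and external events push on the moods contemporaneously.  A single VAR fit
to all days assumes the network never changes; `larmex` instead lets the
network vary from day to day.  For `k` moods `m` and exogenous input `e`,

    m_{i,t} = B_i^ar m_{i,t-1} + B_i^e e_{i,t} + B_i^c + eps_{i,t},
    B_i = beta + b_i,     b_i ~ N(0, G),   eps_{i,t} ~ N(0, sigma2 I),

so `beta` is the person's trait network, and the day effects `b_i` carry
the state-like variation, summarized by the covariance `G`.  Each day is
stacked into a standard mixed-model block `Y_i = X_i beta + Z_i b_i + eps_i`
with `q = k^2 + 2k` coefficients; fixed effects are estimated by GLS inside
a profiled ML/REML objective, and realized day effects are predicted by the
BLUP `b_hat_i = G_hat Z_i' V_i^{-1} (Y_i - X_i beta_hat)`.

The central practical question the package answers by simulation: *how many
days of EMA does it take to recover such a network, and which parts of it
are recoverable at all?*  (Short answer at the reference design: trait
edges to ~13% median relative error after 36 days; day-level edges plateau
near ~36% no matter how many days you add; everything degrades with noise,
missingness, and network size.)

## Worked example

```python
import numpy as np
from larmex import (SimConfig, fit, reference_two_mood_spec,
                    simulate_dataset, stack_dataset)

spec = reference_two_mood_spec()      # 2 moods: self-loops +0.3, cross -0.3,
                                      # exogenous (+0.3, -0.3), G = 0.03 I,
                                      # sigma2 = 0.02  (SNR ~ 6)
data = simulate_dataset(SimConfig(spec=spec, n_days=36, seed=7))
result = fit(stack_dataset(data))     # REML, diagonal G

print(np.round(result.beta_hat[:6], 3))   # six network fixed effects
print(np.round(spec.beta[:6], 3))         # truth
print(round(result.sigma2_hat, 4))
```

prints

```
[ 0.38  -0.349 -0.248  0.291  0.385 -0.366]
[ 0.3 -0.3 -0.3  0.3  0.3 -0.3]
0.02
```

— the trait network (AR matrix row-major, then the two exogenous effects)
recovered to within a few hundredths to ~0.08 from 36 simulated days, and
the innovation variance almost exactly.  `result.blups[i]` holds day `i`'s predicted
random effects; compare with `data.draws[i].b` to see how much harder the
day-varying edges are.

The same workflows are available from a shell:

```bash
larmex simulate --seed 1 --out out/            # EMA CSV + ground-truth sidecar
larmex fit out/ema.csv --out out/              # fit report JSON + BLUP CSV
larmex recover --config grid.yaml --out rec/   # replicate study with caching
larmex snr --seed 1                            # SNR of the configured process
```

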