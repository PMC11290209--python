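# bdokin

Batch kinetic modelling of acetoin and 2,3-butanediol (2,3-BDO) production
by engineered *Cupriavidus necator* H16, for bioprocess engineers and
systems biologists working on gas fermentation.

*C. necator* makes acetoin from pyruvate (AlsS/AlsD) and reduces it to
2,3-BDO with a butanediol dehydrogenase (BudC), either heterotrophically
from fructose or autotrophically from CO₂ with H₂ as electron donor and O₂
as acceptor (knallgas metabolism). `bdokin` implements the two batch process
models, fits their parameters to sparse time series, and does the yield and
efficiency bookkeeping for closed-bottle gas cultivations.

## The models

**Heterotrophic** (4 ODEs): Monod growth on fructose with optional lag and
2,3-BDO product-inhibition terms, a cell-lysis rate that rises as substrate
depletes, growth-coupled production of both products, and a back-reaction
BDO → acetoin that switches on once fructose is exhausted:

    dX/dt    = (μ − μ_d)·X          μ   = μ_max · c_S/(c_S + K_S) · (1 − e^(−t/t_lag)) · K_I/(K_I + c_B)
    dc_S/dt  = −(μ/Y_X,S)·X         μ_d = μ_d,min + μ_d,max · K_S/(K_S + c_S)
    dc_A/dt  = (μ/Y_X,A)·X + q_AB·X
    dc_B/dt  = (μ/Y_X,B)·X − (q_AB/Y_A,B)·X

**Autotrophic** (9 ODEs): the same growth/production skeleton driven by a
triple Monod in the dissolved gases, coupled to the headspace through
k_La-limited transfer toward the Henry equilibrium c\* = x·P·H:

    dc_i,l/dt = k_La·(c_i* − c_i,l) − X·μ/Y_X,i
    dc_i,g/dt = −k_La·(c_i* − c_i,l)·(V_L·R·T)/(V_G·P)

When CO₂ (and later O₂) deplete, the kinetics switch regimes: the CO₂ Monod
factor is dropped, acetoin↔BDO exchange reactions (two forward, one reverse)
activate per strain configuration, and the reverse reaction stops once the
electron acceptor is gone. Switches are event-located by the stiff (BDF)
integrator.

Parameters are estimated by bounded nonlinear least squares (weighted SSE
between model and observations, inverse-variance weights per observable) and
scored per observable with R² = 1 − SS_res/SS_tot. A synthetic-data module
generates noisy datasets from known ground truth under the study designs
(flasks at OD₆₀₀ 0.05 with 20 mM fructose; closed 1-L bottles at OD₆₀₀ 4,
50 mL liquid, 80/5/15% H₂/CO₂/O₂ at 1 bar with 1 mL liquid / 30 mL gas
withdrawn per sample and N₂ top-up).

## Worked example

```python
import numpy as np
from bdokin import (FitConfig, FitContext, fit_parameters,
                    default_het_design, generate_batch_dataset)
from bdokin.synthetic_data import NoiseModel

# a noiseless heterotrophic flask run, 12 samples over 120 h
design = default_het_design(seed=11, noise=NoiseModel.noiseless())
dataset, truth = generate_batch_dataset(design)

# fit growth rate and acetoin coupling from a perturbed start
t = design.params
free = {"mu_max": (0.01, 0.2, 1.15 * t.mu_max),
        "Y_X_A": (0.05, 1.0, 0.85 * t.Y_X_A)}
ctx = FitContext("het", design.state0.to_array(), t, design.structure,
                 None, design.horizon())
result = fit_parameters(dataset, FitConfig(free=free), ctx)
print(f"mu_max = {result.estimates['mu_max']:.4f} 1/h "
      f"(truth {t.mu_max})")
print(f"Y_X_A  = {result.estimates['Y_X_A']:.4f} g/g (truth {t.Y_X_A})")
print({k: round(v, 4) for k, v in result.r2.items()})
```

prints

```
mu_max = 0.0550 1/h (truth 0.055)
Y_X_A  = 0.2500 g/g (truth 0.25)
{'OD600': 1.0, 'acetoin': 1.0, 'bdo': 1.0, 'fructose': 1.0}
```

i.e. both parameters are recovered exactly from noiseless data and every
observable is reproduced with R² = 1. The same pipeline is available from
the shell (`bdokin synthesize / simulate / fit / yields`).

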