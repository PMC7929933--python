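# grnprecision

How does a developing tissue draw sharp gene-expression boundaries with
noisy genes?  This package implements a dynamical-systems analysis of the
question for the ventral neural tube, where graded Sonic Hedgehog (Shh)
signalling and the cross-repressive Pax6–Olig2–Nkx2.2 circuit position the
boundary between motor-neuron progenitors (pMN, Olig2+/Pax6+) and V3
progenitors (p3, Nkx2.2+).  It is written for quantitative/developmental
biologists who want to simulate the stochastic patterning model, compare
wild type against the Pax6 null and an Olig2-enhancer deletion, screen
small gene circuits for boundary precision, and quantify boundary width in
per-cell imaging data.

## The model in brief

Each gene follows a Hill-regulation ODE with chemical-Langevin noise,

    dx_i = [α_i G_i(s, x) − δ_i x_i] dt + sqrt((α_i G_i + δ_i x_i)/Ω) dW_i,

with `G_i ∈ [0,1]` a product of Hill activation/repression terms, `s` the
local Shh/Gli signal (`s(r) = s_max e^{−r/λ}` along the dorsoventral axis)
and Ω the system size that sets the intrinsic noise.  Across an
intermediate band of positions the circuit is bistable (pMN and p3 states
coexist with a saddle between them), and boundary precision reduces to the
rate of noise-driven escapes from the pMN state.  That rate is governed by
the Freidlin–Wentzell minimum action path (MAP): the cumulative action at
the transition point is the effective energy barrier, and the fate jump
time scales as `ln τ ≈ Ω·S`.  The package computes all of these —
bifurcation structure, stochastic tissues, first-passage times, gMAM
transition paths and their geometry (curvature, signal sensitivity,
third-node contribution) — plus a screen over random three-node networks
and a Gaussian-process boundary-width estimator for per-cell images.

## Worked example

```python
import numpy as np
from grnprecision import neuraltube as nt

for geno in nt.GENOTYPES:                       # wt, o2e33, pax6ko
    pos, width = nt.boundary_replicates(geno, n_replicates=6, seed=5)
    bar = nt.barrier_at_offset(geno, offset=0.1)
    print(f"{geno:7s} boundary at {np.median(pos):.3f}, "
          f"width {np.median(width):.3f}, barrier {bar.barrier:.4f}")
```

prints (positions and widths as fractions of the dorsoventral axis):

```
wt      boundary at 0.273, width 0.052, barrier 0.0330
o2e33   boundary at 0.459, width 0.074, barrier 0.0292
pax6ko  boundary at 0.306, width 0.239, barrier 0.0233
```

Losing Pax6 widens the boundary almost five-fold and shifts it dorsally;
the enhancer deletion sits in between — and the effective energy barrier
for a noise-driven pMN→p3 switch falls in the same order, with no change
in the noise of individual genes needed to explain it.  The numbered
scripts under `analysis/` walk through the full study: deterministic
structure, tissue boundaries, fate jump times, minimum action paths, the
three-node network screen, and boundary quantification on synthetic
sections; each writes its tables under `results/`.

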