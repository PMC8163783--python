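# neuriteflow

Graph-network surrogate modelling of motor-assisted material transport in
neurite networks.

Neurons synthesize most material in the cell body and ship it through a
highly branched tree of neurites, driven by diffusion and by molecular
motors walking along cytoskeletal filaments.  Solving the governing
transport equations in full 3D geometry is accurate but slow; this package
implements the surrogate-modelling alternative: decompose the neurite tree
into two repeating unit geometries — **pipes** (unbranched segments) and
**bifurcations** (3-way branch points) — learn a fast graph-network
simulator for each unit from reference solutions, and stitch the local
predictions back together with a learned **assembly** model that enforces
consistency on the shared cross sections.

It is aimed at computational neuroscientists and scientific-ML researchers
who want a self-contained, desk-scale testbed for learned PDE surrogates on
branched tubular geometries: everything — morphology generation, ground
truth, training, evaluation — runs from scratch on one CPU.

## The model

Free material with concentration `c0` diffuses and exchanges with a
motor-bound, advected species `c+` (unipolar filaments, so retrograde
transport is ignored):

    ∂c0/∂t − D ∇²c0 = −k₊ c0 + k₊′ c₊
    ∂c₊/∂t + u₊·∇c₊ =  k₊ c0 − k₊′ c₊

with Dirichlet values `c0 = c, c₊ = λ c` at the incoming end (λ is the
degree of loading).  The velocity is the Poiseuille profile
`u(r) = u_sec (1 − (r/R)²)` along the local centerline, with the section
speed set by volumetric flux conservation (area-proportional splitting at
branch points).  Default parameters: `D = 1.0 μm²/s`, `k₊ = 1.0 s⁻¹`,
`k₊′ = 0.5 s⁻¹`, `u_i = 0.1 μm/s`, `dt = 0.1 s`, `λ = k₊/k₊′ = 2`.

A finite-difference reference solver integrates these equations on
*template graphs*: cross sections of 17 nodes (1 center, 8 at `r = R/2`, 8
at `r = R`) along each unit's centerline, 23 nodes at a bifurcation branch
point.  The unit simulators are recurrent graph-network blocks — an
analytic edge function `[(c_j−c_i)/‖Δp‖, ‖Δp‖]`, mean/sum aggregation, a
width-32 ReLU node MLP, L = 3 message-passing steps — followed by an MLP
decoder that emits the next-step concentrations.  Training minimizes the
MSE plus the squared residuals of the two governing equations
(physics-informed loss); the assembly components are trained with an
interface-consistency penalty of strength α = 10.

Accuracy is reported as MRE (%): the root-mean-square nodal error divided
by the ground-truth concentration range.

## Worked example

```python
import numpy as np
from neuriteflow import (MorphologySpec, SimulationParams, TrainingConfig,
                         generate_morphology, decompose, build_unit_graph)
from neuriteflow.train import (make_unit_dataset, train_simulator,
                               make_network_cases, train_assembly,
                               network_rollout_mre)

# train a pipe and a bifurcation simulator on reference-solver data
sims = {}
for kind in ("pipe", "bifurcation"):
    ds = make_unit_dataset(kind, n_geometries=8, n_boundary_values=3,
                           n_steps=30, seed=101)
    cfg = TrainingConfig(epochs=60, seed=0, loss_mode="mse+pde")
    sims[kind], log = train_simulator(ds, cfg)

# train the assembly model on small networks, evaluate on held-out ones
cases = make_network_cases(6, n_steps=30, seed=202)
assembly, _ = train_assembly(sims, cases[:4], TrainingConfig(epochs=15, seed=0))
for case in cases[4:]:
    print(f"network rollout MRE: "
          f"assembled {network_rollout_mre(sims, assembly, case):.2f}%  "
          f"raw {network_rollout_mre(sims, None, case):.2f}%")
```

Output from this exact script:

```
network rollout MRE: assembled 4.07%  raw 4.43%
network rollout MRE: assembled 2.88%  raw 3.99%
```

i.e. the trained pipeline reproduces the reference solver's network-wide
concentration evolution to a few percent of the concentration range on
networks it never saw, and the assembly pass improves the raw stitched
prediction.

A thin CLI wraps the same functionality
(`neuriteflow generate|train|cv|predict|evaluate|run`); see
`neuriteflow --help`.

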