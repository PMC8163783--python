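# Methods

This note documents the modelling and numerical choices behind
`neuriteflow`: what is simulated, how the surrogates are built and trained,
which knobs matter, and what the synthetic testbed does and does not show.

## Transport model

Material transport in a neurite is modelled with two coupled fields on the
internal space of the neurite: a freely diffusing concentration `c0` and a
motor-bound concentration `c+` advected along the neurite axis,

    dc0/dt = D ∇²c0 − k₊ c0 + k₊′ c₊
    dc₊/dt = −u₊·∇c₊ + k₊ c0 − k₊′ c₊ ,

with `c0 = c`, `c₊ = λ c` held at the incoming end.  The filament system is
assumed unipolar, so the retrograde species and its rates are dropped; a
bidirectional mode (evolving `c−` with mirrored velocity) is retained
behind `SimulationParams.unidirectional=False` but is not exercised by the
shipped experiments.  Parameters and defaults:

| parameter | meaning | default |
|---|---|---|
| `D` | diffusivity of free material | 1.0 μm²/s |
| `k₊`, `k₊′` | filament attachment / detachment rates | 1.0, 0.5 s⁻¹ |
| `u_i` | inlet centerline speed | 0.1 μm/s |
| `λ` | degree of loading at the inlet | `k₊/k₊′` = 2 |
| `c_in` | inlet concentration | 1.0 mol/μm³ (varied per trajectory) |
| `dt` | recording time step | 0.1 s |

The flow field is not solved from the Navier–Stokes equations; instead the
analytic Poiseuille profile `u(r) = u_sec (1 − (r/R)²)` is imposed on every
cross section, oriented along the local centerline tangent, and `u_sec`
follows from conservation of volumetric flux `Q = A·u_sec/2`: constant
along a pipe, split between the two daughters of a bifurcation in
proportion to their cross-section areas.  This matches the prescribed inlet
profile exactly and keeps the velocity model closed-form.

## Geometry: morphologies, decomposition, template graphs

Synthetic morphologies are random binary trees with per-branch constant
radii tapering by a fixed ratio per branch order, gentle random curvature,
and skeletons resampled at a uniform spacing; the generator is fully
seeded.  SWC files (NeuroMorpho dialect) are read and written, so real
morphologies drop in wherever generated ones are used.  Skeleton nodes with
more than two children are split into cascaded 3-way branch points one
spacing apart, because the decomposition only defines pipes and
bifurcations.

Each degree-3 branch point claims three cross sections along every
incident branch (at 1–3 section spacings, spacing defaulting to twice the
local radius); what remains becomes pipes, split at 10 sections by default
so long branches produce several pipe units and pipe–pipe interfaces
exist.  The outermost claimed section of each stub is an *interface*
shared by the two adjacent units.  Cross-section frames are parallel-
transported from the root once per morphology; a pipe's interior frames are
re-transported from its upstream end with the residual twist distributed
linearly so both end frames are met exactly.  Interfaces therefore
coincide node-for-node between their two owners (the tests require
agreement to 1e-9 μm; construction gives exact equality).

Template sections carry 17 nodes — 1 center, 8 on an inner ring at `R/2`, 8
on the wall — and the branch-point section carries 23: the 17-node template
anchored to the bisector of the two child directions plus two extra wall
nodes astride each of the three joining branch directions.  The supplementary
layout the counts come from is not available, so the exact placement is a
documented package convention.  Edges: ring edges, center spokes and
inner–outer radials within a section; same-template-index links between
adjacent sections; the 6 extra branch-point nodes link to their angular
neighbours on the wall ring.

## Reference solver

Spatial operators on a template graph are the simplest consistent ones:
diffusion via the symmetric graph Laplacian with edge weights `1/ℓ²`
(exact second difference on a uniform chain; symmetric, hence mass-
conserving on closed domains, and monotone, hence non-negativity-
preserving under the step bound), and first-order upwinding of
`u·∇c₊` using the velocity component along each incident edge.  The wall
is a no-flux boundary simply because no edges leave the graph; wall nodes
have zero velocity and evolve by reaction only.  Outlets copy the nearest
interior section (zero gradient) unless an outgoing concentration is
prescribed.  Inlet Dirichlet values are re-imposed every substep.

Time stepping is explicit Euler.  The recording step (0.1 s) is subdivided
internally: the substep obeys both the classical bound
`0.4·min(h²/2D, h/u)` and an operator bound `0.9 / max row outflow rate`,
whichever is smaller — the operator bound matters because template-graph
nodes have up to ~10 neighbours, which the textbook `h²/2D` bound does not
account for.  A divergence guard aborts if any concentration exceeds 1e6
times the initial scale.

Whole-network ground truth glues all unit graphs at their interfaces
(duplicate nodes identified by construction), propagates the flux through
the unit adjacency to give every unit its inherited inlet speed, and
integrates on the merged graph.

Steadiness is declared when the max-norm relative change per second falls
below a tolerance (default 1e-4/s), checked every recording step.

## Unit simulators

Each unit kind (pipe, bifurcation) has its own simulator with the same
architecture: a linear encoder from the 13 nodal features (centred
coordinates; D, k₊, k₊′, u_i, c_in; `r/R`; section radius; analytic node
speed; the two current concentrations), L = 3 graph-network blocks, and a
3-hidden-layer width-32 ReLU MLP decoder with a linear 2-channel output
(the next-step `c0, c₊`), after which the inlet Dirichlet values are
re-imposed.  The edge function is analytic —
`[(c_j − c_i)/‖Δp‖, ‖Δp‖]` — and each GN block concatenates the node's
embedding with permutation-invariant statistics of the incident edge
attributes before applying a 2-hidden-layer width-32 ReLU MLP.

The reducer emits, per field, the mean gradient `mean(e₁)`, the summed
second-difference ingredient `Σ e₁/e₂ = Σ Δc/ℓ²` (scaled by the reference
Euler increment `dt·D = 0.1 μm²` so it stays O(Δc)), and an upwind-weighted
gradient `Σ (Δc/ℓ)·max(0, −û·d̂)`; plus the mean edge length and the node
degree.  The mean alone was found to be insufficient in principle: the
solver's one-step map needs `Σ Δc/ℓ²` (the Laplacian row) and a directional
statistic, neither of which is recoverable from mean gradient and mean
length once edge lengths vary within a neighbourhood.  With these
statistics the exact explicit-Euler map is (nearly linearly) representable,
which is what makes the simulators generalize across geometries.
Coordinates are centred per unit but *not* rescaled per unit (fixed 1 μm
length scale), so the operator coefficients the network learns are the
same for every unit; concentrations are normalized by the trajectory's
inlet concentration.

### Training

Adam with step learning-rate decay 1e-3 → 1e-6 (decade drops at 25/50/75%
of the epoch budget), batches of 16 graphs, 75/25 train/test split on
state pairs, fully seeded.  Two stabilizers address the classical
compounding-error failure of autoregressive one-step surrogates:

* small Gaussian input noise (σ = 0.01 in normalized concentration) with a
  clean target;
* the pushforward trick: with the current model, samples are advanced one
  extra model step (no gradient through it) and the training input is that
  drifted state, so the model learns to correct its own rollout drift.

Both are standard for learned simulators.  Noise much larger than σ ≈ 0.01
was found to destabilize rather than stabilize.  In addition, rollout
predictions are projected onto the model's invariant region: with Dirichlet
inlet values and sub-bound initial data the continuous model keeps
`0 ≤ c0 ≤ c_in` and `0 ≤ c₊ ≤ λ c_in` (maximum principle — diffusion and
upwind advection are monotone and the reaction exchanges the two fields at
a ratio bounded by λ), so clipping to that box (with 5% headroom) cannot
distort a correct prediction but makes learned-drift divergence
impossible.

The physics-informed loss adds the mean squared residuals of the two
governing equations, evaluated with the reference solver's own discrete
operators on the interior nodes, to the MSE.  The time derivative is
`(pred − prev)/dt` with `prev` the *clean* state at `t_k`; the spatial and
reaction terms are evaluated by default on that same clean state (a
forward-Euler residual, `residual_form="explicit"`), which keeps the loss
well conditioned — the stiff `1/ℓ²` operators never multiply the
prediction.  The backward-Euler alternative (`"implicit"`, operators on
the prediction) is implemented and tested but is harder to optimize.  All
loss terms carry unit weight.

## Assembly

For every (unit, neighbour) pair, the current unit's interface-section and
adjacent-section values and the neighbour's interface values (17 nodes
each, both fields) are concatenated and passed through the kind-matched
component MLP (pipe–pipe, pipe–bifurcation, bifurcation–bifurcation; three
hidden ReLU layers of width 32, linear output), whose output residually
updates the current unit's interface and adjacent sections.  In this
package's decomposition every interface is an ordinary 17-node section, so
the three components share their input/output sizes and differ only in the
unit-kind pair they serve; they remain separate models.  Updates are
computed Jacobi-style from the incoming prediction and applied afterwards,
making the pass independent of unit enumeration order; finally the two
sides of each interface are averaged to a single value.  Zero-initializing
the component output layers makes the initial assembly an exact identity
passthrough.

The assembly loss is the MSE over the two assembled units plus α times the
mean squared two-sided interface discrepancy (α = 10).  Training samples
are (network, time step, interface) triples: the unit simulators produce
intermediate predictions from the ground-truth state, the component
updates both sides, and the loss compares against the glued-solver truth
at the next step.

Network rollout: at each step every unit simulator advances its local
state — interior units take their upstream neighbour's current interface
values as per-node inlet Dirichlet data, the root unit takes the network
boundary condition, and each unit's inherited inlet speed comes from the
flux propagation — then one assembly pass (configurable) reconciles the
interfaces and the result feeds the next step.

## Evaluation

The error metric is the printed pair: a root-mean-square nodal error
(called MAE for continuity with the surrounding literature, although the
formula is an RMS) and the MRE, that RMS divided by the ground-truth
concentration range, in percent.  Simulator cross-validation folds by
trajectory (geometry × boundary value) with seeded assignment, and scores
each held-out trajectory the way the simulator is used — a full
autoregressive rollout from the initial state, per-step MRE averaged over
steps, then over trajectories and folds.  A sample-level folding mode with
one-step scoring is also provided.  Network-level evaluation rolls out the
full pipeline on held-out networks and averages the per-step MRE of the
glued field.

## Problem sizes

The shipped experiments are desk-scale by design: unit datasets default to
8 geometries × 3 boundary values × 30 time steps (≈ 700 samples per unit
kind; boundary values vary the inlet concentration with λ fixed, so after
normalization their diversity is limited and geometry variation carries
the dataset), 50-epoch trainings, and networks of 1–2 bifurcations.  These
sizes were chosen so a full generate → solve → train → evaluate cycle
completes in minutes on one CPU while the trained models still generalize;
`scripts/acceptance.py` records the exact sizes it uses.

## Limitations, and what the synthetic testbed does not show

* Ground truth comes from the package's own graph discretization, not from
  a 3D finite-element/IGA solve; agreement between surrogate and solver
  does not certify agreement with full 3D physics (no secondary flows, no
  pressure field, no radial advection).
* Because the training targets are generated by the same discrete
  operators used in the physics residual, the residual term carries little
  information beyond the data term in this testbed; its measured effect on
  accuracy is small in either direction here, unlike settings where truth
  comes from an independent solver.
* The generator produces smooth, moderately tapered binary trees; sharp
  radius steps, high-curvature kinks, somata and very short branches are
  not represented, and the decomposition rejects branches too short to
  host a bifurcation's claimed sections.
* Simulation parameters (D, rates, u_i) are held at their defaults across
  the shipped datasets; the feature vector carries them, but
  generalization across physical parameters is untested.
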