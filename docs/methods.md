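# Methods

`vasoadapt` couples a biphasic microvascular blood-flow simulator with an
adjoint-based inverse solver that computes the vessel-diameter changes
needed to raise the time-averaged blood flow in a prescribed "activated"
vessel set — the hemodynamic signature of functional hyperaemia — while
perturbing the rest of the network as little as possible.

## Forward model

The vasculature is a graph of straight-pipe vessels (edges, with
diameter `d` and length `l` in µm) meeting at junction nodes.  At every
global time step the flow obeys Poiseuille's law per vessel,

    q_ij = T_ij (p_i − p_j),      T_ij = π d_ij⁴ / (128 l_ij μ_p μ_rel,ij),

and mass balance at every node; fixed pressures at boundary nodes close
the linear system.  The Laplacian is assembled sparsely, Dirichlet rows
are eliminated symmetrically and the interior system is solved directly;
the residual of the node balance is bounded by 1e−12·max|q| in the test
suite at every step.

Blood is biphasic: red blood cells (RBCs) are tracked as individual
point particles.  Each vessel's tube haematocrit `H_t` follows from its
particle count and geometry, and three empirical in-vitro laws
(Pries–Secomb parameterizations) close the model:

* relative apparent viscosity `μ_rel(H, d)` (Fåhraeus–Lindqvist effect),
  evaluated with the tube haematocrit by default (a switch evaluates it
  with the discharge haematocrit instead, since the original law was
  fitted against `H_d`);
* the tube/discharge haematocrit relation `H_t/H_d = H_d + (1−H_d) r(d)`,
  inverted in closed form (a quadratic in `H_d`); `H_d ≥ H_t` throughout
  the capillary range `d ≳ 2.5 µm`;
* the phase-separation law giving the probability that an RBC at a
  divergent bifurcation enters a given daughter, a logit law in the
  fractional blood flow with cutoffs at `X₀ = 0.4/D_parent`.

Particles advance by `v_rbc Δt` along their vessel, where
`v_rbc = q/A · H_d/H_t ≥ q/A` (RBCs outrun the bulk flow).  A particle
reaching a junction is handed to the downstream vessel — sampled from
the phase-separation law at divergent bifurcations, deterministic
otherwise; bifurcations with more than two outflows apply the
two-daughter law pairwise against the pooled remainder.  A particle may
cross at most one junction per step (at Δt = 0.4 ms a capillary transit
takes hundreds of steps, so multi-junction hops do not occur in
practice); leftover travel is advanced into the new vessel at that
vessel's velocity.  Particles reaching a fixed-pressure boundary leave
the network.  Inflow boundaries carry a prescribed inflow tube
haematocrit `H_t,in`; each inflow vessel maintains a fractional
accumulator incremented by the distance travelled times the target
linear cell density and injects one particle at the vessel entrance
whenever the accumulator exceeds one.  This deterministic rule matches
`H_t,in` in long-run average without Poisson clumping.  Particle
bookkeeping satisfies `injected − exited = Δ(count)` exactly, and
identical seeds give bit-identical trajectories.

Vessels with transiently crowded haematocrit (`H_t > 0.95`, possible in
near-stagnant branches) keep their physical particle count, but the
empirical laws are evaluated at the cap; a warning is emitted once.

Units: µm, ms, Pa, fL.  Plasma viscosity defaults to 1.2 mPa·s
(= 1.2 Pa·ms in internal units), RBC volume to 49 fL (mouse).  The RBC
volume is not pinned by the study this package reproduces; 49 fL follows
the cited model lineage for mouse cortex and is configurable.

## Inverse model

The parameters are relative diameters `α_ij = d_ij/d_ij⁰` of an
adaptable vessel subset (non-adaptable vessels keep `α = 1`; optional
clipping, e.g. ±15%, mimics physiological dilation limits).  Because
RBC dynamics make instantaneous flows stochastic, the problem is posed
on window averages `⟨q⟩, ⟨p⟩` over `N_Δt` steps.  A representative
transmissibility

    T̃_ij = ⟨q_ij⟩ / (⟨p_i⟩ − ⟨p_j⟩)

defines a deterministic linear network that reproduces the averaged
state exactly.  Where the averaged pressure drop is below `η` times the
boundary-pressure spread (default `η = 1e−8`), or where noise makes the
ratio negative, the window mean of the instantaneous transmissibility is
substituted, keeping `T̃ > 0`.

The cost combines the primary activation target with a secondary
constraint:

    J = ((q̄_sim − q̄_tar)/q̄_tar)² + ϵ (ρ − ρ_min)²

where `q̄_sim` is the length-weighted mean of the activated flows signed
by their frozen baseline directions, `q̄_tar = 1.3 q̄⁰_sim` for a +30%
activation, and `ρ` is the Euclidean norm of the flow changes outside
the activated set, normalized by `q̄_tar`.  The gradient `dJ/dα` uses
the adjoint method: one extra interior solve with the same (symmetric)
averaged system matrix, plus the analytic derivative

    ∂T̃/∂α = π d⁰⁴ α³ / (32 l μ_p μ̃_rel),

which holds the representative viscosity `μ̃_rel = π d⁴/(128 l μ_p T̃)`
fixed.  The haematocrit-feedback term `∂μ̃_rel/∂α` has no closed form
under RBC noise and is neglected; its sign never opposes the geometric
`d⁴` term, so this costs convergence speed, not the solution.  The
adjoint gradient is verified against finite differences of the averaged
system (with `μ̃_rel` frozen accordingly) to a relative 1e−5 in the test
suite, for both cost terms.

The cost partials with respect to the averaged flows are applied per
edge through the chain rule `⟨q⟩ = T̃ Δ⟨p⟩`; for the secondary term this
sums over every non-activated edge incident to a node, which is the
exact derivative of `ρ` (a formulation that restricts the sum by node
membership in the activated node set is equivalent whenever every edge
between activated-region nodes is itself activated, as in the honeycomb
scenario).

### Two-phase driver

Phase 1 runs plain gradient descent on the primary term alone (ϵ = 0):
forward window → averages → cost → adjoint gradient → `α ← α − γ dJ/dα`.
Phase 2 activates the secondary term (ϵ = 1 by default), initializes
`ρ_min` just below the phase-1 ρ and, after each reconvergence of the
primary term, tightens `ρ_min` geometrically (factor 0.9 by default).
A level counts as reconverged when the filtered primary term is below
`tol` while the filtered ρ has followed `ρ_min` to within a 10% slack;
a level that fails to reconverge within its iteration budget is
infeasible, and the driver reverts to the last feasible state.  This
realizes the schedule "start from the unconstrained ρ and reduce it
until the target can no longer be met".

### Step size, noise and convergence detection

The step-size scale γ is specified as the largest per-iteration change
of any single α at the first gradient evaluation (default 0.005); the
resulting absolute step is then held constant, re-normalized at each
phase/level transition (the two cost terms have very different gradient
magnitudes), and halved automatically if the filtered cost increases
over ten consecutive iterations.

Convergence on noisy costs: with discrete RBCs a 500-step window mean
of the activated flow fluctuates by ~1–2% on the honeycomb test case,
so the raw per-window cost has a noise floor well above `tol = 1e−5`
and single-window dips below `tol` say little about the true state.
The driver therefore evaluates the cost at the moving average of
`q̄_sim` and ρ over `filter_window` iterations (default 30), which
suppresses the variance floor below `tol`, and declares convergence
only on this filtered cost (deterministic plasma-only runs use the raw
cost).  On convergence the returned α is the average over the same
window — the gradient iteration dithers in a noise ball around the
optimum, and averaging removes the arbitrariness of the stopping
iterate.  Finally the converged diameters are frozen and measured over
a longer assessment window (default ten per-iteration windows) to
report unbiased converged averages.

The reported activation ratio divides the converged activated mean flow
by the baseline value measured by the same procedure, so the (noisy)
absolute calibration of the baseline cancels.

`dir⁰` for an edge whose baseline mean flow is exactly zero is set to
+1 along the stored orientation with a warning.

## Synthetic test network

The honeycomb generator builds a planar lattice of hexagonal cells
(side = vessel length 75 µm, uniform baseline diameter 4.5 µm — the
mean capillary geometry of mouse cortex), with every interior junction
of degree 3.  One inlet (left-most node) and one outlet (right-most
node) carry fixed pressures; the default drop is 200 Pa per edge of the
inlet–outlet graph distance, which yields baseline RBC velocities of
0.5–1 mm/s, and the inflow tube haematocrit is 0.3.  The default 9×9
cell lattice (278 vessels) keeps the 30-edge activated region — the
central cell plus its six neighbours, a "flower" of 7 hexagons — at
least three edge-generations away from any boundary.  Relative results
(activation ratios, dilation patterns) are insensitive to the absolute
pressure scale; in the plasma-only limit the flow field is exactly
linear in the boundary pressures.

Simulations start from vessels uniformly seeded at the inflow
haematocrit and run a warm-up (default twelve per-iteration windows;
6000 steps for the honeycomb scenario) before the baseline window: the network haematocrit field relaxes over
several thousand steps, and a baseline measured mid-transient would
bias the activation target.

What the honeycomb emulates — a dense, highly interconnected capillary
bed with uniform geometry — and what it does not: real microvascular
networks are three-dimensional, heterogeneous in diameter and length,
hierarchically fed by arterioles and drained by venules, and have many
boundary nodes.  Passing tests on the honeycomb therefore validate the
mechanics (conservation, rheology, adjoint consistency, constrained
convergence), not predictions for any real cortical network.

## Numerical choices and limitations

* Direct sparse solves; the contract is the residual bound, not the
  method.
* Time step Δt = 0.4 ms and `N_Δt = 500` averaging windows by default.
* Problem sizes: the shipped study runs use the 9×9-cell honeycomb
  (278 vessels, ≈ 2000–3000 RBCs); a phase-1 inversion takes on the
  order of a minute on one core.
* Zero-flow vessels stall their particles; a later flow reversal moves
  them back.  Near-stagnant side branches can crowd with cells (see the
  haematocrit cap above) — a known artifact of point-particle advection
  without volume exclusion.
* The stochastic noise floor scales inversely with window length; on
  networks much smaller than the honeycomb the default tolerances may
  require longer windows.
* Only diameters are inferred.  The adjoint machinery is generic in the
  parameter vector (boundary pressures or lengths would enter through
  their own `∂g̃/∂·`), but no such extension is implemented.
* No oxygen transport, vessel compliance, pulsatility or signalling:
  the model is purely hemodynamic, in the low-Reynolds, low-Womersley
  regime of the microcirculation.
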