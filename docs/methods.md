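# Methods

## The model

`gapdyn` implements the connectionist (gene-circuit) model of the
*Drosophila melanogaster* trunk gap gene system. The state variables are
the protein concentrations `g_a` of the four trunk gap genes *hb*, *Kr*,
*kni* and *gt* in each nucleus of a one-dimensional row spanning 35–75%
egg length (anterior pole at 0%). Within a nucleus,

    dg_a/dt = R_a · φ(u_a) − λ_a · g_a
    u_a     = Σ_b w_ba g_b + Σ_m e_ma g_m + h_a
    φ(u)    = ½ (u / √(u² + 1) + 1)

`R_a` is the maximal production rate (concentration/min), `λ_a` the
linear decay rate (1/min), `W = (w_ba)` the gap–gap interconnectivity
matrix (regulator-by-target orientation: `w_ba` is the effect of
regulator *b* on target *a*), `E = (e_ma)` the weights of the external
maternal inputs Bcd and Cad, and `h_a` a constant threshold encoding
basal activity. φ maps total regulatory input to fractional promoter
activity in (0, 1), so every equilibrium concentration is bounded by the
saturation level `R_a/λ_a`.

The model is hybrid in time: continuous dynamics during interphase,
production switched off (`R_a = 0`) during mitosis, and an
instantaneous nuclear division at the end of C13 mitosis. Diffusion is
omitted, which makes every nucleus an independent 4-dimensional system
driven by its local, time-varying maternal inputs — 41 nuclei × 4 genes
= 164 state variables in total over the trunk.

### Stage timing

The literature source for the modelled stages gives no numeric
durations, so the schedule is a package default, fully configurable
through `StageSchedule`: t = 0 at C13 onset, 16 min C13 interphase,
5 min C13 mitosis with the division at its end (t = 21 min), then
50 min of C14A divided into eight equal time classes T1–T8 of 6.25 min.
Only the relative structure matters for the analyses; all C14A-based
computations key off class boundaries and midpoints, not absolute
times.

### Nuclear lattice and division

C13 nuclei sit on a 2% lattice (21 mothers at odd positions 35–75%).
At division each mother at position *p* produces daughters at *p* ± 0.5%
which are rounded (half-up) to the 1% C14A lattice, i.e. daughters at
*p* and *p* + 1; the daughter that would fall outside the maternal
tables' position support (76%) is dropped, leaving exactly 41 C14A
nuclei at integer positions 35–75%. Daughters inherit the mother's
concentrations unchanged — the minimal assumption, since the modelled
quantity is a concentration, which instantaneous cytoplasm partition
preserves.

### Numerics

The reference integrator is `scipy`'s LSODA at rtol 1e−8 / atol 1e−10,
run segment-by-segment with exact stops at phase boundaries so the
mitotic production switch is never smeared across a step. `simulate_row`
is a literal loop over single-nucleus integrations (nuclei are exactly
independent). A fast path, `gapdyn.fitting.simulate_ensemble`, stacks
all nuclei into one system at rtol 1e−6 for use inside optimisation
loops; it agrees with the reference path to ~1e−4 absolute on the
synthetic circuits and is never used where the reference accuracy is
asserted.

## Synthetic data generator

The generator emulates the study conditions so that every downstream
stage is testable without the original (externally deposited)
measurements. What it reproduces, and what it does not:

- **Maternal gradients.** Bcd-like: `A·exp(−(x−35)/ℓ)` with A = 65 a.u.
  and ℓ = 11.5%, chosen so the gradient spans ≈ 23 → 7 a.u. between 47
  and 61% — the concentration window the regime analyses probe — and
  passes ≈ 15 a.u. near 52%. Cad-like: a logistic rise
  `P·(0.52 + 0.48·σ((x−53)/6))` with P = 115 a.u., spanning ≈ 70 → 108
  a.u. over the same window. Both decline mildly and linearly in time
  (default 2% per 6.25-min class for Bcd, half that for Cad); a seeded
  per-gene amplitude jitter of at most 1% makes different seeds produce
  different tables without breaking monotonicity. Real gradients have
  nucleus-to-nucleus noise and embryo-to-embryo variability that the
  generator deliberately omits.
- **Ground-truth circuits.** The `full` archetype wires the
  alternating-cushions architecture: strong mutual repression between
  the non-overlapping pairs (hb, kni) and (Kr, gt) (weights drawn from
  [−0.048, −0.038]), weak asymmetric repression of each anterior
  neighbour by its posterior one ([−0.0035, −0.0015]), weak
  auto-activation ([0.004, 0.007]), Bcd activating hb and Kr, Cad
  activating kni and gt. Thresholds are drawn so the hb/kni race tips
  near 48% and the Kr/gt race near 57%, which yields staggered domains
  (hb+Kr anterior, Kr declining through the middle, kni from ~51%, gt
  from ~61%) and a multistable→monostable bifurcation of the
  (hb, Kr, kni) subcircuit near 51–52%. The `acdc` archetype is the
  three-gene motif: one strong double-negative pair plus a weak
  three-gene repression cycle.
- **Datasets.** Circuits are simulated from zero initial concentrations
  at C13 onset (maternal inputs establish the domains), sampled at the
  T1–T8 class midpoints per nucleus, and perturbed with independent
  zero-mean Gaussian noise truncated at zero — the simplest noise model
  consistent with concentration positivity. Real data have spatially
  correlated errors and per-gene calibration differences.

Because the generator's domain topology (which genes are active where)
is simpler than the real system's — gt has no anterior domain, Kr's
domain is anterior-anchored rather than central — tests that pass on it
demonstrate the correctness of the *machinery* (simulation, censusing,
classification, screening, fitting), not fidelity to the real fly.

## Node-sensitivity screen

A gene is removed by deleting its row and column of `W`, its maternal
column, and its `R`, `λ`, `h` entries. Full and reduced circuits are
integrated over C14A only, from the full model's state at T1, and
compared at the eight class midpoints with

    d = √( Σ_{i=1..8} Σ_a (g_a^full(T_i) − g_a^reduced(T_i))² / 8 )

where the removed gene's concentration in the reduced trajectory is
zero. The placement of the square root and the 1/8 follows from
requiring that a constant offset δ in a single gene yields d = δ, which
makes d a scaled Euclidean metric (symmetry, identity, triangle
inequality). A consequence of entering the removed gene as zero is that
d is bounded below by the full model's own expression of that gene, so
"insensitive" regions are regions where the gene is both dispensable
*and* barely expressed. The default region-calling threshold is 5% of
the maximum d in the scan (the notion of "close to zero" is not
quantified in the source literature); it is exposed as a parameter and
a CLI flag.

## Subcircuits

`extract_subcircuit` restricts `W` to three member genes (keeping
auto-activation), keeps their full maternal rows and `R`, `λ`, `h`.
Subcircuits are simulated over C14A only — no mitosis, no division —
from the full model's member-gene state at T1. Trajectory agreement is
quantified by the d-metric applied to per-gene residuals normalised by
each gene's full-model dynamic range (max − min over the eight
classes), so a gene displaced by its whole range scores 1 and genes
with different absolute scales are comparable. The canonical module
regions follow the odd-percent boundaries (35–47, 49–59, 61–75), with
the nuclei at 48% and 60% assigned to no module.

## Phase-space analysis

Freezing the maternal inputs at a time point makes the system
autonomous; its steady states are found by Newton–Raphson with the
analytic Jacobian

    J_ab = R_a φ′(u_a) w_ba − λ_a δ_ab,   φ′(u) = 1 / (2 (u²+1)^{3/2})

from a regular 5-per-dimension seed grid over [0, R_a/λ_a] plus any
user seeds (e.g. trajectory endpoints). Newton iterates are not
clipped, but converged roots are discarded if any coordinate is below
−1e−6 or above 1.5·R_a/λ_a. Tolerances: residual max-norm 1e−9
(absolute, a.u.); per-axis deduplication at 1e−4 of the saturation
level; eigenvalue real-part tolerance 1e−6 and imaginary tolerance
1e−9 for classification. Labels follow the sign pattern of the
eigenvalues (point attractor, spiral sink, saddle, unstable
node/focus); any eigenvalue with |Re| within tolerance of zero sets a
near-bifurcation flag instead of forcing a class, because proximity to
criticality is precisely the quantity of interest and silent
misclassification would corrupt the phase diagrams. Portraits at
successive time points are computed independently (no continuation).

An independent brute-force oracle, `basin_census`, integrates a dense
grid of initial conditions (20 per axis by default) forward for
60/min(λ) and clusters the endpoints; it shares no code path with the
Newton census and is used to validate census completeness.

## Regime classification and phase diagrams

A frozen circuit's regime is read from its attractor census: one
attractor → monostable, several → multistable, with the
"damped-oscillatory" qualifier when any attractor is a spiral sink.
With the cycle check enabled, an empty attractor set or an unstable
focus triggers `detect_limit_cycle`, which integrates long trajectories
(default horizon 50/min(λ)), discards the first half as transient, and
reports a sustained cycle iff some gene's peak-to-peak amplitude
exceeds 1% of its saturation and successive cycle amplitudes agree to
within 5%. Phase diagrams (maternal level × position, weight × position,
weight × weight, or the two composite controls of the simplified model)
classify each cell independently with all other inputs frozen at their
T1 values; cells are pure functions of their parameters, so refining a
grid never changes previously computed labels. Bifurcation boundaries
on discrete grids are reported as the midpoint between the last cell of
one regime and the first of the other.

### Simplified AC/DC model

The two-parameter family `simplified_acdc(p, n)` has equal decay rates
(0.1/min), equal production (10/min), constant basal activation
(h = 2.5), no auto-activation and no maternal input. The
negative-feedback control *n* sets the three repressions of the cycle
g1 ⊣ g2 ⊣ g3 ⊣ g1; the positive-feedback control *p* adds the mutual
repression of the double-negative pair (g1, g2), the shared g1 ⊣ g2
edge carrying −(n + p). Closed-form composite control parameters can be
derived analytically for such motifs, but this package does not
reproduce that derivation; the additive mapping above is its own
(configurable) definition and preserves the monotone meaning of the two
axes (p = 0, large n: repressilator-like
limit cycle; n = 0, large p: toggle-like multistability; both weak:
monostable). Under the shallow φ used here, a strong repression cycle
structurally prevents the second toggle state no matter how strong the
pair is (the third gene keeps one pair gene suppressed), so
multistability requires weak negative feedback — the multistable and
limit-cycle regions of the control map are separated by
damped-oscillatory territory rather than adjacent.

## Fitting

The objective is the weighted RMS
`√(Σ w_k (model_k − data_k)² / Σ w_k)` over matching
(position, time class, gene) records, with unit default weights (the
original study's weighting scheme is defined in prior literature and
not reproduced here). Model output is the full forward simulation of
the hybrid schedule from zero initial concentrations, sampled like the
data.

The optimiser is deliberately desk-scale, replacing cluster-scale
simulated annealing with deterministic multi-start bounded local
optimisation. Each start is first decomposed into four independent
per-target least-squares problems in which the regulator concentrations
are taken from the data (piecewise-linear in time, lightly smoothed in
space with a [1, 2, 1]/4 kernel — domains are smooth in position, so
this suppresses measurement noise in the regressors without moving
boundaries). This gradient-matching stage costs a few one-dimensional
ODE solves per target and is what recovers interaction signs; the best
start by full-simulation score can then be polished with a short
bounded least-squares run against the forward simulation. The
unmodified initial circuit is always kept as a candidate, so the final
score never exceeds the initial one. Default bounds: gap–gap weights
[−0.05, 0.05]; maternal weights [−0.2, 0.2] (maternal concentrations
reach ~115 a.u., so unit-scale drive needs weights up to ~0.1);
production (0, 30]; decay (0.01, 0.5]; thresholds [−10, 10].

`parameter_recovery_report` calls an interaction strong when its
maximal input contribution `|w_ba|·R_b/λ_b` exceeds 2 dimensionless
units, which selects exactly the four double-negative pair weights of
the synthetic ground truth. At 5% noise the sign of the Kr→gt pair
weight is the least identifiable quantity: posterior Kr is expressed at
near-noise levels and its spatial profile is collinear with Bcd, so a
free Bcd→gt weight can absorb part of its effect. The recovery study
(10 seeded datasets, 4 starts, no polish) typically recovers all strong
signs in 7–9 of 10 runs depending on the seed set; more starts help
(a failing run recovers with 10) at proportional cost.

## Problem sizes used by the shipped studies

The acceptance studies run at sizes chosen to keep a full desk
reproduction in minutes: 20 random circuits × 20³ initial conditions
for census completeness; a 9 × 9 control-parameter map (81 cells, cycle
check on); a 1200-min oscillation probe (> 10 cycles after the
transient cut); 10 fits of 1312-record datasets with 4 starts each.
Grids for the published-parameter sweeps (Bcd steps of 0.01, Cad 0.1,
weights 0.0005) are implemented at the conventions of the source
analyses and run in minutes per sweep when that parameter file is
supplied.

## Known limitations

- The published *D. melanogaster* parameter set is not distributable
  with the package; every analysis that quotes its numbers (52%
  boundary, ~15 a.u. Bcd threshold, vanishing point near −0.0025)
  requires the user to supply that circuit file
  (`data/published/dmel_circuit.txt`).
- No diffusion, no stochasticity, 1-D geometry: inherited scope of the
  diffusion-less model.
- Instantaneous portraits are recomputed per time point; steady states
  are not tracked through time, and geometric-capture events before
  C14A are out of range.
- `detect_limit_cycle` is a simulation-based test, not a proof; a cycle
  with period longer than half the horizon, or an attractor with a
  basin missed by the probe initial conditions, would be misjudged. The
  default horizon (50/min(λ)) is ~33 periods of the simplified model's
  fastest oscillations but fewer for near-critical slow cycles.
- The per-target fitting stage assumes the data densely sample every
  regulator; with missing genes or classes it degrades to the plain
  multi-start local search.
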