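# Methods

`phaselattice` analyzes cluster synchronization in two-dimensional
torus networks of tonically firing inhibitory interneurons.  The
pipeline has four stages: a single-cell conductance-based model, its
phase reduction, closed-form stability analysis of cluster states on
the lattice, and full-network simulation experiments.  This note
records the model, the numerical choices, and the limits of what the
computations show.

## Single cell

Each cell is a Wang–Buzsáki interneuron: fast sodium (instantaneous
activation `m_inf(V)`, inactivation `h`), delayed-rectifier potassium
(`n`), leak, and a first-order synaptic gate `s` driven by the cell's
own voltage through `alpha_inh(V) = alpha0 / (1 + exp(-V/5))`.
Defaults (`NeuronParams`): C = 1 µF/cm², I_app = 0.4 µA/cm²,
g_Na = 35, g_K = 9, g_L = 0.1, g_syn = 0.05 mS/cm², V_Na = 55,
V_K = −90, V_L = −65, V_syn = −75 mV, gating rate scale γ = 1,
α₀ = 4 ms⁻¹, τ_inh = 2 ms.  At these values the isolated cell fires
tonically with period T ≈ 50.06 ms (≈ 20 Hz).  The rate functions
`alpha_m` and `alpha_n` have removable singularities (V = −35 and
−34 mV) evaluated by a short series whenever the exponent magnitude is
below 1e−4.

The limit cycle is located by integrating (DOP853, rtol 1e−8,
atol 1e−10) past a 1.5 s transient and detecting upward crossings of
V = 0 mV with event refinement; successive inter-spike intervals must
agree to the stated tolerance.  Phase 0 is the section crossing; the
orbit is resampled at 1024 uniform phases (periodic cubic interpolation
between samples).  The phase origin is a free convention: the
interaction function depends only on phase differences.

The adjoint (infinitesimal phase response) solves
dZ/dt = −DF(X̂(t))ᵀZ with the analytic 4×4 Jacobian.  Backward
integration contracts the non-periodic Floquet directions (the orbit's
nontrivial multipliers are ≈ 1.2e−3, 4e−12, 1e−14 per period, so
backward decay is fast).  Two implementation details matter:

* during backward integration the orbit is evaluated from the dense
  time interpolant of the detection integration rather than the
  1024-point phase spline — the spike upstroke is steep enough that
  spline error otherwise acts as a periodic forcing of the adjoint;
* that forcing has a component along the neutral direction which makes
  the raw period map drift in scale; the iteration therefore rescales
  Z each period and tracks convergence of the direction only.  The
  final normalization (1/T)∫ Z·F dt = 1 fixes the scale exactly.

## Interaction function

For weak coupling the network reduces to one phase per cell,

    dθᵢⱼ/dt = Ω + ε Σ w_pq H(θ_{i+p,j+q} − θᵢⱼ),

with H(ψ) the period average of Z against the synaptic coupling field
at offset ψ (presynaptic phase minus postsynaptic phase).  Scale
convention: ε = g_syn, weights are dimensionless multipliers, and the
1/C factor is folded into the coupling field, so H itself is
independent of g_syn.  On the shared uniform grid the integral is the
periodic trapezoid rule, i.e. an exact circular cross-correlation
(computed via FFT).  Derivatives use central finite differences with
periodic wrap (O(Δψ²); at 1024 points far below every tolerance used);
the odd part is a grid-exact index reversal.

Computed landmarks for the default cell (anchors of everything
downstream): H'_odd(0) ≈ −0.111, H'_odd(π/3) ≈ −1.137,
H'_odd(π/2) ≈ −0.177, H'_odd(2π/3) ≈ +0.779, H'_odd(π) ≈ +1.660;
H'_odd changes sign at ψ ≈ 1.661 and ≈ 4.622 rad.  The negative slope
at 0 — synchrony-destabilizing, unlike a Kuramoto sine — comes from
the synaptic delay built into the gating kinetics.

## Cluster states and closed-form stability

On an m×n torus (columns i mod n, rows j mod m) the admissible
constant-step states have ψ_h = 2πℓ_h/p_h with p_h | n,
gcd(ℓ_h, p_h) = 1 (and likewise vertically), giving exactly n·m
distinct (ψ_h, ψ_v) pairs and p = lcm(p_h, p_v) equal clusters.  The
coupling stencil S holds the 4 nearest (h1, v1), 4 diagonal (d), and 4
second-nearest (h2, v2) offsets.

Linearization about a cluster state gives du/dt = ε(−cI + Ŵ)u with
Ŵ block circulant; the eigenvalue real parts are

    Re λⱼₖ = − Σ_{(p,q)∈S} w_pq H'(p ψ_h + q ψ_v)
                 · (1 − cos 2π(jp/n + kq/m)).

For direction-symmetric weights the paired offsets combine through
H'(x) + H'(−x) = 2 H'_odd(x).  The implementation evaluates the
general (asymmetric-capable) form; a dense N×N Jacobian assembled
entry-by-entry serves as an independent oracle (multiset equality of
spectra at 1e−8 over hundreds of randomized lattices, weights, and
tabulated H').  The (0,0) mode is always zero (global phase shift);
a state is stable when all other modes are below −tol, with
tol = 1e−9·max(1, |c|), and "marginal" when any mode sits inside the
band.  ε > 0 only scales the spectrum and is set to 1.

Two caveats encoded in the code and tests: coinciding stencil offsets
on narrow lattices (e.g. ±2 steps on a 4-wide torus) are summed, as
the mod arithmetic implies; and the trace identity Σ Re λ = −mnc holds
only when no offset wraps to the identity (m, n ≥ 3).

Thresholds: the (π, π) diagonal stripe loses stability when
d/min(h1, v1) exceeds −H'_odd(π)/(2 H'_odd(0)) ≈ 7.49 for the default
cell; root-finding the leading mode over d on the full grid reproduces
the formula to machine precision because the critical modes are the
purely horizontal/vertical ones.  A p-cluster horizontal stripe needs
2 d H'_odd(ψ_v) + h1 H'_odd(0) > 0 (necessary only).

## Network simulations

The full network integrates all 4N state variables (RK45, rtol 1e−6,
atol 1e−8) with I_syn,i = g_syn (Vᵢ − V_syn) Σⱼ Wᵢⱼ sⱼ; W holds the
dimensionless stencil weights.  Spikes are upward V = 0 crossings,
linearly interpolated on a 0.25 ms sampling grid (jitter ≲ 0.1 ms,
well under the 2 ms pattern-matching tolerance).  Initial conditions
place each cell on the limit cycle at its pattern phase.  Spike-time
phases are read out relative to cell 0 over the last five network
periods (a cell ahead in phase fires earlier); two phase fields match
when a global shift aligns all sites within 2π·2 ms/T.

Empirical stability uses a perturb-and-relax protocol: a seeded random
half of the cells receives an extra applied current ΔI for 100 ms,
the network then settles for 2.4 s, and the readout must match the
initial pattern.  A cell that falls silent counts as a lost pattern.
The probe default is ΔI = 0.002 µA/cm²: small enough not to act as a
state switch, while the induced phase deviation (a few 10⁻³ rad) still
dominates the integrator's phase-noise floor (~10⁻⁴ rad).

### What the perturbation experiments do and do not show

At the default conductances the coupling is *not* weak: with h1 = v1
= 1 the synaptic drive already shifts the network period by tens of
percent once diagonal weights grow (ISI 50 → 68 ms at d = 9).  Two
consequences, measured and reproducible:

* Coexisting attractors are everywhere.  Probes of ΔI ≥ 0.003 act as
  state switches long before any linear instability: the 6×6 (π, π)
  stripe escapes into a half-suppressed state (one cluster silenced)
  at d ≈ 2.5 under a ΔI = 0.005 probe, and the 4×4 stripes hop into
  the alternating 4-cluster state, whose basin is large.
* The measured destabilization threshold of the (π, π) stripe is
  therefore probe-dependent with no plateau: ≈ 2.5 (ΔI = 0.005),
  ≈ 5.5 (0.003), ≈ 9.6 (0.002), ≈ 13 (0.001, where the deviation
  demonstrably decays at d = 9 even over 6 s).  The weak-coupling
  formula gives 7.49.  The package reports the bisection result under
  its fixed default probe (≈ 9.6) and makes the amplitude a parameter;
  no single number deserves to be called *the* biophysical threshold
  in this regime.

By contrast the *structural* predictions of the phase model are robust
across all probe sizes tested: which patterns are stable (Tables of
verdicts, the 9 → 15 count on 6×6, the four stable 4×4 patterns
including the alternating template), the persistence of every
predicted-stable state, and the p-fold multiplication of the
population event rate.

Limitations: no noise, no heterogeneous intrinsic parameters, no
conduction delays, no gap junctions; stability of the alternating-phase
4-cluster state and of non-uniform 2-cluster states is probed only
empirically (no closed form is implemented for non-constant-step
patterns); asymmetric weights (w_pq ≠ w_{−p,−q}) are accepted by the
general eigenvalue form but untested against published values.

## Problem sizes

Default experiments use the lattices the analysis targets: 4×4 and 6×6
tori (16/36 cells, 64/144 ODEs), 1024-point phase grids, 3 s
simulated time per perturbation run, and bisection to 0.1 in d.  The
randomized oracle suite covers all lattice sizes 2–8 per direction.
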