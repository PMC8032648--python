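# Methods

This note documents the model, the numerical scheme, the synthetic data
(beat pattern), the parameters that matter, and the known limitations of
`lagstokes`.

## Physical model

Flow at the micrometer scale is inertialess: `0 = −∇p + μ∇²u`, `∇·u = 0`,
with no-slip boundary condition `u(x) = v(x)` on every immersed surface.
Linearity gives a superposition principle for boundary velocities and
tractions, which is the backbone of everything here.

A shape-changing surface constrained to generalized coordinates
`q = (q_1, …, q_n)` has surface velocity `v = Σ w_i q̇_i` with
`w_i = ∂x/∂q_i`. The resistance problem maps each `w_i` to a normalized
traction `g_i`; the generalized friction matrix
`Γ_ij(q) = ∫_S w_i · g_j d²x` then gives the friction forces conjugate to
each coordinate, `P_i = Σ_j Γ_ij q̇_j`, and the dissipation rate
`R = q̇·Γ·q̇ ≥ 0`. `Γ` is symmetric by the Lorentz reciprocal theorem and
positive definite except where the `w_i` become linearly dependent.
Dynamics follows from the instantaneous balance `Q_i = P_i` between active
driving forces and friction, `q̇ = Γ⁻¹Q` — Newton's second law without
inertia. Driving forces are assumed load-independent and local,
`Q_i = Q_i(q_i)`; an interface hook for load-dependent driving (an implicit
self-consistency solve) is reserved but not implemented.

Assumptions: Newtonian fluid, zero Reynolds number, no thermal or active
noise (the solver is deterministic precisely so that noise, when added
later, can be *physical* noise), shape dynamics restricted to the chosen
coordinates.

## Hydrodynamic backend

Surfaces are point clouds ("blob elements") with areas `A_k` and element
radii; slender cilia are chains of blobs. The kernel is the regularized
Stokeslet of the standard smooth blob `ψ_ε(r) = 15ε⁴ / (8π(r²+ε²)^{7/2})`:

    8πμ G_ij = δ_ij (r² + 2ε²)/(r²+ε²)^{3/2} + r_i r_j/(r²+ε²)^{3/2}

with `ε` equal to the per-element radius by default. In the half space
above a no-slip wall the image system (image Stokeslet, Stokeslet doublet,
source doublet) is used; the correction terms are regularized with the same
`r → √(r²+ε²)` substitution. With `ε = 0` the wall velocity vanishes
identically (verified in tests to 1e-15 relative); with `ε > 0` the
on-wall residual is O(ε²/h²) of the near-source flow, negligible for
blobs at heights `h ≫ ε` (cilium blobs sit at h ≥ 0.25 µm with
ε = 0.1 µm).

The resistance solve collocates `u(x_k) = v_k`: a dense `3N×3N` system,
LU-factorized once per configuration with a reciprocal-condition-number
check (refusal below 1e-13), then reused for all `n` right-hand sides of a
friction-matrix assembly. Because the collocation matrix is itself
symmetric, the assembled `Γ` is symmetric to machine precision;
asymmetry beyond 1e-4 relative raises an error instead of being silently
averaged, and the symmetric part is used afterwards. Dense direct
factorization is the deliberate choice at these problem sizes (N ≤ a few
hundred); iterative and fast-multipole solvers are out of scope.

Discretization accuracy (drag of a translating sphere vs `6πμav`): 3.2%,
2.1%, 1.5%, 1.0% at N = 125, 250, 500, 1000 elements with blob radius
0.5× the mean point spacing — the default for closed surfaces.

## Velocity bases and friction tables

`∂x/∂q_i` uses central differences with step `1e-6 ×` the coordinate scale
(O(ε²); forward differencing is available for one-sided models); built-in
models supply analytic derivatives. Shape models must keep the element
enumeration and areas fixed under perturbation — violating this raises a
contract error rather than producing garbage derivatives.

`Γ(q)` is tabulated on per-coordinate grids: `m` uniform points on
`[0, 2π)` per periodic coordinate, `n·mⁿ` resistance solves total (counted
and recorded in the table provenance, with a budget refusal above 50k
solves). Interpolation is truncated-Fourier (trigonometric) for periodic
coordinates — exact at the nodes and for band-limited data, spectrally
accurate for smooth `Γ` — with cubic-spline and global-polynomial
alternatives for 1-D non-periodic grids. Interpolated matrices are
symmetrized (the symmetric part is what is interpolated) and stay positive
definite in practice; tables serialize to HDF5 (JSON fallback) with a
payload hash checked on load. Default `m = 24` for production single-cilium
tables, `m = 16` for pair tables.

## Dynamics

`q̇ = Γ⁻¹Q` is integrated with adaptive explicit Runge–Kutta
(`scipy.solve_ivp`, RK45), defaults rtol 1e-8 / atol 1e-10, dense output
for event detection (phase crossings). Lyapunov and steady-state runs use
tighter tolerances (1e-11/1e-13 and 1e-10/1e-12) because they resolve
phase-difference changes of order 1e-7. Coordinates may be free,
prescribed (`q_i(t)` given; its force-balance row moves to the right-hand
side), constrained (`q̇_i = 0`, reporting the constraining force `P_i`), or
free with an added external force. A clamped body in uniform external flow
is the prescribed case `q̇_i = −u₀·e_i` in the co-moving frame.

Calibration: for an isolated unit with one periodic coordinate,
`Q(φ) = ω₀ Γ₁₁(φ)` is the unique driving force giving constant phase
speed `ω₀`. Because the same interpolant enters calibration and dynamics,
the recovered period is exact up to integrator tolerance (measured
relative error < 1e-9 at ω₀/2π = 32 Hz).

## Rigid bodies and swimmers

Six rigid coordinates (translations along, rotations about the material
triad `e_1, e_2, e_3`) have analytic bases; their friction matrix is the
classical 6×6 resistance matrix (sphere check: translation block `6πμa·I`,
rotation block `8πμa³·I`, each within 5% at N = 600; chirality coupling
< 1%). A force- and torque-free swimmer satisfies a 6×6 linear system for
its rigid velocity given the traction of the pure shape change; the
returned total traction integrates to zero force and torque to 1e-8
relative. Frames advance by exact rotation exponentials
(`scipy.spatial.transform.Rotation`) with a polar re-orthonormalization
guard — orthonormality drifts < 1e-9 over 1e4 random steps; trajectories
integrate the quaternion directly to avoid chart singularities.

The built-in three-sphere swimmer (spheres of radius 1 µm, mean arm
10 µm, stroke 4 µm, four-stroke square cycle) displaces ≈ 0.17 µm per
cycle; the displacement reverses with cycle orientation and is independent
of traversal speed to < 1e-3 (a geometric phase), and a reciprocal
single-arm stroke yields drift < 1e-6 of the stroke amplitude (scallop
theorem) — these are the strongest end-to-end correctness checks in the
suite.

## Synthetic beat pattern (what it emulates, and what not)

The experimentally digitized ciliate waveform the pair study would ideally
use is not redistributable, so the package ships a synthetic,
parameterized 3-D beat of a wall-anchored 10 µm filament, emulating a
Paramecium-like stroke. The centerline tangent angle from the wall normal
in the beat plane is a tilted traveling wave

    α(s, φ) = tilt + sweep·(0.6 + 0.4 s/L)·cos(φ − lag·s/L)
                   + curl·(s/L)·cos(2(φ − lag·s/L))

with an out-of-plane tilt `β = asym·(s/L)·sin(φ − lag·s/L)`. Defaults
(radians): tilt 0.85, sweep 0.55, curl 0.10, lag 2.0, asym 0.4. The mean
tilt leans the beat envelope toward the effective-stroke axis (+y) as in
ciliates; the growing, lagged first harmonic produces an extended filament
sweeping through the +y half-space (tip height up to 0.87 L) and a
recovery stroke returning bent close to the wall (tip down to 0.31 L);
`asym` adds the lateral recovery excursion that makes the beat chiral and
fully 3-D (`asym = 0` gives a planar beat, used in tests). Since
`|α| < π/2` for the default angles, the centerline structurally cannot
penetrate the wall; a validation scan rejects parameter sets that do.

What the synthetic pattern does **not** reproduce: the measured waveform's
exact curvature profile, so the *specific map* of separation directions
with stable vs unstable in-phase synchronization is pattern-dependent and
should be read qualitatively. Pattern-robust results are: the existence of
both stable (δ* = 0) and unstable (δ* ≈ π) directions, the point-reflection
symmetry λ(ψ) = λ(ψ+π), the in-phase manifold invariance, the ~1/d³
far-field decay of coupling and synchronization strength, and calibration
recovery. Absolute Γ magnitudes also depend on the (unpublished) mesh and
regularization of any reference computation and are not comparable between
solvers; φ-dependence shapes and scalings are.

## Cilia-pair study: defaults and problem sizes

Cilium: 20 blob segments of radius 0.1 µm (tests use 12 where the physics
is resolution-independent); μ = 1e-3 Pa·s; ω₀/2π = 32 Hz. Pair tables on a
16×16 phase torus (24 for single-cilium production tables); self-friction
of the pair is replaced by the isolated-cilium `Γ₁₁(φ)` — the measured
replacement error is 0.02% at d = 18 µm ("virtually independent" of the
partner phase, as assumed). The coupled 2×2 force balance is solved in
closed form at each step; the in-phase state's stability is quantified by
the one-cycle Lyapunov exponent `λ = log|δ₁/δ₀|` from initial phases
`∓δ₀/2` (δ₀ = 1e-3 rad, linear to 1e-4 relative) integrated until the mean
phase completes `2π` (event detection). Steady states `δ*` are sampled
stroboscopically at mean-phase multiples of 2π from a fan of 8 initial
phase differences, with convergence at 1e-4 rad cycle-to-cycle and
attractor clustering at 0.05 rad; probes that never move are flagged
neutral/non-converged.

Distance scans use 5 log-spaced separations from 18 to 60 µm at fixed
direction ψ = π/3 (18 µm is the canonical reference separation of the
study this emulates) and fit least-squares log–log slopes of the torus L2
norm `‖Γ₁₂‖₂(d)` and of `|λ|(d)`; distances below 1.5 L are excluded as
near-field with a warning.

## Known limitations

- **Far-field crossover.** The wall-parallel point-force flow decays as
  `1/d³` only at constant height and for `d` much larger than the source
  heights. A 10 µm cilium has interaction-weighted heights of 4–6 µm, so
  over d = 18–60 µm the *local* decay exponent is still rising toward its
  asymptote: the package measures exponents ≈ 2.61 for `‖Γ₁₂‖₂` and
  ≈ 2.49 for `|λ|` in this window, against the asymptotic 3 (the
  kernel-level control at constant height over a 10×–100× height window
  gives 2.978). This is crossover physics, not discretization error — the
  same shortfall appears in the bare Blake tensor at these heights — and
  it closes slowly as the window moves outward.
- Zero Reynolds number only; long-range interactions degrade first at
  finite Re. Newtonian fluids only (superposition is essential).
- No noise, no elastic/amplitude degrees of freedom of the beat, no
  load-dependent driving, two cilia only (no carpets), dense solves only.
- The blob discretization trades boundary-integral rigor for robustness;
  absolute friction coefficients carry a few-percent discretization bias
  (see the drag table above) that cancels in ratios, scalings and
  calibrated dynamics.
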