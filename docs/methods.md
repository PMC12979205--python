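# Methods

## The continuum model

The package models the density ρᵢ(x, t) of growing microtubule plus ends
of aster *i* on a 1D axis through the aster centres:

    ∂ρᵢ/∂t = ∓v_p ∂ρᵢ/∂x
             + α ρᵢ / (1 + ρ_tot/ρ_s)
             − θ ρᵢ
             − λ ρᵢ ρ_opp / (ρᵢ + ρ_opp)

Advection (speed v_p, outward from each aster's own centre) transports
plus ends; autocatalytic nucleation (rate α) amplifies the local density,
saturating when the total density ρ_tot approaches ρ_s (nucleator
depletion); whole-filament turnover (rate θ) removes plus ends; and the
last term is a phenomenological mutual inhibition acting where asters
overlap (ρ_opp is the summed density of the other asters; the term is
defined as 0 where ρ_tot = 0, its removable singularity). For two asters
the inhibition reduces to λ ρ₁ρ₂/(ρ₁+ρ₂).

Units are fixed: µm, min, plus-ends/µm. The equation is invariant under a
joint rescaling of (ρ, ρ_s, ρ_c), so the absolute density scale is
conventional and is carried by the centre amplitude.

**Boundary conditions.** Each aster is anchored by pinning the density of
its own centre cell to ρ_c, a stand-in for centrosomal nucleation, which
the transport term otherwise drains (without a source at the centre every
profile washes out in one transit time). The far ends are free outflow; a
reflecting, unanchored variant exists for conservation checks.

**Parameters that matter** (defaults for the frozen "study truths"):

| parameter | meaning | extract-like | bead-like |
|---|---|---|---|
| v_p | polymerization velocity | 10 µm/min | 10 µm/min |
| θ | turnover rate | 0.2 /min (5 min lifetime) | 0.2 /min |
| α | autocatalytic rate | 0.554 /min | 0.147 /min |
| λ | inhibition strength | 1.0 /min | 1.0 /min |
| ρ_s | saturation density | 1 (density unit) | 1 |
| ρ_c | centre amplitude | 0.5 | 0.5 |

The two α values were calibrated once so that the effective ratio α′/θ is
≈ 1.30 (unstable) and ≈ 0.60 (stable) on the default 200 µm two-aster
geometry, deliberately straddling the stability boundary; they are then
frozen as the package's reference conditions.

## Numerics

First-order upwind finite-volume advection in flux form with explicit
Euler reaction, CFL v_p·Δt/Δx ≤ 1 (default Δt = 0.5 Δx/v_p). The scheme
is monotone and positivity-preserving (negative round-off is clipped at
0), and conserves the finite-volume mass Δx·Σρ exactly in the pure
advection limit with reflecting walls. The inner loop is numba-compiled.
Steady states are found by time-marching until the relative change per
minute of model time falls below 10⁻⁸ (10⁻⁷ inside fit iterations), with
a convergence error carrying the residual otherwise. Symmetric steady
pairs are computed with the mirror constraint ρ₂(x) = ρ₁(L−x) enforced
each step; this also removes the antisymmetric unstable mode, so the
symmetric branch is reachable on both sides of the stability boundary.

Known discretization effects, stated because they set test tolerances:
explicit Euler contributes ~n(θΔt)²/2 relative error to pure exponential
decay (the 0.1%-accuracy decay check uses Δt = 0.002 min), and the upwind
scheme biases exponential-profile slopes by O(Δx) (the closed-form slope
check converges under grid refinement; 2% at 256 cells over 200 µm).

## Stability: criterion and classification

Linearizing the symmetric two-aster steady state gives the boundary
stability criterion θ > α′ = α/(1 + 2ρ_int/ρ_s): at the interface
crossing the inhibition term is identical for both asters and cancels in
the difference mode, whose local growth rate is α′ − θ. ρ_int is
operationalized as the density value at the crossing point of the
symmetric steady solution.

The numerical classifier perturbs the symmetric steady state to a small
(default 1%) mass asymmetry and watches |M₁ − M₂|: growth by a factor e
within the window ⇒ unstable; decay by e ⇒ stable; neither ⇒ "marginal"
(critical slowing down makes finite-time classification ill-posed near
the boundary, so a ±5% band around α′ = θ is excluded from criterion
checks).

Two empirical properties of the anchored finite-domain system matter for
study design:

1. **Threshold renormalization.** When the inter-aster interface is
   weakly developed (short domain, weak λ — e.g. 200 µm with λ = θ), the
   centre anchors stabilize the interface and the numerical instability
   threshold sits above α′ = θ (at α′/θ ≈ 1.17 in that geometry). With a
   well-formed interface (≥ 400 µm domains, or λ ≳ 5θ) the numerical
   threshold converges to α′ = θ within 1–2%, and the criterion is
   λ-independent as the linear analysis asserts. The classification grid
   study therefore runs at L = 400 µm, λ = 5θ.
2. **Achievable α′ cap.** Because ρ_int grows with the plateau density
   ρ_s(α/θ − 1), α′/θ saturates as α grows; the cap shrinks as the growth
   length v_p/θ becomes small against the domain. The grid study uses
   θ ∈ {0.06…0.14}/min and ratios {0.6, 0.8, 0.9, 1.1, 1.18}, all
   achievable and all outside the marginal band; `calibrate_alpha`
   inverts α ↦ α′/θ by bisection and reports an unreachable target
   explicitly.

## Invasion time

τ is defined as the time for the invaded (smaller) aster's mass to
decrease by a factor e from its initial value, extracted with linear
interpolation. The alternative literal reading — e-folding of the mass
*difference* — conflicts with the fact that |M₁−M₂| grows during an
invasion; it is available as `convention="difference"`, implemented as
the e-folding of |ΔM − ΔM∞| (the difference's distance from its limit).
`predict_invasion_time` is parameter-free: it perturbs the symmetric
steady interface to the requested fractional mass difference and solves
the dynamics. τ(ΔM) decreases with ΔM and diverges logarithmically as
ΔM → 0 (equal factors in ΔM add equal time increments ln f / g, with g
the linear growth rate), and all phases stretch as 1/g near the boundary.
In the stable regime the same machinery reports "no invasion" together
with the decay timescale of the asymmetry.

## Cell-cycle coupling

`run_cycling` punctuates the multi-aster dynamics with mitotic resets
every T_cc minutes: densities are multiplied by `reset_fraction`
(default 0.05 — asters disassemble almost completely at mitosis) and each
surviving aster is re-anchored at the centroid of its own density
(default on — dynein recentres the nucleus). An aster whose mass has
fallen below 10% of the mean is removed (its compartment is fused into
the invader's); 10% rather than a smaller cut because an anchored,
defeated aster retains ~6% of the mean mass — its centrosome keeps
nucleating — and never reaches zero. Per-aster anchor amplitudes carry 5%
lognormal-like jitter, mimicking variable nucleation sources.

The rescue mechanism this exposes: after a near-complete reset the
outgoing growth fronts re-collide midway between anchors, re-forming the
interfaces, so cycles shorter than the invasion time erase accumulated
asymmetry; long cycles let invasions complete, producing coarsening and a
broadening size distribution. The sweep study uses 12 asters spaced
200 µm (total time 320 min held fixed across T_cc ∈ {10, 20, 40, 80});
with fewer asters long cycles coarsen to two near-equal winners and the
final-size variance saturates instead of growing monotonically.

## Agent-based simulation

Filaments are straight segments in a (300–400) × (120–300) × 10 µm slab:
plus-end elongation at v_p (clamped at walls), whole-filament death at
rate θ (matching the continuum turnover term and the speckle-lifetime
observable, rather than explicit catastrophe/rescue), centrosomal
nucleation Poisson(k_nuc·dt) with in-plane isotropic directions, and
branching Poisson(k_branch·dt·polymer·free_fraction) on length-weighted
parents with branch angles Normal(0, 10°) about the parent (shallow-angle
branching, per the branching-nucleation literature). Each alive filament
sequesters one nucleator from a per-aster pool; `free_fraction` throttles
branching as the pool empties — the microscopic analogue of ρ_s.
Antiparallel inhibition marks a filament whose plus end lies within
`d_inh` of an opposing filament body (sampled at `d_inh` spacing, KD-tree
query) with negative direction dot product; marked filaments turn over
`f_inh`-fold faster and can optionally arrest. All randomness flows from
one seeded generator, so runs are bit-reproducible.

**Continuum correspondence.** With exponential whole-filament lifetimes,
the stationary polymer density is (v_p/θ) × the plus-end density at every
radius, so branching per unit polymer maps onto a local plus-end
autocatalysis with α = k_branch·v_p/θ. The consistency study bins
plus-end counts per unit radial distance (pooled over post-burn-in
snapshots) and compares against the 1D continuum single-aster steady
profile, amplitude-matched by total mass; at α = 0.5/min, θ = 1/min the
RMSE is ~2% of the peak. The birth–death closed forms (count k_nuc/θ,
mean length v_p/θ) are checked with autocorrelation-corrected effective
sample sizes.

## Synthetic data

`gen_profile_tracks` samples the exact stationary plus-end process implied
by the continuum steady state: births with intensity equal to the local
autocatalytic term (plus a centre atom equal to the anchored flux
v_p·ρ(0)), outward transport at v_p with per-step velocity jitter
(0.5 µm/min), and position-dependent death hazard θ + λρ_opp/ρ_tot
(path-integrated for the pre-window leg). The generator's ground truth is
the integrating-factor solution of its own transport–birth–death ODE —
self-consistent to machine precision, unlike the O(Δx)-biased grid
profile. Acquisition mirrors sparse EB1 imaging: 3 s frames, 30 nm
localization noise, a 20 µm strip, ~200 µm axis. What it does **not**
emulate: detection failures, fluorophore blinking/bleaching, drift, or
curved trajectories — so passing closure tests validate the estimators
under the model's own assumptions, not robustness to imaging pathology.

Closure notes. Consecutive detections of one track are strongly
correlated, so profile-closure χ² must use cluster-robust (per-track)
variances; with per-bin Poisson errors χ²/dof ≈ 3.5 even at zero noise.
Greedy nearest-neighbour linking is density-dependent: ≥ 95% link
accuracy holds at the reference density of ~100 comets/frame
(≈ 0.025/µm²); at 3× that density accuracy drops to ~94%.

Other generators: exponential right-censored lifetimes; noisy exponential
FRAP recovery; invasion movies (perturbed steady pair + multiplicative
profile noise, masses by trapezoidal integration); and 2D multi-aster
fields built from Gaussian kernels whose amplitudes follow a competitive
Lotka–Volterra law derived from the truth's margin (winner-take-all
exclusion for unstable truths, coexistence for stable ones; kernel width
0.4× the minimum spacing so a density saddle separates every pair —
watershed segmentation then recovers nearest-centre areas within a few
percent).

## Global profile fit

`ProfileFitModel` fits the mirror-symmetric steady pair solution to
replicate density profiles by weighted nonlinear least squares
(weights 1/sem, floored at half the median sem to keep empty bins
finite). v_p and θ are measured independently and held fixed; (α, λ, ρ_s)
are shared across replicates and each replicate gets its own centre
amplitude ρ_c (nucleation sources vary biologically; a pure intensity
rescale is *not* equivalent to a ρ_c change because the model is
nonlinear). Parameters are optimized in log space (positivity by
construction) with ≥ 8 multi-starts: α log-spaced over [0.7, 8]×θ, ρ_s
seeded from the plateau relation ρ* = ρ_s(α/θ − 1) at the data's peak
density so every start lies near the (α, ρ_s) trade-off ridge — the
landscape has a shallow secondary basin along that ridge which random
starts frequently hit. The finite-difference step (10⁻³ relative) is
deliberately far above the steady-solver tolerance; smaller steps drown
the Jacobian in solver noise. Covariances come from the Gauss–Newton
Jacobian at the optimum, delta-method-transformed to the natural scale.

Identifiability: on unstable truths the saturation plateau pins ρ_s and
all three shared parameters are recovered within a few percent at 5%
noise; on stable truths the profile never approaches ρ_s, which is then
weakly identified (~14% error at 5% noise) while α, λ and the stability
side remain accurate.

Phase placement maps a fit to (θ, α′) via the fitted steady interface
density (geometric-mean ρ_c across replicates). `bootstrap_phase`
resamples whole replicates (bins are spatially correlated; the replicate
is the exchangeable unit), refits warm-started at the full-data optimum,
and reports the 95% confidence ellipse (χ²₂ contour) of the bootstrap
covariance; with θ held fixed the ellipse is degenerate along θ.

`predict_param_shift` propagates a polymerization-velocity perturbation
through the mean filament length ℓ = v_p/θ: α ∝ ℓ (branching per unit
polymer) and ρ_s ∝ 1/ℓ (a fixed nucleator pool saturates at lower
plus-end density when filaments are longer), θ and λ unchanged. A −20%
velocity shift then moves a near-marginal unstable system (α′/θ ≈ 1.05)
across the boundary to stable. The scaling rule is an explicit modelling
choice recorded in the returned metadata; a velocity-only variant is
selectable.

## Problem sizes

Default study sizes (chosen as desk-scale reference conditions): 128–256
cells over 200–600 µm domains; 25-point classification grid; 500–800
synthetic tracks; 1000 lifetimes; 8 replicate profiles with 50 noise
realizations for placement; 200 bootstrap draws; 12 asters × 10 seeds ×
4 cycle periods for the cycling sweep. The full test suite runs in a few
minutes on one CPU.

## Known limitations

* 1D continuum only; dimensionality is covered qualitatively by the agent
  simulator, not by a 2D/3D PDE solver.
* The cell-centred Dirichlet anchor is a modelling convention; a
  distributed source term would shift near-centre profiles at O(Δx).
* The agent simulator omits explicit dynamic instability, motor
  mechanics, filament bending and dynein transport.
* Track linking is greedy nearest-neighbour without gap closing;
  photobleaching correction of lifetimes is out of scope.
* The 2D field generator is phenomenological (kernel superposition), built
  for segmentation/area analyses rather than microscopic realism.
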