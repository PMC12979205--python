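# asterwave

Dynamics and inference of interacting microtubule asters — the cytoskeletal
machinery that partitions the cytoplasm of early embryos into compartments
before (and without) cell membranes.

Early vertebrate and insect embryos organize their cytoplasm around large
microtubule asters that grow by *autocatalytic (branching) nucleation*: new
microtubules nucleate from existing ones, so aster growth is self-amplifying.
Where two asters meet, antiparallel overlap locally inhibits growth and a
boundary forms. Self-amplification plus mutual inhibition is the classic
recipe for a winner-take-all instability: one aster can invade and consume
its neighbour, fusing their compartments. `asterwave` implements the theory
and the measurement pipeline for this problem, exercised entirely on
synthetic data:

* a **continuum model** of N interacting asters in 1D,

  ∂ρᵢ/∂t = ∓v_p ∂ρᵢ/∂x + α ρᵢ/(1 + ρ_tot/ρ_s) − θ ρᵢ − λ ρᵢρ_opp/(ρᵢ+ρ_opp)

  where ρᵢ is the density of growing plus ends of aster *i*, v_p the
  polymerization velocity (µm/min), α the autocatalytic nucleation rate,
  θ the whole-filament turnover rate, λ the inter-aster inhibition strength
  and ρ_s the saturation density set by nucleator depletion;
* the **stability criterion** for the boundary between two asters: stable iff
  θ > α′ ≡ α/(1 + 2ρ_int/ρ_s), with ρ_int the plus-end density where the
  asters intersect — a competition between turnover and effective
  autocatalysis that does not involve the inhibition strength;
* an **agent-based simulator** of two branching asters in a quasi-2D slab
  (explicit filaments, centrosomal + branching nucleation, a finite
  nucleator pool, antiparallel-proximity inhibition), used to validate the
  continuum picture microscopically;
* the **inference pipeline** that places a real system on the (θ, α′−θ)
  phase diagram: plus-end comet linking and v_p estimation,
  censored-exponential turnover MLE from single-molecule lifetimes, FRAP
  recovery fits, density/polarity profile reconstruction, a global
  nonlinear fit of the model to replicate profiles (statsmodels-style
  `ProfileFitModel.fit() → ProfileFitResults` with `summary()`,
  covariances and bootstrap confidence ellipses);
* **compartment analyses**: aster masses, invasion times τ(ΔM), 1D/2D
  segmentation, phase portraits A(t) vs A(t+τ), size distributions,
  cytoplasmic filling fraction, and cell-cycle-coupled simulations showing
  how mitotic resets rescue the instability when the cycle is shorter than
  the invasion time;
* a **synthetic-data module** that generates every input above from known
  ground truth, with the statistical structure the estimators assume.

## Worked example

Measure v_p and θ from synthetic tracking/lifetime data, globally fit the
profile shape, and place the system on the phase diagram:

```python
import asterwave as aw
from asterwave import studies, synth

truth = synth.extract_like()                     # unstable ground truth
tracks = synth.gen_profile_tracks(synth.SynthConfig(n_tracks=500), seed=1)
vp = aw.estimate_vp(tracks.tracks)
life = synth.gen_lifetimes(truth.theta, 1000, t_obs=30.0, seed=1)
th = aw.estimate_theta_lifetimes(life)
profs = studies.make_replicate_profiles(truth, 8, 0.05, seed=1)
res = aw.ProfileFitModel(profs, v_p=vp.v_p, theta=th.theta).fit(seed=0)
print(res.summary())
print(aw.predict_invasion_time(truth, dM_frac=0.1).tau)
```

prints

```
v_p = 10.01 +/- 0.01 um/min  (504 tracks)
theta = 0.198 1/min  (95% CI 0.186-0.211)
Global profile fit (two-aster continuum steady state)
========================================================
replicates: 8   observations: 1536   cost: 407.9
fixed: v_p = 10.0114 um/min   theta = 0.198282 1/min
--------------------------------------------------------
param           estimate     std err
alpha            0.55891      0.0157
lam               1.0033     0.00646
rho_s            0.96856      0.0574
...
alpha' = 0.2568 1/min   margin alpha'-theta = +0.05854 1/min   (unstable)
```

The generating parameters were α = 0.554, λ = 1.0, ρ_s = 1.0: the global
fit recovers them within its standard errors, and the fitted margin
α′ − θ ≈ +0.06 /min correctly classifies the system as unstable — its
compartment boundaries will coarsen unless the cell cycle resets the
asters faster than the ~30–75 min invasion times
(`aw.predict_invasion_time`) at realistic mass asymmetries.

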