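"""Reusable study protocols: phase-diagram sweeps, recovery and
consistency studies run on synthetic ground truth.

These functions compose the solver, the generators and the inference
pipeline into the standard "experiments" of the package — the numerical
confirmation of the stability criterion, the divergence of the
instability-development time near the boundary, the invasion-time law,
parameter-recovery and phase-placement studies, the agent-continuum
consistency check and the cell-cycle rescue sweep.  They are used by the
test suite and the reproduction script alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import synth
from .compartments import measure_invasion_time
from .continuum import (
    asymmetry_efold_time,
    calibrate_alpha,
    classify_stability_numerical,
    predict_invasion_time,
    run_cycling,
    single_aster_profile,
    stability_margin,
)
from .exceptions import NoInvasionError
from .fitting import ProfileFitModel
from .params import CycleConfig, Grid1D, ModelParams
from .profiles import DensityProfile

__all__ = [
    "stability_grid_study",
    "development_time_scan",
    "invasion_time_study",
    "make_replicate_profiles",
    "recovery_study",
    "phase_placement_study",
    "agent_continuum_study",
    "cycling_sweep_study",
]


# ---------------------------------------------------------------------------
# stability criterion (numerical vs analytic)
# ---------------------------------------------------------------------------

@dataclass
class GridPoint:
    theta: float
    target_ratio: float
    alpha: float
    margin: float
    analytic: str
    numerical: str


def stability_grid_study(thetas=(0.06, 0.08, 0.1, 0.12, 0.14),
                         ratios=(0.6, 0.8, 0.9, 1.1, 1.18),
                         v_p: float = 10.0, rho_s: float = 1.0,
                         rho_c: float = 0.5, lam_over_theta: float = 5.0,
                         L: float = 400.0, nx: int = 192,
                         t_max: float = 2000.0) -> list[GridPoint]:
    """Classify a (theta, alpha'/theta) grid numerically and analytically.

    The domain is long (400 µm) and the inhibition strong enough that the
    inter-aster interface is fully developed, the regime in which the
    linear criterion alpha' = theta describes the boundary dynamics; the
    requested alpha'/theta ratios exclude a ±5% marginal band where
    critical slowing down makes finite-time classification ill-posed.
    The turnover range keeps the growth length v_p/theta a sizeable
    fraction of the aster separation, where the scanned ratios are all
    achievable (alpha'/theta saturates with alpha once the interface
    density reaches the plateau).
    """
    grid = Grid1D(L, nx)
    out = []
    for theta in thetas:
        base = ModelParams(v_p=v_p, alpha=2 * theta, theta=theta,
                           lam=lam_over_theta * theta, rho_s=rho_s,
                           rho_c=rho_c)
        for ratio in ratios:
            alpha = calibrate_alpha(ratio, base, grid)
            p = base.replace(alpha=alpha)
            margin = stability_margin(p, grid=grid).margin
            num = classify_stability_numerical(p, grid, t_max=t_max)
            out.append(GridPoint(theta=theta, target_ratio=ratio,
                                 alpha=alpha, margin=margin,
                                 analytic="stable" if margin < 0
                                 else "unstable", numerical=num))
    return out


# ---------------------------------------------------------------------------
# instability development time near the boundary
# ---------------------------------------------------------------------------

@dataclass
class DevelopmentScan:
    ratios: tuple
    alphas: list
    efold_times: list          # min; NaN where no growth within the window
    max_time: float            # max over the scan points that destabilize
    n_points: int


def development_time_scan(ratios=(1.5, 1.2, 1.1, 1.05, 1.02),
                          v_p: float = 10.0, theta: float = 0.2,
                          rho_s: float = 1.0, rho_c: float = 0.5,
                          L: float = 200.0, nx: int = 128,
                          eps: float = 0.01,
                          t_max: float = 1200.0) -> DevelopmentScan:
    """E-folding time of a small mass asymmetry approaching the boundary.

    Two asters 200 µm apart with lam = theta; for each target
    alpha'/theta the autocatalytic rate is calibrated, the symmetric
    steady interface perturbed to a 1% mass asymmetry, and the time for
    the asymmetry to grow by a factor e recorded.  Scan points whose
    asymmetry does not grow within the window (the anchored finite system
    renormalizes the threshold upward) are reported as NaN; the headline
    number is the maximum over the points that do destabilize.
    """
    grid = Grid1D(L, nx)
    base = ModelParams(v_p=v_p, alpha=2 * theta, theta=theta, lam=theta,
                       rho_s=rho_s, rho_c=rho_c)
    alphas, times = [], []
    for ratio in ratios:
        alpha = calibrate_alpha(ratio, base, grid)
        alphas.append(alpha)
        try:
            tau = asymmetry_efold_time(base.replace(alpha=alpha), grid,
                                       eps=eps, t_max=t_max)
        except NoInvasionError:
            tau = math.nan
        times.append(tau)
    finite = [t for t in times if not math.isnan(t)]
    return DevelopmentScan(ratios=tuple(ratios), alphas=alphas,
                           efold_times=times,
                           max_time=max(finite) if finite else math.nan,
                           n_points=len(ratios))


# ---------------------------------------------------------------------------
# invasion-time law
# ---------------------------------------------------------------------------

@dataclass
class InvasionStudy:
    dM_fracs: tuple
    tau_theory: list
    tau_measured: list


def invasion_time_study(truth: ModelParams | None = None,
                        dM_fracs=(0.02, 0.05, 0.1, 0.2, 0.4),
                        grid: Grid1D | None = None,
                        seed: int = 0) -> InvasionStudy:
    """Predicted vs measured invasion times over initial mass differences.

    Theory: parameter-free solver prediction.  Measurement: noiseless
    synthetic mass series passed through the mass-series extractor.
    """
    truth = truth or synth.extract_like()
    grid = grid or Grid1D(200.0, 128)
    theory, measured = [], []
    for dm in dM_fracs:
        theory.append(predict_invasion_time(truth, dm, grid).tau)
        data = synth.gen_invasion_series(truth, dm, noise=0.0, seed=seed,
                                         grid=grid, frame_dt=0.5)
        measured.append(measure_invasion_time(data.mass_series))
    return InvasionStudy(dM_fracs=tuple(dM_fracs), tau_theory=theory,
                         tau_measured=measured)


# ---------------------------------------------------------------------------
# parameter recovery and phase placement
# ---------------------------------------------------------------------------

def make_replicate_profiles(truth: ModelParams, n_replicates: int,
                            noise: float, seed: int,
                            grid: Grid1D | None = None,
                            rc_range=(0.35, 0.7)) -> list[DensityProfile]:
    """Replicate steady profiles with per-replicate centre amplitudes and
    multiplicative measurement noise (per-bin sem = noise level)."""
    from .continuum import symmetric_pair_profile

    grid = grid or Grid1D(200.0, 96)
    rng = np.random.default_rng(seed)
    profs = []
    for _ in range(n_replicates):
        rc = rng.uniform(*rc_range)
        r1, r2 = symmetric_pair_profile(truth.replace(rho_c=rc), grid)
        n1 = np.clip(r1 * (1 + noise * rng.standard_normal(len(r1))), 0, None)
        n2 = np.clip(r2 * (1 + noise * rng.standard_normal(len(r2))), 0, None)
        sem = np.maximum(max(noise, 0.01) * np.maximum(r1, r2), 1e-4)
        profs.append(DensityProfile(x=grid.x, rho1=n1, rho2=n2,
                                    sem1=sem, sem2=sem))
    return profs


@dataclass
class RecoveryStudy:
    truth: ModelParams
    fitted: dict
    errors: dict               # relative errors on alpha, lam, rho_s
    phase_ratio: float         # fitted alpha'/theta


def recovery_study(truth: ModelParams | None = None, n_replicates: int = 8,
                   noise: float = 0.05, seed: int = 0,
                   grid: Grid1D | None = None) -> RecoveryStudy:
    """Global-fit recovery of (alpha, lam, rho_s) from noisy replicates."""
    truth = truth or synth.extract_like()
    grid = grid or Grid1D(200.0, 96)
    profs = make_replicate_profiles(truth, n_replicates, noise, seed, grid)
    res = ProfileFitModel(profs, truth.v_p, truth.theta, grid=grid).fit(
        n_starts=8, seed=seed)
    errors = {k: abs(res.params[k] / getattr(truth, k) - 1.0)
              for k in ("alpha", "lam", "rho_s")}
    th, ae = res.phase_point()
    return RecoveryStudy(truth=truth, fitted=dict(res.params),
                         errors=errors, phase_ratio=ae / th)


@dataclass
class PlacementStudy:
    truth_side: str
    sides: list
    frac_correct: float


def phase_placement_study(truth: ModelParams | None = None,
                          n_realizations: int = 50, n_replicates: int = 8,
                          noise: float = 0.05, seed: int = 0,
                          grid: Grid1D | None = None) -> PlacementStudy:
    """Fraction of noise realizations whose fitted phase placement falls
    on the truth's side of the alpha' = theta boundary.

    Each realization generates fresh replicate profiles, refits
    (warm-started at the full multi-start optimum of the first
    realization) and classifies the fitted (theta, alpha') point.
    """
    truth = truth or synth.extract_like()
    grid = grid or Grid1D(200.0, 96)
    truth_side = "stable" if stability_margin(truth, grid=grid).stable \
        else "unstable"
    warm = None
    sides = []
    for k in range(n_realizations):
        profs = make_replicate_profiles(truth, n_replicates, noise,
                                        seed + 1000 * k, grid)
        model = ProfileFitModel(profs, truth.v_p, truth.theta, grid=grid)
        if warm is None:
            res = model.fit(n_starts=8, seed=seed)
            warm = res.logp
        else:
            res = model.fit(x0=warm)
        th, ae = res.phase_point()
        sides.append("stable" if ae < th else "unstable")
    frac = float(np.mean([s == truth_side for s in sides]))
    return PlacementStudy(truth_side=truth_side, sides=sides,
                          frac_correct=frac)


# ---------------------------------------------------------------------------
# agent-continuum consistency
# ---------------------------------------------------------------------------

@dataclass
class AgentContinuumStudy:
    rmse_over_peak: float
    count_mean: float
    count_expected: float
    count_tol_3sigma: float
    length_mean: float
    length_expected: float
    length_tol_3sigma: float


def agent_continuum_study(seed: int = 0) -> AgentContinuumStudy:
    """Match the agent simulator against continuum closed forms.

    (a) Branching off: stationary filament count k_nuc/theta and mean
    length v_p/theta (immigration-death closed forms).  (b) Low branching
    mapped onto alpha = k_branch v_p / theta: the radially binned
    plus-end density against the continuum single-aster steady profile.
    """
    from .agents import AgentConfig, radial_plus_end_profile, run_agents

    # (a) birth-death closed forms
    cfg = AgentConfig(v_p=10.0, theta=1.0, k_nuc=50.0, k_branch=0.0,
                      dt=0.02, seed=seed, slab=(400.0, 200.0, 10.0),
                      separation=200.0)
    run = run_agents(cfg, T=30.0, sample_every=1.0)
    counts = run.counts()[10:]
    count_mean = float(counts.mean())
    n_eff = counts.size / 2.0  # ~1/theta autocorrelation at 1-min sampling
    count_tol = 3.0 * math.sqrt(50.0 / n_eff)
    lens = np.concatenate([s.length for s in run.snapshots[10:]])
    length_mean = float(lens.mean())
    # exponential lengths: sd = mean; cluster-decorrelated sample count
    length_tol = 3.0 * 10.0 / math.sqrt(len(lens) / 10.0)

    # (b) continuum correspondence at alpha = k_branch v_p / theta
    alpha, theta, v_p = 0.5, 1.0, 10.0
    cfg2 = AgentConfig(v_p=v_p, theta=theta, k_nuc=200.0,
                       k_branch=alpha * theta / v_p, n_nucleators=10 ** 7,
                       dt=0.05, seed=seed + 1, slab=(400.0, 300.0, 10.0),
                       separation=240.0)
    run2 = run_agents(cfg2, T=40.0, sample_every=0.5)
    r, dens = radial_plus_end_profile(run2, aster=1, binwidth=4.0,
                                      r_max=80.0, burn_in=15.0)
    g = Grid1D(100.0, 200)
    p = ModelParams(v_p=v_p, alpha=alpha, theta=theta, lam=0.0,
                    rho_s=1e9, rho_c=1.0)
    prof = single_aster_profile(p, g)
    model = np.interp(r, g.x, prof)
    model *= dens.sum() / model.sum()
    rmse = float(np.sqrt(np.mean((dens - model) ** 2)) / dens.max())
    return AgentContinuumStudy(
        rmse_over_peak=rmse, count_mean=count_mean, count_expected=50.0,
        count_tol_3sigma=count_tol, length_mean=length_mean,
        length_expected=10.0, length_tol_3sigma=length_tol)


# ---------------------------------------------------------------------------
# cell-cycle rescue sweep
# ---------------------------------------------------------------------------

@dataclass
class CyclingSweep:
    T_ccs: tuple
    mean_sizes: dict           # T_cc -> mean normalized size over seeds
    size_variances: dict       # T_cc -> variance of pooled final sizes
    n_alive: dict              # T_cc -> list of survivor counts per seed


def cycling_sweep_study(truth: ModelParams, T_ccs=(10.0, 20.0, 40.0, 80.0),
                        n_seeds: int = 10, n_asters: int = 12,
                        spacing: float = 200.0, total_time: float = 320.0,
                        seed: int = 0) -> CyclingSweep:
    """Compartment-size statistics under mitotic resets of varying period.

    N asters spaced 200 µm apart; total simulated time is held fixed so
    longer cycles mean fewer resets.  Sizes are read just before each
    reset and normalized to the initial compartment extent.
    """
    L = n_asters * spacing
    grid = Grid1D(L, int(L / 3.125))
    centres = (np.arange(n_asters) + 0.5) * spacing
    means, variances, alive = {}, {}, {}
    for tcc in T_ccs:
        m, pooled, na = [], [], []
        cyc = CycleConfig(T_cc=tcc, n_cycles=max(1, round(total_time / tcc)))
        for s in range(n_seeds):
            res = run_cycling(truth, centres, grid, cyc, seed=seed + s)
            m.append(res.mean_size_norm())
            pooled.extend(res.final_sizes_norm())
            na.append(res.summaries[-1].n_alive)
        means[tcc] = float(np.mean(m))
        variances[tcc] = float(np.var(pooled))
        alive[tcc] = na
    return CyclingSweep(T_ccs=tuple(T_ccs), mean_sizes=means,
                        size_variances=variances, n_alive=alive)
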