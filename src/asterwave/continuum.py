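"""Continuum model of interacting microtubule asters.

The density of growing plus ends of aster *i* obeys

    drho_i/dt = -s_i v_p drho_i/dx
                + alpha rho_i / (1 + rho_tot/rho_s)
                - theta rho_i
                - lam rho_i rho_opp / (rho_i + rho_opp)

where ``s_i`` points outward from the aster's own centre, ``rho_tot`` is the
total density of all asters and ``rho_opp`` the total density of the other
asters (for two asters the inhibition term reduces to
``lam rho_1 rho_2 / (rho_1 + rho_2)``, defined as 0 where both vanish).

Numerics: first-order upwind advection in flux form (monotone and
positivity-preserving) with explicit Euler reaction, CFL <= 1.  Each aster
is anchored by pinning the density of its own centre cell to ``rho_c``
(a stand-in for centrosomal nucleation) with free outflow at the far ends;
a mass-conserving reflecting variant without anchors is available for
verification runs.

Linearizing around the symmetric two-aster steady state yields the
stability criterion: the boundary between the asters is stable iff

    theta > alpha' = alpha / (1 + 2 rho_int / rho_s)

with ``rho_int`` the density where the two asters intersect.  The numerical
classifier below checks this by perturbing the symmetric steady state and
watching whether the mass asymmetry grows or decays by a factor e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    InvalidParameterError,
    NoInvasionError,
    NumericalBlowupError,
)
from .params import CycleConfig, Grid1D, ModelParams, default_dt

__all__ = [
    "PairState",
    "Trajectory",
    "StabilityAssessment",
    "effective_autocatalysis",
    "stability_margin",
    "single_aster_profile",
    "symmetric_pair_profile",
    "rho_intersection",
    "solve_pair",
    "solve_multi_aster",
    "interface_position",
    "predict_invasion_time",
    "asymmetry_efold_time",
    "classify_stability_numerical",
    "calibrate_alpha",
    "run_cycling",
    "CycleSummary",
    "CyclingResult",
    "InvasionPrediction",
]

E = math.e


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _march(rho, cidx, alive, dt, dx, vp, alpha, theta, lam, rho_s, rho_c,
           anchored, reflect_left, reflect_right, mirror, nsteps):
    """Advance ``rho`` (shape (N, nx)) by ``nsteps`` explicit steps in place.

    Returns True if a non-finite value appeared.  ``mirror`` enforces the
    mirror symmetry rho_2(x) = rho_1(L - x) after every step (used for
    symmetric steady-state computation, where it also removes the unstable
    antisymmetric mode).
    """
    N, nx = rho.shape
    flux = np.empty(nx + 1)
    tot = np.empty(nx)
    new = np.empty_like(rho)
    for _ in range(nsteps):
        for j in range(nx):
            s = 0.0
            for i in range(N):
                if alive[i]:
                    s += rho[i, j]
            tot[j] = s
        for i in range(N):
            if not alive[i]:
                continue
            c = cidx[i]
            # upwind fluxes, positive rightward; cells right of the centre
            # advect at +vp, cells left of it at -vp, the centre feeds both
            flux[0] = 0.0
            if (not reflect_left) and c > 0:
                flux[0] = -vp * rho[i, 0]
            flux[nx] = 0.0
            if (not reflect_right) and c < nx - 1:
                flux[nx] = vp * rho[i, nx - 1]
            for k in range(1, nx):
                if k - 1 >= c:
                    flux[k] = vp * rho[i, k - 1]
                else:  # k <= c
                    flux[k] = -vp * rho[i, k]
            for j in range(nx):
                r = rho[i, j]
                t = tot[j]
                growth = alpha * r / (1.0 + t / rho_s)
                opp = t - r
                inhib = 0.0
                if t > 0.0:
                    inhib = lam * r * opp / t
                val = r + dt * ((flux[j] - flux[j + 1]) / dx
                                + growth - theta * r - inhib)
                if val < 0.0:
                    val = 0.0
                new[i, j] = val
            if anchored:
                new[i, c] = rho_c[i]
        for i in range(N):
            if alive[i]:
                for j in range(nx):
                    rho[i, j] = new[i, j]
        if mirror:
            for j in range(nx):
                rho[1, j] = rho[0, nx - 1 - j]
    bad = False
    for i in range(N):
        for j in range(nx):
            if not np.isfinite(rho[i, j]):
                bad = True
    return bad


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class PairState:
    """Densities of two asters on a common grid at one instant."""

    t: float
    rho1: np.ndarray
    rho2: np.ndarray

    def __post_init__(self):
        self.rho1 = np.asarray(self.rho1, dtype=float)
        self.rho2 = np.asarray(self.rho2, dtype=float)
        if self.rho1.shape != self.rho2.shape:
            raise InvalidParameterError("rho1 and rho2 must share a grid")
        if (not np.all(np.isfinite(self.rho1)) or
                not np.all(np.isfinite(self.rho2))):
            raise InvalidParameterError("densities must be finite")
        if (self.rho1 < 0).any() or (self.rho2 < 0).any():
            raise InvalidParameterError("densities must be non-negative")


@dataclass
class Trajectory:
    """Time-ordered densities of N asters: ``rho[k, i, j]`` at ``t[k]``."""

    t: np.ndarray
    rho: np.ndarray
    params: ModelParams
    grid: Grid1D
    centres: np.ndarray

    @property
    def n_asters(self) -> int:
        return self.rho.shape[1]

    def state(self, k: int) -> PairState:
        if self.n_asters != 2:
            raise InvalidParameterError("state() requires a two-aster run")
        return PairState(self.t[k], self.rho[k, 0], self.rho[k, 1])

    def masses(self) -> np.ndarray:
        """Per-aster mass over time (area under the density curve)."""
        return np.trapezoid(self.rho, dx=self.grid.dx, axis=2)

    def to_frame(self):
        """Long-format DataFrame (t_min, x_um, aster_id, rho)."""
        import pandas as pd

        nt, N, nx = self.rho.shape
        t = np.repeat(self.t, N * nx)
        aster = np.tile(np.repeat(np.arange(1, N + 1), nx), nt)
        x = np.tile(self.grid.x, nt * N)
        return pd.DataFrame(
            {"t_min": t, "x_um": x, "aster_id": aster,
             "rho": self.rho.reshape(-1)}
        )


@dataclass(frozen=True)
class StabilityAssessment:
    """Outcome of the analytic stability criterion."""

    alpha_eff: float
    theta: float
    margin: float
    stable: bool
    rho_int: float


@dataclass(frozen=True)
class InvasionPrediction:
    """Predicted invasion time and the mass series it was read from."""

    tau: float
    dM_frac: float
    times: np.ndarray
    masses: np.ndarray  # (nt, 2)


# ---------------------------------------------------------------------------
# stability criterion
# ---------------------------------------------------------------------------

def effective_autocatalysis(alpha: float, rho_int: float, rho_s: float) -> float:
    """Effective autocatalytic rate alpha' = alpha / (1 + 2 rho_int / rho_s)."""
    if rho_s <= 0:
        raise InvalidParameterError(f"rho_s must be > 0, got {rho_s!r}")
    if rho_int < 0:
        raise InvalidParameterError(f"rho_int must be >= 0, got {rho_int!r}")
    return alpha / (1.0 + 2.0 * rho_int / rho_s)


def stability_margin(params: ModelParams, rho_int: float | None = None,
                     grid: Grid1D | None = None) -> StabilityAssessment:
    """Analytic stability of the aster-aster boundary.

    ``margin = alpha' - theta``; the boundary is stable iff the margin is
    negative.  If ``rho_int`` is not supplied it is extracted from the
    symmetric two-aster steady state on ``grid`` (default 200 µm / 128
    cells), i.e. the density value at the interface crossing.
    """
    if rho_int is None:
        grid = grid or Grid1D(200.0, 128)
        rho1, rho2 = symmetric_pair_profile(params, grid)
        rho_int = rho_intersection(rho1, rho2, grid)
    a_eff = effective_autocatalysis(params.alpha, rho_int, params.rho_s)
    margin = a_eff - params.theta
    return StabilityAssessment(
        alpha_eff=a_eff, theta=params.theta, margin=margin,
        stable=margin < 0.0, rho_int=rho_int,
    )


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def _steady(params: ModelParams, grid: Grid1D, n: int, mirror: bool,
            tol: float, t_max: float, init: np.ndarray | None,
            dt: float | None = None) -> np.ndarray:
    dt = dt if dt is not None else default_dt(params, grid)
    nx = grid.nx
    if init is None:
        rho = np.zeros((n, nx))
    else:
        rho = np.array(init, dtype=float).reshape(n, nx).copy()
    cidx = (np.array([0], dtype=np.int64) if n == 1
            else np.array([0, nx - 1], dtype=np.int64))
    alive = np.ones(n, dtype=np.bool_)
    rho_c = np.full(n, params.rho_c)
    for i in range(n):
        rho[i, cidx[i]] = params.rho_c
    chunk = max(1, int(round(2.0 / dt)))  # ~2 min of model time per check
    t = 0.0
    scale = max(params.rho_c, params.rho_s * max(params.alpha / max(params.theta, 1e-12) - 1.0, 0.0), 1e-12)
    while t < t_max:
        prev = rho.copy()
        bad = _march(rho, cidx, alive, dt, grid.dx, params.v_p, params.alpha,
                     params.theta, params.lam, params.rho_s, rho_c,
                     True, False, False, mirror and n == 2, chunk)
        if bad:
            raise NumericalBlowupError(
                "non-finite density during steady-state iteration",
                last_valid_time=t)
        t += chunk * dt
        resid = np.max(np.abs(rho - prev)) / (chunk * dt) / scale
        if resid < tol:
            return rho
    raise ConvergenceError(
        f"steady state not reached within t_max={t_max} min", residual=resid)


def single_aster_profile(params: ModelParams, grid: Grid1D,
                         tol: float = 1e-8, t_max: float = 4000.0,
                         init: np.ndarray | None = None) -> np.ndarray:
    """Steady density of a lone aster anchored at x = 0, advecting in +x.

    In the low-density limit the profile is ``rho_c exp((alpha-theta) x/v_p)``;
    for alpha > theta the far field saturates at ``rho_s (alpha/theta - 1)``.
    """
    return _steady(params, grid, 1, False, tol, t_max, init)[0]


def symmetric_pair_profile(params: ModelParams, grid: Grid1D,
                           tol: float = 1e-8, t_max: float = 4000.0,
                           init: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mirror-symmetric steady state of the two-aster system.

    Centres sit at the first and last grid cell; the mirror constraint
    rho_2(x) = rho_1(L-x) is enforced during the march, which also
    suppresses the antisymmetric instability so the symmetric branch is
    reachable on both sides of the stability boundary.
    """
    rho = _steady(params, grid, 2, True, tol, t_max, init)
    return rho[0], rho[1]


def rho_intersection(rho1: np.ndarray, rho2: np.ndarray, grid: Grid1D) -> float:
    """Density value where the two aster profiles cross."""
    xi = interface_position(PairState(0.0, rho1, rho2), grid)
    return float(np.interp(xi, grid.x, rho1))


# ---------------------------------------------------------------------------
# initial-value solvers
# ---------------------------------------------------------------------------

def _run(params, grid, cidx, init, dt, T, save_every, anchored=True,
         reflect=False, rho_c_per_aster=None, alive=None):
    nx = grid.nx
    N = len(cidx)
    dt = dt if dt is not None else default_dt(params, grid)
    if params.v_p * dt / grid.dx > 1.0 + 1e-12:
        raise ConfigurationError(
            f"CFL violation: v_p*dt/dx = {params.v_p * dt / grid.dx:.3f} > 1")
    rho = np.array(init, dtype=float).reshape(N, nx).copy()
    if (rho < 0).any():
        raise InvalidParameterError("initial densities must be non-negative")
    cidx = np.asarray(cidx, dtype=np.int64)
    alive = (np.ones(N, dtype=np.bool_) if alive is None
             else np.asarray(alive, dtype=np.bool_))
    rho_c = (np.full(N, params.rho_c) if rho_c_per_aster is None
             else np.asarray(rho_c_per_aster, dtype=float))
    if anchored:
        for i in range(N):
            if alive[i]:
                rho[i, cidx[i]] = rho_c[i]
    nsteps = int(round(T / dt))
    save_every = save_every or max(1, nsteps // 200)
    times = [0.0]
    out = [rho.copy()]
    done = 0
    while done < nsteps:
        k = min(save_every, nsteps - done)
        bad = _march(rho, cidx, alive, dt, grid.dx, params.v_p, params.alpha,
                     params.theta, params.lam, params.rho_s, rho_c,
                     anchored, reflect, reflect, False, k)
        done += k
        if bad:
            raise NumericalBlowupError(
                "non-finite density during integration",
                last_valid_time=times[-1])
        times.append(done * dt)
        out.append(rho.copy())
    return Trajectory(np.array(times), np.array(out), params, grid,
                      grid.x[cidx])


def solve_pair(params: ModelParams, init: PairState | Sequence[np.ndarray],
               grid: Grid1D, dt: float | None = None, T: float = 60.0,
               save_every: int | None = None, anchored: bool = True,
               reflect: bool = False) -> Trajectory:
    """Evolve two asters anchored at x = 0 (rightward) and x = L (leftward).

    ``reflect=True`` replaces the open far-end boundaries with reflecting
    walls (used together with ``anchored=False`` for conservation checks).
    """
    if isinstance(init, PairState):
        init = np.stack([init.rho1, init.rho2])
    else:
        init = np.stack([np.asarray(a, dtype=float) for a in init])
    cidx = [0, grid.nx - 1]
    return _run(params, grid, cidx, init, dt, T, save_every,
                anchored=anchored, reflect=reflect)


def solve_multi_aster(params: ModelParams, centres: Sequence[float],
                      grid: Grid1D, dt: float | None = None, T: float = 60.0,
                      init: np.ndarray | None = None,
                      save_every: int | None = None,
                      rho_c_per_aster: Sequence[float] | None = None) -> Trajectory:
    """Evolve N asters anchored at ``centres`` (strictly increasing, µm).

    Each aster advects outward from its own centre; saturation uses the
    total density and the inhibition of aster *i* uses the summed density
    of all other asters.  With centres {0, L} this reduces exactly to
    :func:`solve_pair`.
    """
    centres = np.asarray(centres, dtype=float)
    if centres.ndim != 1 or len(centres) < 1:
        raise ConfigurationError("need at least one centre")
    if np.any(np.diff(centres) <= 0):
        raise ConfigurationError("centres must be strictly increasing")
    cidx = [grid.index_of(c) for c in centres]
    if len(set(cidx)) != len(cidx):
        raise ConfigurationError("aster centres overlap on the grid")
    N = len(cidx)
    if init is None:
        init = np.zeros((N, grid.nx))
    return _run(params, grid, cidx, init, dt, T, save_every,
                rho_c_per_aster=rho_c_per_aster)


# ---------------------------------------------------------------------------
# interface
# ---------------------------------------------------------------------------

def interface_position(state: PairState, grid: Grid1D,
                       previous: float | None = None) -> float:
    """Linear-interpolated x where rho_1 - rho_2 changes sign.

    With several crossings the one closest to ``previous`` (or the domain
    midpoint) is returned.  Raises :class:`NoInvasionError` when one density
    dominates everywhere (invasion complete).
    """
    d = state.rho1 - state.rho2
    x = grid.x
    sign = np.sign(d)
    # treat exact zeros as crossings at the cell centre
    zeros = np.flatnonzero(sign == 0)
    crossings = []
    for j in zeros:
        crossings.append(x[j])
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    for j in idx:
        xc = x[j] + (x[j + 1] - x[j]) * d[j] / (d[j] - d[j + 1])
        crossings.append(xc)
    if not crossings:
        raise NoInvasionError("invasion complete: no interface crossing")
    ref = grid.L / 2 if previous is None else previous
    return float(min(crossings, key=lambda c: abs(c - ref)))


# ---------------------------------------------------------------------------
# invasion / stability dynamics
# ---------------------------------------------------------------------------

def _perturbed_steady(params, grid, dM_frac):
    rho1, rho2 = symmetric_pair_profile(params, grid)
    up = 1.0 + dM_frac / 2.0
    dn = 1.0 - dM_frac / 2.0
    return np.stack([rho1 * up, rho2 * dn])


def _mass_series(params, grid, init, dt, t_max, record_min):
    """March the pair and record masses every ``record_min`` minutes."""
    dt = dt if dt is not None else default_dt(params, grid)
    rho = init.copy()
    cidx = np.array([0, grid.nx - 1], dtype=np.int64)
    alive = np.ones(2, dtype=np.bool_)
    rho_c = np.full(2, params.rho_c)
    rho[0, 0] = params.rho_c
    rho[1, -1] = params.rho_c
    k = max(1, int(round(record_min / dt)))
    nrec = int(math.ceil(t_max / (k * dt)))
    times = np.empty(nrec + 1)
    masses = np.empty((nrec + 1, 2))
    times[0] = 0.0
    masses[0] = np.trapezoid(rho, dx=grid.dx, axis=1)
    for r in range(1, nrec + 1):
        bad = _march(rho, cidx, alive, dt, grid.dx, params.v_p, params.alpha,
                     params.theta, params.lam, params.rho_s, rho_c,
                     True, False, False, False, k)
        if bad:
            raise NumericalBlowupError("non-finite density",
                                       last_valid_time=times[r - 1])
        times[r] = r * k * dt
        masses[r] = np.trapezoid(rho, dx=grid.dx, axis=1)
    return times, masses


def predict_invasion_time(params: ModelParams, dM_frac: float,
                          grid: Grid1D | None = None, dt: float | None = None,
                          t_max: float = 3000.0,
                          record_min: float = 0.25) -> InvasionPrediction:
    """Invasion time from first principles (no free parameters).

    The symmetric steady interface is perturbed to a fractional mass
    difference ``dM_frac`` and the pair dynamics solved; tau is the first
    time the invaded (smaller) aster's mass has decreased by a factor e
    from its initial value.  In the stable regime no invasion occurs and a
    :class:`NoInvasionError` carrying the decay timescale of the mass
    asymmetry is raised instead.
    """
    if not (0.0 < dM_frac < 1.0):
        raise InvalidParameterError("dM_frac must be in (0, 1)")
    grid = grid or Grid1D(200.0, 128)
    assessment = stability_margin(params, grid=grid)
    init = _perturbed_steady(params, grid, dM_frac)
    times, masses = _mass_series(params, grid, init, dt, t_max, record_min)
    loser = masses[:, 1]
    target = loser[0] / E
    below = np.flatnonzero(loser <= target)
    if assessment.stable or len(below) == 0:
        # decay timescale of the asymmetry instead
        dm = np.abs(masses[:, 0] - masses[:, 1])
        dec = np.flatnonzero(dm <= dm[0] / E)
        decay = float(times[dec[0]]) if len(dec) else float("inf")
        raise NoInvasionError(
            "stable parameters: mass asymmetry decays, no invasion",
            decay_time=decay)
    j = below[0]
    tau = float(np.interp(target, loser[j - 1:j + 1][::-1],
                          times[j - 1:j + 1][::-1])) if j > 0 else 0.0
    return InvasionPrediction(tau=tau, dM_frac=dM_frac, times=times,
                              masses=masses)


def asymmetry_efold_time(params: ModelParams, grid: Grid1D | None = None,
                         eps: float = 0.01, dt: float | None = None,
                         t_max: float = 4000.0,
                         record_min: float = 0.25) -> float:
    """Time for a small initial mass asymmetry to grow by a factor e.

    The symmetric steady state is perturbed to a fractional mass difference
    ``eps``; returns the first time |M1 - M2| reaches e times its initial
    value (linear interpolation between samples).  Raises
    :class:`NoInvasionError` if the asymmetry never grows by e (stable or
    window exhausted).
    """
    grid = grid or Grid1D(200.0, 128)
    init = _perturbed_steady(params, grid, eps)
    times, masses = _mass_series(params, grid, init, dt, t_max, record_min)
    dm = masses[:, 0] - masses[:, 1]
    target = E * dm[0]
    above = np.flatnonzero(dm >= target)
    if len(above) == 0:
        raise NoInvasionError(
            f"asymmetry did not grow by e within {t_max} min")
    j = above[0]
    if j == 0:
        return 0.0
    return float(np.interp(target, dm[j - 1:j + 1], times[j - 1:j + 1]))


def classify_stability_numerical(params: ModelParams,
                                 grid: Grid1D | None = None,
                                 eps: float = 0.01,
                                 dt: float | None = None,
                                 t_max: float = 1500.0,
                                 record_min: float = 0.5) -> str:
    """Classify the boundary by direct perturbation of the steady state.

    Returns "unstable" when the mass asymmetry grows by >= e within the
    observation window, "stable" when it decays by >= e, and "marginal"
    when neither happens (critical slowing down makes finite-time
    classification ill-posed near the boundary).
    """
    grid = grid or Grid1D(200.0, 128)
    init = _perturbed_steady(params, grid, eps)
    times, masses = _mass_series(params, grid, init, dt, t_max, record_min)
    dm = np.abs(masses[:, 0] - masses[:, 1])
    if np.any(dm >= E * dm[0]):
        return "unstable"
    if np.any(dm <= dm[0] / E):
        return "stable"
    return "marginal"


def calibrate_alpha(target_ratio: float, params: ModelParams,
                    grid: Grid1D | None = None,
                    bracket: tuple[float, float] | None = None,
                    xtol: float = 1e-4) -> float:
    """Autocatalytic rate alpha giving alpha'/theta == target_ratio.

    alpha' depends on alpha through the interface density of the symmetric
    steady state, so the mapping is solved by bisection.  The remaining
    fields of ``params`` are held fixed.
    """
    grid = grid or Grid1D(200.0, 128)
    th = params.theta

    def f(alpha):
        p = params.replace(alpha=alpha)
        a = stability_margin(p, grid=grid)
        return a.alpha_eff / th - target_ratio

    if bracket is None:
        # alpha' <= alpha bounds from below; expand upward until the target
        # is bracketed.  alpha'/theta saturates at large alpha (the
        # interface density grows with the plateau), so stop early if the
        # map turns over before reaching the target.
        lo = th * target_ratio
        hi = lo
        prev = -np.inf
        for _ in range(60):
            hi *= 1.5
            val = f(hi)
            if val > 0:
                break
            if val < prev - 1e-6:
                raise ConvergenceError(
                    f"target alpha'/theta = {target_ratio} exceeds the "
                    f"achievable maximum (~{target_ratio + prev:.3f}) for "
                    "these parameters")
            prev = val
        else:
            raise ConvergenceError("could not bracket alpha")
        bracket = (lo, hi)
    return float(brentq(f, *bracket, xtol=xtol))


# ---------------------------------------------------------------------------
# cell-cycle coupled dynamics
# ---------------------------------------------------------------------------

@dataclass
class CycleSummary:
    """Per-cycle compartment measurements (taken just before the reset)."""

    cycle: int
    t: float
    masses: np.ndarray          # per surviving aster
    sizes: np.ndarray           # compartment extents, µm
    sizes_norm: np.ndarray      # normalized to the initial mean extent
    centres: np.ndarray         # anchor positions, µm
    n_alive: int


@dataclass
class CyclingResult:
    params: ModelParams
    grid: Grid1D
    cycle: CycleConfig
    summaries: list = field(default_factory=list)

    def final_sizes_norm(self) -> np.ndarray:
        return self.summaries[-1].sizes_norm

    def mean_size_norm(self) -> float:
        return float(np.mean(self.summaries[-1].sizes_norm))


def _compartment_sizes(rho, alive, dx):
    """Territory of each alive aster: cells where it has the largest density."""
    sub = rho[alive]
    owner = np.argmax(sub, axis=0)
    counts = np.bincount(owner, minlength=sub.shape[0])
    return counts * dx


def run_cycling(params: ModelParams, centres: Sequence[float], grid: Grid1D,
                cycle: CycleConfig, seed: int = 0,
                dt: float | None = None, amp_noise: float = 0.05,
                kill_frac: float = 0.1) -> CyclingResult:
    """Multi-aster dynamics punctuated by mitotic resets.

    Asters start from their anchors with per-aster amplitude jitter of
    relative size ``amp_noise`` (mimicking unequal nucleation sources).
    At the end of each cycle compartment masses and extents are measured;
    asters whose mass fell below ``kill_frac`` of the mean are removed
    (their nucleus is lost to the invading neighbour), densities are
    multiplied by ``reset_fraction`` and, if requested, surviving asters
    are re-anchored at their own mass centroid.
    """
    rng = np.random.default_rng(seed)
    centres = np.asarray(centres, dtype=float)
    if np.any(np.diff(centres) <= 0):
        raise ConfigurationError("centres must be strictly increasing")
    N = len(centres)
    cidx = np.array([grid.index_of(c) for c in centres], dtype=np.int64)
    if len(set(cidx.tolist())) != N:
        raise ConfigurationError("aster centres overlap on the grid")
    dt = dt if dt is not None else default_dt(params, grid)
    rho_c = params.rho_c * np.clip(
        1.0 + amp_noise * rng.standard_normal(N), 0.1, None)
    alive = np.ones(N, dtype=np.bool_)
    rho = np.zeros((N, grid.nx))
    for i in range(N):
        rho[i, cidx[i]] = rho_c[i]
    size0 = grid.L / N
    result = CyclingResult(params, grid, cycle)
    nsteps = int(round(cycle.T_cc / dt))
    for c in range(cycle.n_cycles):
        bad = _march(rho, cidx, alive, dt, grid.dx, params.v_p, params.alpha,
                     params.theta, params.lam, params.rho_s, rho_c,
                     True, False, False, False, nsteps)
        if bad:
            raise NumericalBlowupError("non-finite density in cycling run",
                                       last_valid_time=c * cycle.T_cc)
        masses = np.trapezoid(rho, dx=grid.dx, axis=1)
        mean_alive = masses[alive].mean()
        # an aster whose mass collapsed has been invaded: remove it
        for i in range(N):
            if alive[i] and masses[i] < kill_frac * mean_alive:
                alive[i] = False
                rho[i] = 0.0
        sizes = _compartment_sizes(rho, alive, grid.dx)
        result.summaries.append(CycleSummary(
            cycle=c, t=(c + 1) * cycle.T_cc,
            masses=masses[alive].copy(), sizes=sizes,
            sizes_norm=sizes / size0,
            centres=grid.x[cidx[alive]].copy(), n_alive=int(alive.sum()),
        ))
        # mitotic reset
        rho *= cycle.reset_fraction
        if cycle.recentre:
            for i in range(N):
                if alive[i] and rho[i].sum() > 0:
                    cm = float(np.sum(grid.x * rho[i]) / np.sum(rho[i]))
                    cidx[i] = grid.index_of(cm)
            # collapse collisions: keep first occupant of a cell
            seen = {}
            for i in range(N):
                if not alive[i]:
                    continue
                if cidx[i] in seen:
                    alive[i] = False
                    rho[i] = 0.0
                else:
                    seen[cidx[i]] = i
        for i in range(N):
            if alive[i]:
                rho[i, cidx[i]] = rho_c[i]
    return result
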