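"""Synthetic data with the statistical structure the pipeline assumes.

Every input the measurement pipeline consumes can be generated here from a
known ground truth, so each stage (linking, velocity and turnover
estimation, profile reconstruction, global fitting, invasion timing,
segmentation) is testable end-to-end without any external data.

Plus-end tracks are sampled from the exact stationary process implied by
the continuum steady state: births occur with intensity equal to the local
autocatalytic nucleation term (plus a centre atom representing the
anchored centrosomal flux), plus ends advect outward at v_p, and death is
position-dependent with hazard theta + lam * rho_opp / rho_tot — the
stationary plus-end density of this process is exactly the model profile.

All randomness flows through one seeded generator per call; the seed is
recorded on every output object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compartments import MassSeries, aster_mass
from .continuum import solve_pair, symmetric_pair_profile, stability_margin
from .exceptions import ConfigurationError, InvalidParameterError
from .params import Grid1D, ModelParams
from .tracking import Track
from .turnover import FrapCurve, LifetimeSample

__all__ = [
    "SynthConfig",
    "extract_like",
    "bead_like",
    "SyntheticTracks",
    "InvasionSynth",
    "Field2DSynth",
    "gen_profile_tracks",
    "gen_lifetimes",
    "gen_frap",
    "gen_invasion_series",
    "gen_multi_aster_field2d",
]


def extract_like() -> ModelParams:
    """Frog-extract-like unstable truth (alpha'/theta ~ 1.3).

    v_p = 10 µm/min and a ~5 min mean filament lifetime are typical of
    interphase extract asters; alpha is calibrated so that the effective
    autocatalytic ratio alpha'/theta sits at ~1.3, on the unstable side of
    the phase boundary, with a well-developed inter-aster interface.
    """
    return ModelParams(v_p=10.0, alpha=0.554, theta=0.2, lam=1.0,
                       rho_s=1.0, rho_c=0.5)


def bead_like() -> ModelParams:
    """AurkA-bead / Drosophila-like stable truth (alpha'/theta ~ 0.6).

    Same dynamics but with reduced autocatalytic nucleation, giving
    centre-peaked decaying profiles and a stable boundary.
    """
    return ModelParams(v_p=10.0, alpha=0.147, theta=0.2, lam=1.0,
                       rho_s=1.0, rho_c=0.5)


@dataclass(frozen=True)
class SynthConfig:
    """Ground truth and acquisition parameters for synthetic data.

    Acquisition defaults mirror typical plus-end imaging: frames 3 s apart
    (0.05 min), ~30 nm localization noise, a 20 µm strip along the
    inter-aster axis, and a ~200 µm axis span.
    """

    truth: ModelParams = field(default_factory=extract_like)
    L: float = 200.0
    nx: int = 256
    strip_width: float = 20.0
    n_tracks: int = 500
    frames: int = 60
    frame_dt: float = 0.05
    loc_sigma: float = 0.03      # localization noise, µm
    speed_sigma: float = 0.5     # per-step velocity jitter, µm/min
    profile_noise: float = 0.05  # multiplicative profile noise
    frap_sigma: float = 0.05
    n_lifetimes: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_tracks < 1 or self.frames < 2 or self.n_lifetimes < 1:
            raise InvalidParameterError("counts must be positive")
        for name in ("loc_sigma", "speed_sigma", "profile_noise",
                     "frap_sigma"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass
class SyntheticTracks:
    """Per-frame detections plus the ground truth that generated them."""

    detections: list          # [(t, points (n, 2), true ids (n,))]
    tracks: list              # ground-truth Track objects (>= 2 samples)
    grid: Grid1D
    rho: np.ndarray           # (2, nx) stationary truth profiles
    config: SynthConfig
    seed: int
    owner: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def expected_counts(self, edges: np.ndarray, aster: int) -> np.ndarray:
        """Expected per-bin detection counts for one aster, normalized to
        the observed total — the chi-square reference for closure tests."""
        dens = np.interp(0.5 * (edges[:-1] + edges[1:]), self.grid.x,
                         self.rho[aster - 1])
        total = sum(int((self.owner[ids] == aster).sum())
                    for _, _, ids in self.detections if len(ids))
        return dens / dens.sum() * total


def _sample_positions(rng, n, x, dens, atom_x, atom_w):
    """Sample n positions from density ``dens`` plus an atom at atom_x."""
    total_cont = np.trapezoid(dens, x)
    p_atom = atom_w / (atom_w + total_cont)
    from_atom = rng.random(n) < p_atom
    out = np.full(n, atom_x, dtype=float)
    n_cont = int((~from_atom).sum())
    if n_cont:
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(x))])
        cdf /= cdf[-1]
        out[~from_atom] = np.interp(rng.random(n_cont), cdf, x)
    return out


def gen_profile_tracks(cfg: SynthConfig, seed: int | None = None
                       ) -> SyntheticTracks:
    """Synthetic plus-end comet movie over the inter-aster axis.

    Birth positions follow the autocatalytic-nucleation intensity of the
    two-aster steady state (with a centre atom for the anchored
    centrosomal flux); plus ends advect outward at v_p with per-step
    velocity jitter and die with the position-dependent hazard
    theta + lam rho_opp / rho_tot, so the stationary detection density
    equals the model profile.  Detections carry localization noise and
    ground-truth identities for linker scoring.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    p = cfg.truth
    grid = Grid1D(cfg.L, cfg.nx)
    rho1, rho2 = symmetric_pair_profile(p, grid)
    tot = rho1 + rho2
    x = grid.x

    t_end = (cfg.frames - 1) * cfg.frame_dt
    burn = 6.0 / p.theta
    # per-aster birth intensities (per min): interior + centre atom
    sat = 1.0 + tot / p.rho_s
    b = [p.alpha * rho1 / sat, p.alpha * rho2 / sat]
    atoms = [p.v_p * rho1[0], p.v_p * rho2[-1]]
    atom_x = [x[0], x[-1]]
    B = [float(np.trapezoid(b[i], x) + atoms[i]) for i in (0, 1)]

    with np.errstate(invalid="ignore", divide="ignore"):
        hazard = [np.where(tot > 0, p.theta + p.lam * rho2 / tot, p.theta),
                  np.where(tot > 0, p.theta + p.lam * rho1 / tot, p.theta)]
    # cumulative hazard along x (len nx, aligned with x) so that the
    # survival over a travelled path is exp(-|H(x1) - H(x0)| / v_p)
    cumhaz = [np.concatenate([[0.0], np.cumsum(
        0.5 * (h[1:] + h[:-1]) * np.diff(x))]) for h in hazard]

    def _path_hazard(a, x_from, x_to):
        c0, c1 = np.interp([x_from, x_to], x, cumhaz[a])
        return abs(c1 - c0) / p.v_p

    # exact stationary density of the continuous birth-transport-death
    # process (integrating-factor solution of v_p rho' = b - mu rho with
    # rho(0) = anchor flux / v_p); this, not the discrete grid solution,
    # is the generator's own ground truth
    from scipy.integrate import cumulative_trapezoid

    efac = np.exp(cumhaz[0] / p.v_p)
    integ = cumulative_trapezoid(b[0] * efac, x, initial=0.0) / p.v_p
    rho1_cont = (rho1[0] + integ) / efac
    rho_cont = np.stack([rho1_cont, rho1_cont[::-1]])

    # target ~n_tracks tracks visible in the window; the mean track
    # lifetime reflects the density-weighted hazard (inhibition included)
    theta_eff = float(
        np.trapezoid(hazard[0] * rho1 + hazard[1] * rho2, x)
        / np.trapezoid(rho1 + rho2, x))
    rate = cfg.n_tracks / (t_end + 1.0 / theta_eff)
    n_births = rng.poisson(rate * (burn + t_end))
    aster = (rng.random(n_births) < B[1] / (B[0] + B[1])).astype(int)
    births = rng.uniform(-burn, t_end, n_births)
    frame_times = np.arange(cfg.frames) * cfg.frame_dt

    det_t, det_xy, det_id = [[] for _ in range(cfg.frames)], \
        [[] for _ in range(cfg.frames)], [[] for _ in range(cfg.frames)]
    raw_tracks = {}
    owners = {}
    for k in range(n_births):
        a = aster[k]
        sgn = 1.0 if a == 0 else -1.0
        dens = b[a]
        x0 = float(_sample_positions(rng, 1, x, dens, atom_x[a], atoms[a])[0])
        y0 = rng.uniform(0.0, cfg.strip_width)
        tb = births[k]
        # advance to the first frame after birth at the nominal velocity
        j0 = int(np.searchsorted(frame_times, tb))
        if j0 >= cfg.frames:
            continue
        pos = x0 + sgn * p.v_p * (frame_times[j0] - tb)
        # path-integrated survival from birth to the first visible frame
        if pos < 0.0 or pos > cfg.L:
            continue
        if rng.random() >= math.exp(-_path_hazard(a, x0, pos)):
            continue
        samples = []
        for j in range(j0, cfg.frames):
            if pos < 0.0 or pos > cfg.L:
                break
            if j > j0:
                mu = float(np.interp(pos, x, hazard[a]))
                if rng.random() >= math.exp(-mu * cfg.frame_dt):
                    break
            samples.append((frame_times[j], pos, y0))
            v = p.v_p + rng.normal(0.0, cfg.speed_sigma)
            pos = pos + sgn * v * cfg.frame_dt
        if not samples:
            continue
        owners[k] = a + 1
        raw_tracks[k] = samples
        for (tt, xx, yy) in samples:
            j = int(round(tt / cfg.frame_dt))
            det_t[j].append(tt)
            det_xy[j].append((xx + rng.normal(0, cfg.loc_sigma),
                              yy + rng.normal(0, cfg.loc_sigma)))
            det_id[j].append(k)

    detections = []
    owner_arr = np.full(max(raw_tracks, default=0) + 1, 0, dtype=int)
    for k, a in owners.items():
        owner_arr[k] = a
    for j in range(cfg.frames):
        pts = np.array(det_xy[j]).reshape(-1, 2)
        detections.append((frame_times[j], pts,
                           np.array(det_id[j], dtype=int)))
    tracks = []
    for k, samples in raw_tracks.items():
        if len(samples) >= 2:
            arr = np.array(samples)
            # noisy coordinates for the returned ground-truth tracks too
            xn = arr[:, 1] + rng.normal(0, cfg.loc_sigma, len(arr))
            yn = arr[:, 2] + rng.normal(0, cfg.loc_sigma, len(arr))
            tracks.append(Track(k, arr[:, 0], xn, yn, aster_id=owners[k]))
    return SyntheticTracks(detections=detections, tracks=tracks, grid=grid,
                           rho=rho_cont, config=cfg, seed=seed,
                           owner=owner_arr)


def gen_lifetimes(theta: float, n: int, t_obs: float = math.inf,
                  seed: int = 0) -> LifetimeSample:
    """Exponential filament lifetimes right-censored at ``t_obs``."""
    if theta <= 0:
        raise InvalidParameterError("theta must be > 0")
    rng = np.random.default_rng(seed)
    raw = rng.exponential(1.0 / theta, size=n)
    censored = raw > t_obs
    durations = np.minimum(raw, t_obs)
    return LifetimeSample(durations=durations, censored=censored,
                          t_obs=t_obs)


def gen_frap(theta: float, amplitude: float = 1.0, sigma: float = 0.05,
             times: np.ndarray | None = None, seed: int = 0) -> FrapCurve:
    """Noisy single-exponential recovery A (1 - exp(-theta t))."""
    if theta <= 0:
        raise InvalidParameterError("theta must be > 0")
    if times is None:
        t_half = math.log(2) / theta
        times = np.linspace(0.0, 6 * t_half, 50)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    y = amplitude * (1.0 - np.exp(-theta * times))
    return FrapCurve(times=times, recovery=y + rng.normal(0, sigma,
                                                          len(times)))


@dataclass
class InvasionSynth:
    """Noisy invasion movie: per-frame profiles and extracted masses."""

    mass_series: MassSeries
    times: np.ndarray
    profiles: np.ndarray       # (nt, 2, nx) noisy density movie
    grid: Grid1D
    truth: ModelParams
    dM_frac: float
    stable_truth: bool
    seed: int


def gen_invasion_series(truth: ModelParams, dM_frac: float,
                        noise: float = 0.05, seed: int = 0,
                        grid: Grid1D | None = None, t_max: float = 240.0,
                        frame_dt: float = 2.0) -> InvasionSynth:
    """Invasion movie from a perturbed symmetric steady interface.

    The pair dynamics is solved from the steady state with masses
    perturbed by ``±dM_frac/2``; per-frame profiles carry multiplicative
    noise and per-aster masses are extracted by trapezoidal integration.
    For a stable truth the output is flagged (no invasion expected)
    rather than raising.
    """
    grid = grid or Grid1D(200.0, 128)
    rng = np.random.default_rng(seed)
    stable = stability_margin(truth, grid=grid).stable
    rho1, rho2 = symmetric_pair_profile(truth, grid)
    init = np.stack([rho1 * (1 + dM_frac / 2), rho2 * (1 - dM_frac / 2)])
    nsteps_per_frame = max(1, int(round(
        frame_dt / (0.5 * grid.dx / truth.v_p))))
    traj = solve_pair(truth, (init[0], init[1]), grid, T=t_max,
                      save_every=nsteps_per_frame)
    movie = traj.rho * (1.0 + noise * rng.standard_normal(traj.rho.shape))
    movie = np.clip(movie, 0.0, None)
    masses = np.stack([
        [aster_mass(movie[k, i], dx=grid.dx) for i in (0, 1)]
        for k in range(movie.shape[0])])
    return InvasionSynth(
        mass_series=MassSeries(times=traj.t, masses=masses),
        times=traj.t, profiles=movie, grid=grid, truth=truth,
        dM_frac=dM_frac, stable_truth=stable, seed=seed)


@dataclass
class Field2DSynth:
    """Synthetic multi-aster field movie for segmentation analyses."""

    times: np.ndarray
    frames: np.ndarray          # (nt, ny, nx)
    seeds_rc: np.ndarray        # (N, 2) aster centres, (row, col) pixels
    amplitudes: np.ndarray      # (nt, N)
    pixel_size: float
    seed: int


def gen_multi_aster_field2d(N: int, size: tuple[int, int],
                            truth: ModelParams, seed: int = 0,
                            T: float = 120.0, frame_dt: float = 2.0,
                            T_cc: float | None = None,
                            reset_fraction: float = 0.05,
                            pixel_size: float = 2.0,
                            min_spacing_px: float | None = None
                            ) -> Field2DSynth:
    """2D field of N competing radial asters at random centres.

    Aster amplitudes follow a competitive growth law derived from the
    truth parameters: growth at rate alpha - theta saturating at a shared
    carrying capacity, with overlap-weighted competition that is
    winner-take-all for an unstable truth (coarsening) and coexisting for
    a stable one.  Optional cycling resets (``T_cc``) knock amplitudes
    down by ``reset_fraction`` each cycle.  Frames are sums of Gaussian
    kernels; the aster centres are returned as watershed seeds.
    """
    if N < 2:
        raise InvalidParameterError("need N >= 2 asters")
    ny, nx = size
    rng = np.random.default_rng(seed)
    spacing = min_spacing_px or 0.35 * min(ny, nx) / math.sqrt(N)
    centres = []
    for _ in range(5000):
        cand = rng.uniform([0.15 * ny, 0.15 * nx], [0.85 * ny, 0.85 * nx])
        if all(np.hypot(*(cand - c)) >= spacing for c in centres):
            centres.append(cand)
        if len(centres) == N:
            break
    else:
        raise ConfigurationError(
            f"could not place {N} centres with spacing {spacing:.1f}px")
    centres = np.array(centres)

    margin = truth.alpha - truth.theta
    g = max(abs(margin), 0.05)
    # winner-take-all requires beta * w(nearest) > 1 (Lotka-Volterra
    # exclusion); a stable truth coexists
    beta = 4.0 if margin > 0 else 0.5
    # narrow enough that a density saddle separates the closest pair
    s_kernel = 0.4 * spacing
    yy, xx = np.mgrid[0:ny, 0:nx]
    kernels = np.stack([
        np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * s_kernel ** 2))
        for r, c in centres])
    d2 = ((centres[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2 * spacing ** 2))
    np.fill_diagonal(w, 0.0)

    A = 0.5 + 0.05 * rng.standard_normal(N)
    dt = 0.5
    steps = int(round(T / dt))
    frame_every = max(1, int(round(frame_dt / dt)))
    times, frames, amps = [], [], []
    next_reset = T_cc if T_cc else math.inf
    for s in range(steps + 1):
        t = s * dt
        if s % frame_every == 0:
            times.append(t)
            frames.append((A[:, None, None] * kernels).sum(axis=0))
            amps.append(A.copy())
        comp = A + beta * (w @ A)
        A = A + dt * g * A * (1.0 - comp)
        A = np.clip(A, 0.0, None)
        A[A < 0.02] = 0.0
        if t >= next_reset:
            A = A * reset_fraction + 0.02 * (A > 0)
            next_reset += T_cc
    return Field2DSynth(times=np.array(times), frames=np.array(frames),
                        seeds_rc=centres, amplitudes=np.array(amps),
                        pixel_size=pixel_size, seed=seed)
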