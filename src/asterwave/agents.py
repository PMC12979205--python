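"""Stochastic agent-based simulation of two branching microtubule asters.

Two asters nucleate from centrosome points on the midline of a rectangular
slab.  Filaments are straight segments that elongate at the plus end with
velocity v_p, disappear as whole filaments at rate theta (matching the
continuum turnover term and the speckle-lifetime observable), and nucleate
new filaments in two ways: centrosomal nucleation at rate k_nuc per aster,
and autocatalytic branching at rate k_branch per µm of existing polymer,
throttled by a finite nucleator pool (each alive filament sequesters one
nucleator, released on death — the microscopic analogue of the saturation
density rho_s).  Branches start on a length-weighted random filament with
a direction drawn Normal(0, sigma_branch) degrees about the parent.
Filaments whose plus end comes within d_inh of an antiparallel filament
of the other aster are "inhibited": their turnover is multiplied by f_inh
(and optionally their growth arrested), the microscopic counterpart of the
continuum mutual-inhibition term.  Plus ends clamp at the slab walls.

All randomness flows from one seeded generator, so runs are bit-identical
given (config, T).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ConfigurationError, InvalidParameterError
from .profiles import DensityProfile

__all__ = [
    "AgentConfig",
    "FilamentSet",
    "AgentRun",
    "run_agents",
    "plus_end_positions",
    "project_density_1d",
    "radial_plus_end_profile",
]


@dataclass(frozen=True)
class AgentConfig:
    """Parameters of the slab agent simulation (µm, min units)."""

    v_p: float = 10.0
    theta: float = 1.0
    k_nuc: float = 50.0          # centrosomal nucleations / min / aster
    k_branch: float = 0.0        # branch nucleations / µm polymer / min
    n_nucleators: int = 100000   # pool size per aster
    sigma_branch: float = 10.0   # branch-angle st.dev., degrees
    d_inh: float = 0.0           # antiparallel interaction distance, µm
    f_inh: float = 1.0           # turnover multiplier when inhibited
    arrest_inhibited: bool = False
    slab: tuple[float, float, float] = (300.0, 120.0, 10.0)
    separation: float = 150.0    # centrosome separation along x, µm
    dt: float = 0.1
    seed: int = 0
    max_filaments: int = 500_000

    def __post_init__(self):
        for name in ("v_p", "theta", "k_nuc", "k_branch", "sigma_branch",
                     "d_inh", "dt"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.f_inh < 1:
            raise InvalidParameterError("f_inh must be >= 1")
        if any(s <= 0 for s in self.slab):
            raise InvalidParameterError("slab dimensions must be > 0")
        if self.n_nucleators < 1:
            raise InvalidParameterError("n_nucleators must be >= 1")

    @property
    def centrosomes(self) -> np.ndarray:
        """Two centrosome points on the slab midline, (2, 3)."""
        lx, ly, lz = self.slab
        cx = lx / 2.0
        half = self.separation / 2.0
        if half >= cx:
            raise ConfigurationError("separation exceeds the slab length")
        return np.array([[cx - half, ly / 2, lz / 2],
                         [cx + half, ly / 2, lz / 2]])


@dataclass
class FilamentSet:
    """Snapshot of the filament population (alive filaments only)."""

    t: float
    origin: np.ndarray        # (n, 3)
    direction: np.ndarray     # (n, 3), unit norm
    birth_t: np.ndarray       # (n,)
    length: np.ndarray        # (n,)
    aster_id: np.ndarray      # (n,), values 1 or 2
    inhibited: np.ndarray     # (n,), bool
    arrested: np.ndarray      # (n,), bool (clamped at a wall)

    def __len__(self):
        return len(self.length)

    @property
    def plus_ends(self) -> np.ndarray:
        return self.origin + self.direction * self.length[:, None]

    def to_frame(self):
        import pandas as pd

        pe = self.plus_ends
        return pd.DataFrame({
            "aster_id": self.aster_id,
            "ox_um": self.origin[:, 0], "oy_um": self.origin[:, 1],
            "oz_um": self.origin[:, 2],
            "dx": self.direction[:, 0], "dy": self.direction[:, 1],
            "dz": self.direction[:, 2],
            "length_um": self.length, "birth_t_min": self.birth_t,
            "px_um": pe[:, 0], "py_um": pe[:, 1], "pz_um": pe[:, 2],
            "inhibited": self.inhibited.astype(int),
        })


@dataclass
class AgentRun:
    config: AgentConfig
    times: np.ndarray
    snapshots: list = field(default_factory=list)
    truncated: bool = False

    def counts(self) -> np.ndarray:
        """Alive filaments per aster per snapshot, shape (nt, 2)."""
        return np.array([[(s.aster_id == 1).sum(), (s.aster_id == 2).sum()]
                         for s in self.snapshots])


class _Population:
    """Growable struct-of-arrays filament store."""

    def __init__(self):
        self.origin = np.empty((0, 3))
        self.direction = np.empty((0, 3))
        self.birth_t = np.empty(0)
        self.length = np.empty(0)
        self.aster = np.empty(0, dtype=np.int8)
        self.inhibited = np.empty(0, dtype=bool)
        self.arrested = np.empty(0, dtype=bool)

    def __len__(self):
        return len(self.length)

    def add(self, origin, direction, t, aster):
        n = len(origin)
        if n == 0:
            return
        self.origin = np.vstack([self.origin, origin])
        self.direction = np.vstack([self.direction, direction])
        self.birth_t = np.concatenate([self.birth_t, np.full(n, t)])
        self.length = np.concatenate([self.length, np.zeros(n)])
        self.aster = np.concatenate(
            [self.aster, np.full(n, aster, dtype=np.int8)])
        self.inhibited = np.concatenate([self.inhibited, np.zeros(n, bool)])
        self.arrested = np.concatenate([self.arrested, np.zeros(n, bool)])

    def keep(self, mask):
        self.origin = self.origin[mask]
        self.direction = self.direction[mask]
        self.birth_t = self.birth_t[mask]
        self.length = self.length[mask]
        self.aster = self.aster[mask]
        self.inhibited = self.inhibited[mask]
        self.arrested = self.arrested[mask]

    def snapshot(self, t) -> FilamentSet:
        return FilamentSet(
            t=t, origin=self.origin.copy(), direction=self.direction.copy(),
            birth_t=self.birth_t.copy(), length=self.length.copy(),
            aster_id=self.aster.astype(int).copy(),
            inhibited=self.inhibited.copy(), arrested=self.arrested.copy())


def _in_plane_dirs(rng, n):
    phi = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])


def _clamp_to_slab(pop: _Population, slab):
    """Clamp plus ends at the slab walls (growth arrest)."""
    pe = pop.origin + pop.direction * pop.length[:, None]
    lims = np.array(slab)
    over = (pe < 0) | (pe > lims)
    hit = over.any(axis=1)
    if not hit.any():
        return
    for i in np.flatnonzero(hit):
        d = pop.direction[i]
        o = pop.origin[i]
        lmax = pop.length[i]
        for ax in range(3):
            if d[ax] > 1e-12:
                lmax = min(lmax, (lims[ax] - o[ax]) / d[ax])
            elif d[ax] < -1e-12:
                lmax = min(lmax, -o[ax] / d[ax])
        pop.length[i] = max(lmax, 0.0)
        pop.arrested[i] = True


def _mark_inhibited(pop: _Population, d_inh: float):
    """Antiparallel-proximity test between the plus ends of one aster and
    the filament bodies of the other (bodies sampled at d_inh spacing)."""
    pop.inhibited[:] = False
    if d_inh <= 0 or len(pop) == 0:
        return
    pe = pop.origin + pop.direction * pop.length[:, None]
    for me, other in ((1, 2), (2, 1)):
        mine = np.flatnonzero(pop.aster == me)
        theirs = np.flatnonzero(pop.aster == other)
        if len(mine) == 0 or len(theirs) == 0:
            continue
        # sample points along the opposing filaments
        pts = []
        owners = []
        for j in theirs:
            npts = max(int(pop.length[j] / d_inh) + 1, 2)
            frac = np.linspace(0.0, 1.0, npts)
            pts.append(pop.origin[j]
                       + np.outer(frac * pop.length[j], pop.direction[j]))
            owners.append(np.full(npts, j))
        pts = np.vstack(pts)
        owners = np.concatenate(owners)
        tree = cKDTree(pts)
        for i in mine:
            for k in tree.query_ball_point(pe[i], d_inh):
                j = owners[k]
                if np.dot(pop.direction[i], pop.direction[j]) < 0:
                    pop.inhibited[i] = True
                    break


def run_agents(config: AgentConfig, T: float,
               sample_every: float | None = None) -> AgentRun:
    """Run the slab simulation for ``T`` minutes.

    Snapshots of the alive filament population are stored every
    ``sample_every`` minutes (default: 20 samples over the run).  If the
    population exceeds ``config.max_filaments`` the run stops gracefully
    and returns the snapshots collected so far (``truncated`` flag set).
    """
    rng = np.random.default_rng(config.seed)
    cfg = config
    pop = _Population()
    centros = cfg.centrosomes
    sample_every = sample_every or max(T / 20.0, cfg.dt)
    sample_steps = max(1, int(round(sample_every / cfg.dt)))
    nsteps = int(round(T / cfg.dt))
    times = [0.0]
    snaps = [pop.snapshot(0.0)]
    truncated = False
    for step in range(1, nsteps + 1):
        t = step * cfg.dt
        # (i) elongation
        grow = ~pop.arrested
        if cfg.arrest_inhibited:
            grow &= ~pop.inhibited
        pop.length[grow] += cfg.v_p * cfg.dt
        _clamp_to_slab(pop, cfg.slab)
        # (ii) whole-filament death
        rate = np.where(pop.inhibited, cfg.theta * cfg.f_inh, cfg.theta)
        die = rng.random(len(pop)) < -np.expm1(-rate * cfg.dt)
        pop.keep(~die)
        # (iii) centrosomal nucleation
        for a in (1, 2):
            n_new = rng.poisson(cfg.k_nuc * cfg.dt)
            if n_new:
                pop.add(np.tile(centros[a - 1], (n_new, 1)),
                        _in_plane_dirs(rng, n_new), t, a)
        # (iv) autocatalytic branching, throttled by the nucleator pool
        for a in (1, 2):
            sel = pop.aster == a
            bound = min(int(sel.sum()), cfg.n_nucleators)
            free_frac = (cfg.n_nucleators - bound) / cfg.n_nucleators
            total_len = float(pop.length[sel].sum())
            lam = cfg.k_branch * cfg.dt * total_len * free_frac
            n_new = rng.poisson(lam) if lam > 0 else 0
            if n_new:
                idx = np.flatnonzero(sel)
                w = pop.length[idx]
                parents = rng.choice(idx, size=n_new, p=w / w.sum())
                frac = rng.random(n_new)
                origins = (pop.origin[parents] + pop.direction[parents]
                           * (frac * pop.length[parents])[:, None])
                ang = np.deg2rad(
                    rng.normal(0.0, cfg.sigma_branch, n_new))
                pd = pop.direction[parents]
                cos, sin = np.cos(ang), np.sin(ang)
                dirs = np.column_stack([
                    cos * pd[:, 0] - sin * pd[:, 1],
                    sin * pd[:, 0] + cos * pd[:, 1],
                    np.zeros(n_new)])
                pop.add(origins, dirs, t, a)
        # (v) antiparallel inhibition marking
        _mark_inhibited(pop, cfg.d_inh)
        if len(pop) > cfg.max_filaments:
            truncated = True
            times.append(t)
            snaps.append(pop.snapshot(t))
            break
        if step % sample_steps == 0:
            times.append(t)
            snaps.append(pop.snapshot(t))
    return AgentRun(config=cfg, times=np.array(times), snapshots=snaps,
                    truncated=truncated)


def plus_end_positions(snapshot: FilamentSet
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Labelled plus-end point set: (points (n, 3), aster ids (n,))."""
    return snapshot.plus_ends, snapshot.aster_id


def project_density_1d(points: np.ndarray, aster_ids: np.ndarray,
                       axis, binwidth: float) -> DensityProfile:
    """Per-aster plus-end density along an axis.

    Points are projected onto the segment ``axis = (start, end)`` (3D or
    2D) and binned into half-open bins of ``binwidth`` µm; densities are
    counts per unit length.
    """
    start = np.asarray(axis[0], dtype=float)
    end = np.asarray(axis[1], dtype=float)
    span = float(np.linalg.norm(end - start))
    if span <= 0:
        raise ConfigurationError("degenerate projection axis")
    if binwidth <= 0:
        raise ConfigurationError("binwidth must be > 0")
    u = (end - start) / span
    pts = np.asarray(points, dtype=float)
    if pts.shape[1] != len(start):
        raise ConfigurationError("points and axis dimensionality differ")
    s = (pts - start) @ u
    nbins = int(np.ceil(span / binwidth))
    edges = np.arange(nbins + 1) * binwidth
    rho = []
    counts = []
    for a in (1, 2):
        sel = (aster_ids == a) & (s >= 0) & (s < edges[-1])
        c, _ = np.histogram(s[sel], bins=edges)
        counts.append(c.astype(float))
        rho.append(c / binwidth)
    return DensityProfile(x=0.5 * (edges[:-1] + edges[1:]),
                          rho1=rho[0], rho2=rho[1],
                          sem1=np.sqrt(counts[0]) / binwidth,
                          sem2=np.sqrt(counts[1]) / binwidth,
                          counts1=counts[0], counts2=counts[1])


def radial_plus_end_profile(run: AgentRun, aster: int, binwidth: float,
                            r_max: float, burn_in: float = 0.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Plus-end density per unit radius around one aster's centrosome.

    Pools all snapshots with t >= ``burn_in`` and divides by the number of
    pooled snapshots, so the result estimates the stationary density per
    unit radial distance — directly comparable to the 1D continuum steady
    profile of a single aster.  Returns (bin centres, density).
    """
    centre = run.config.centrosomes[aster - 1]
    edges = np.arange(0.0, r_max + binwidth, binwidth)
    acc = np.zeros(len(edges) - 1)
    n = 0
    for snap in run.snapshots:
        if snap.t < burn_in or len(snap) == 0:
            continue
        sel = snap.aster_id == aster
        r = np.linalg.norm(snap.plus_ends[sel] - centre, axis=1)
        acc += np.histogram(r, bins=edges)[0]
        n += 1
    if n == 0:
        raise InvalidParameterError("no snapshots after burn-in")
    return 0.5 * (edges[:-1] + edges[1:]), acc / (n * binwidth)
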