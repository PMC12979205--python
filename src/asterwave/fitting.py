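"""Global fitting of the continuum model to density profiles.

`ProfileFitModel` fits the mirror-symmetric steady state of the two-aster
continuum model to one or more replicate density profiles simultaneously.
The polymerization velocity v_p and turnover theta are measured
independently (tracking, lifetimes, FRAP) and held fixed; the fit shares
the autocatalytic rate alpha, the inhibition strength lam and the
saturation density rho_s across replicates while giving each replicate its
own centre amplitude rho_c (profiles come in arbitrary intensity units).

The fitted parameter set maps onto the stability phase diagram through the
effective autocatalytic rate alpha' = alpha / (1 + 2 rho_int / rho_s),
with rho_int read off the fitted steady interface; bootstrap resampling of
whole replicates gives the 95% confidence ellipse of the (theta, alpha')
placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import least_squares
from scipy.stats import chi2

from .continuum import (
    effective_autocatalysis,
    rho_intersection,
    symmetric_pair_profile,
)
from .exceptions import FitFailureError, InvalidParameterError
from .params import Grid1D, ModelParams

__all__ = [
    "ProfileFitModel",
    "ProfileFitResults",
    "PhaseEllipse",
    "fit_profiles_global",
    "bootstrap_phase",
    "predict_param_shift",
]


@dataclass(frozen=True)
class PhaseEllipse:
    """95% confidence ellipse of the mean phase-diagram placement."""

    mean: tuple[float, float]          # (theta, alpha_eff)
    cov: np.ndarray                    # 2x2 bootstrap covariance
    axes: tuple[float, float]          # 95% semi-axis lengths
    angle: float                       # orientation of the major axis, rad
    points: np.ndarray                 # (B, 2) bootstrap placements
    frac_stable: float
    n_failed: int = 0
    warning: str | None = None

    @property
    def area(self) -> float:
        return float(np.pi * self.axes[0] * self.axes[1])

    @property
    def margin(self) -> float:
        """alpha_eff - theta of the bootstrap mean (< 0 means stable)."""
        return self.mean[1] - self.mean[0]


class _SteadyCache:
    """Warm-started steady-state evaluations keyed per replicate."""

    def __init__(self, grid: Grid1D):
        self.grid = grid
        self.last: dict[int, np.ndarray] = {}

    def profile(self, params: ModelParams, key: int) -> np.ndarray:
        init = self.last.get(key)
        if init is not None and init.shape != (2, self.grid.nx):
            init = None
        rho1, rho2 = symmetric_pair_profile(
            params, self.grid, tol=1e-7, t_max=3000.0, init=init)
        self.last[key] = np.stack([rho1, rho2])
        return self.last[key]


class ProfileFitModel:
    """Weighted global nonlinear least squares on replicate profiles.

    Parameters
    ----------
    profiles : sequence of :class:`~asterwave.profiles.DensityProfile`
        Replicate profiles over a common axis span.
    v_p, theta : float
        Independently measured polymerization velocity (µm/min) and
        turnover rate (1/min), held fixed during the fit.
    grid : Grid1D, optional
        Internal solver grid; defaults to 96 cells over the profile span.
    """

    def __init__(self, profiles, v_p: float, theta: float,
                 grid: Grid1D | None = None):
        if len(profiles) < 1:
            raise InvalidParameterError("need at least one profile")
        self.profiles = list(profiles)
        self.v_p = float(v_p)
        self.theta = float(theta)
        span = self.profiles[0].span
        self.grid = grid or Grid1D(span, 96)
        self._cache = _SteadyCache(self.grid)
        # per-replicate weights: 1/sem with a floor to avoid empty-bin blowup
        self._weights = []
        for p in self.profiles:
            w = []
            for sem, rho in ((p.sem1, p.rho1), (p.sem2, p.rho2)):
                if sem is None:
                    w.append(np.ones_like(rho))
                else:
                    pos = sem[sem > 0]
                    floor = np.median(pos) if len(pos) else 1.0
                    w.append(1.0 / np.maximum(sem, floor * 0.5))
            self._weights.append(np.stack(w))

    # -- residuals -------------------------------------------------------

    def _params_from_vector(self, logp: np.ndarray, r: int) -> ModelParams:
        alpha, lam, rho_s = np.exp(logp[:3])
        rho_c = float(np.exp(logp[3 + r]))
        return ModelParams(v_p=self.v_p, alpha=alpha, theta=self.theta,
                           lam=lam, rho_s=rho_s, rho_c=rho_c)

    def _residuals(self, logp: np.ndarray) -> np.ndarray:
        out = []
        for r, prof in enumerate(self.profiles):
            try:
                pr = self._params_from_vector(logp, r)
                rho = self._cache.profile(pr, r)
            except Exception:
                # a pathological parameter set: keep the optimizer moving
                return np.full(self._n_resid, 1e6)
            m1 = np.interp(prof.x, self.grid.x, rho[0])
            m2 = np.interp(prof.x, self.grid.x, rho[1])
            w = self._weights[r]
            out.append((m1 - prof.rho1) * w[0])
            out.append((m2 - prof.rho2) * w[1])
        return np.concatenate(out)

    @property
    def _n_resid(self) -> int:
        return sum(2 * len(p.x) for p in self.profiles)

    def _starts(self, n_starts: int, seed: int) -> list[np.ndarray]:
        """Log-spaced alpha starts; rho_s seeded from the plateau relation
        rho* = rho_s (alpha/theta - 1) so each start lies near the ridge of
        the (alpha, rho_s) trade-off rather than far off the data scale."""
        rng = np.random.default_rng(seed)
        scale = max(max(p.rho1.max(), p.rho2.max()) for p in self.profiles)
        scale = max(scale, 1e-6)
        rc0 = np.log([max(p.rho1[0], scale * 0.1) for p in self.profiles])
        alphas = self.theta * np.geomspace(0.7, 8.0, n_starts)
        starts = []
        for k, alpha in enumerate(alphas):
            excess = alpha / self.theta - 1.0
            if excess > 0.3:
                rho_s = scale / excess
            else:
                rho_s = scale * 2.0
            lam = 2.0 * self.theta * 10 ** rng.uniform(-0.2, 0.5)
            starts.append(np.concatenate(
                [np.log([alpha, lam, rho_s]), rc0]))
        return starts

    # -- fit -------------------------------------------------------------

    def fit(self, n_starts: int = 8, seed: int = 0,
            x0: np.ndarray | None = None, xtol: float = 1e-8
            ) -> "ProfileFitResults":
        """Run the multi-start optimization and return the best solution.

        ``x0`` (log-parameter vector) bypasses the multi-start schedule —
        used for warm-started bootstrap refits.
        """
        starts = ([np.asarray(x0, dtype=float)] if x0 is not None
                  else self._starts(n_starts, seed))
        best = None
        failures = []
        for s in starts:
            try:
                # diff_step well above the steady-solver tolerance so the
                # finite-difference Jacobian is not drowned in solver noise
                sol = least_squares(self._residuals, s, method="trf",
                                    xtol=xtol, diff_step=1e-3, max_nfev=400)
            except Exception as err:  # pragma: no cover - defensive
                failures.append(str(err))
                continue
            if not np.all(np.isfinite(sol.x)):
                failures.append("non-finite solution")
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailureError("all optimizer starts failed",
                                  diagnostics={"failures": failures})
        return ProfileFitResults(self, best)


class ProfileFitResults:
    """Estimates, uncertainties and diagnostics of a global profile fit."""

    _shared = ("alpha", "lam", "rho_s")

    def __init__(self, model: ProfileFitModel, solution):
        self.model = model
        self._sol = solution
        self.logp = solution.x
        self.cost = float(solution.cost)
        nr = len(model.profiles)
        self.param_names = list(self._shared) + [
            f"rho_c[{r}]" for r in range(nr)]
        self.params = dict(zip(self.param_names, np.exp(self.logp)))
        self.nobs = model._n_resid
        self.df_resid = self.nobs - len(self.logp)
        self._cov = None

    # -- uncertainties ---------------------------------------------------

    @property
    def scale(self) -> float:
        """Residual variance estimate (weighted residuals)."""
        return 2.0 * self.cost / max(self.df_resid, 1)

    def cov_params(self) -> np.ndarray:
        """Parameter covariance from the Jacobian at the optimum.

        Delta-method transform of the log-space covariance, so the matrix
        is symmetric positive semi-definite on the natural scale.
        """
        if self._cov is None:
            J = self._sol.jac
            JtJ = J.T @ J
            try:
                cov_log = self.scale * linalg.pinvh(JtJ)
            except linalg.LinAlgError:  # pragma: no cover
                cov_log = np.full_like(JtJ, np.nan)
            d = np.exp(self.logp)
            self._cov = cov_log * np.outer(d, d)
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params()), 0, None))

    # -- derived quantities ----------------------------------------------

    def model_params(self, replicate: int = 0) -> ModelParams:
        return self.model._params_from_vector(self.logp, replicate)

    def mean_params(self) -> ModelParams:
        """Fitted parameters with the geometric-mean centre amplitude."""
        rc = float(np.exp(np.mean(self.logp[3:])))
        return ModelParams(v_p=self.model.v_p, alpha=self.params["alpha"],
                           theta=self.model.theta, lam=self.params["lam"],
                           rho_s=self.params["rho_s"], rho_c=rc)

    def fittedvalues(self, replicate: int = 0) -> tuple[np.ndarray, np.ndarray]:
        pr = self.model_params(replicate)
        rho = symmetric_pair_profile(pr, self.model.grid, tol=1e-7)
        x = self.model.profiles[replicate].x
        gx = self.model.grid.x
        return np.interp(x, gx, rho[0]), np.interp(x, gx, rho[1])

    def phase_point(self) -> tuple[float, float]:
        """(theta, alpha') placement on the stability phase diagram."""
        pr = self.mean_params()
        rho1, rho2 = symmetric_pair_profile(pr, self.model.grid, tol=1e-7)
        rho_int = rho_intersection(rho1, rho2, self.model.grid)
        a_eff = effective_autocatalysis(pr.alpha, rho_int, pr.rho_s)
        return self.model.theta, float(a_eff)

    def bootstrap_phase(self, B: int = 200, seed: int = 0) -> PhaseEllipse:
        return bootstrap_phase(self.model.profiles, self.model.v_p,
                               self.model.theta, B=B, seed=seed,
                               grid=self.model.grid, warm=self)

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Global profile fit (two-aster continuum steady state)",
            "=" * 56,
            f"replicates: {len(self.model.profiles)}   "
            f"observations: {self.nobs}   cost: {self.cost:.4g}",
            f"fixed: v_p = {self.model.v_p:g} um/min   "
            f"theta = {self.model.theta:g} 1/min",
            "-" * 56,
            f"{'param':<12}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(self.param_names,
                                 np.exp(self.logp), self.bse):
            lines.append(f"{name:<12}{est:>12.5g}{se:>12.3g}")
        th, ae = self.phase_point()
        verdict = "stable" if ae < th else "unstable"
        lines += [
            "-" * 56,
            f"alpha' = {ae:.4g} 1/min   margin alpha'-theta = "
            f"{ae - th:+.4g} 1/min   ({verdict})",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_profile_fit

        return plot_profile_fit(self, ax=ax)


def fit_profiles_global(profiles, v_p: float, theta: float,
                        n_starts: int = 8, seed: int = 0,
                        grid: Grid1D | None = None) -> ProfileFitResults:
    """Functional wrapper around :class:`ProfileFitModel`."""
    return ProfileFitModel(profiles, v_p, theta, grid=grid).fit(
        n_starts=n_starts, seed=seed)


def bootstrap_phase(profiles, v_p: float, theta: float, B: int = 200,
                    seed: int = 0, grid: Grid1D | None = None,
                    warm: ProfileFitResults | None = None,
                    max_fail_frac: float = 0.2) -> PhaseEllipse:
    """Bootstrap the (theta, alpha') phase placement over replicates.

    Whole replicate profiles are resampled with replacement (bins within a
    profile are spatially correlated, so the replicate is the exchangeable
    unit), the global fit is repeated for each resample (warm-started at
    the full-data optimum), and the 95% confidence ellipse of the mean
    placement is computed from the bootstrap covariance.
    """
    if len(profiles) < 3:
        raise InvalidParameterError("bootstrap needs >= 3 replicates")
    if B < 2:
        raise InvalidParameterError("B must be >= 2")
    rng = np.random.default_rng(seed)
    if warm is None:
        warm = ProfileFitModel(profiles, v_p, theta, grid=grid).fit(seed=seed)
    grid = warm.model.grid
    nr = len(profiles)
    pts = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, nr, size=nr)
        boot = [profiles[i] for i in idx]
        x0 = np.concatenate([warm.logp[:3], warm.logp[3 + idx]])
        try:
            res = ProfileFitModel(boot, v_p, theta, grid=grid).fit(x0=x0)
            pts.append(res.phase_point())
        except Exception:
            failed += 1
    if not pts:
        raise FitFailureError("all bootstrap refits failed")
    pts = np.asarray(pts)
    mean = pts.mean(axis=0)
    if len(pts) > 1:
        cov = np.cov(pts.T)
        cov = np.atleast_2d(cov)
        if cov.shape == (1, 1):  # theta fixed: degenerate in that direction
            cov = np.array([[0.0, 0.0], [0.0, float(cov[0, 0])]])
    else:
        cov = np.zeros((2, 2))
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0, None)
    k = chi2.ppf(0.95, df=2)
    axes = tuple(np.sqrt(k * evals[::-1]))
    angle = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
    warning = None
    if failed > max_fail_frac * B:
        warning = f"{failed}/{B} bootstrap refits failed"
    return PhaseEllipse(
        mean=(float(mean[0]), float(mean[1])), cov=cov, axes=axes,
        angle=angle, points=pts,
        frac_stable=float(np.mean(pts[:, 1] < pts[:, 0])),
        n_failed=failed, warning=warning,
    )


def predict_param_shift(dv_frac: float, params: ModelParams,
                        rule: str = "length") -> tuple[ModelParams, dict]:
    """Propagate a polymerization-velocity perturbation to (alpha, rho_s).

    A fractional change ``dv_frac`` of v_p rescales the mean filament
    length l = v_p/theta by (1 + dv_frac).  Under the default "length"
    rule the autocatalytic rate scales with l (branching happens per unit
    polymer) and the saturation density with 1/l (the same nucleator pool
    is exhausted at a lower plus-end density when filaments are longer);
    turnover and inhibition are unchanged.  Returns the shifted parameters
    and a metadata dict recording the applied scaling.
    """
    if dv_frac <= -1:
        raise InvalidParameterError("dv_frac must be > -1")
    f = 1.0 + dv_frac
    if rule == "length":
        shifted = params.replace(v_p=params.v_p * f, alpha=params.alpha * f,
                                 rho_s=params.rho_s / f)
        meta = {"rule": "length", "v_p": f, "alpha": f, "rho_s": 1.0 / f,
                "theta": 1.0, "lam": 1.0}
    elif rule == "velocity-only":
        shifted = params.replace(v_p=params.v_p * f)
        meta = {"rule": "velocity-only", "v_p": f, "alpha": 1.0,
                "rho_s": 1.0, "theta": 1.0, "lam": 1.0}
    else:
        raise InvalidParameterError(f"unknown scaling rule {rule!r}")
    return shifted, meta
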