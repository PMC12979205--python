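"""Core parameter containers: continuum model parameters, 1D grid, cycling.

Units are fixed throughout the package: lengths in µm, times in min,
densities in plus-ends/µm (an arbitrary intensity scale absorbed by the
centre amplitude ``rho_c``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import InvalidParameterError


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-aster continuum model.

    Attributes
    ----------
    v_p : float
        Polymerization (plus-end advection) velocity, µm/min.
    alpha : float
        Autocatalytic (branching) nucleation rate, 1/min.
    theta : float
        Whole-filament turnover rate, 1/min.
    lam : float
        Strength of the mutual inhibition between asters, 1/min.
    rho_s : float
        Saturation density set by nucleator depletion, plus-ends/µm.
    rho_c : float
        Density amplitude pinned at each aster's own centre
        (standing in for centrosomal nucleation), plus-ends/µm.
    """

    v_p: float
    alpha: float
    theta: float
    lam: float
    rho_s: float
    rho_c: float

    def __post_init__(self):
        for name in ("v_p", "alpha", "theta", "lam", "rho_s", "rho_c"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise InvalidParameterError(
                    f"{name} must be finite and >= 0, got {val!r}"
                )
        if self.rho_s <= 0:
            raise InvalidParameterError(f"rho_s must be > 0, got {self.rho_s!r}")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Grid1D:
    """Uniform cell-centred 1D grid on [0, L].

    Cell centres sit at ``x = (j + 1/2) dx``; aster centres are snapped to
    the nearest cell, where the density is pinned to ``rho_c``.
    """

    L: float
    nx: int

    def __post_init__(self):
        if self.nx < 16:
            raise InvalidParameterError(f"nx must be >= 16, got {self.nx}")
        if self.L <= 0:
            raise InvalidParameterError(f"L must be > 0, got {self.L}")

    @property
    def dx(self) -> float:
        return self.L / self.nx

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    def index_of(self, pos: float) -> int:
        """Nearest cell index for a physical position in [0, L]."""
        if pos < 0 or pos > self.L:
            raise InvalidParameterError(f"position {pos} outside [0, {self.L}]")
        return int(np.clip(round(pos / self.dx - 0.5), 0, self.nx - 1))


@dataclass(frozen=True)
class CycleConfig:
    """Cell-cycle reset schedule for multi-aster runs.

    Every ``T_cc`` minutes the densities are multiplied by
    ``reset_fraction`` (mitotic aster disassembly) and, if ``recentre`` is
    set, each surviving aster is re-anchored at the mass centroid of its own
    density field (dynein-driven recentring of the nucleus).
    """

    T_cc: float
    n_cycles: int
    reset_fraction: float = 0.05
    recentre: bool = True

    def __post_init__(self):
        if self.T_cc <= 0:
            raise InvalidParameterError(f"T_cc must be > 0, got {self.T_cc}")
        if not (0 <= self.reset_fraction <= 1):
            raise InvalidParameterError(
                f"reset_fraction must be in [0, 1], got {self.reset_fraction}"
            )
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")


def default_dt(params: ModelParams, grid: Grid1D, cfl: float = 0.5) -> float:
    """Default explicit time step: ``cfl * dx / v_p`` (upwind CFL)."""
    if params.v_p <= 0:
        raise InvalidParameterError("v_p must be > 0 for advective runs")
    return cfl * grid.dx / params.v_p
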