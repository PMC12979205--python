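"""Validated YAML/JSON run configuration.

Schema validation (unknown keys rejected, defaults filled) is handled by
pydantic models; the error message names the offending key.  The CFL
constraint ``v_p * dt / dx <= 1`` is enforced at validation time so a bad
time step is caught before any solver runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .exceptions import ConfigurationError, ParseError
from .params import CycleConfig, Grid1D, ModelParams

__all__ = ["RunSpec", "read_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    v_p: float = 10.0
    alpha: float = 0.554
    theta: float = 0.2
    lam: float = 1.0
    rho_s: float = 1.0
    rho_c: float = 0.5

    def to_params(self) -> ModelParams:
        return ModelParams(v_p=self.v_p, alpha=self.alpha, theta=self.theta,
                           lam=self.lam, rho_s=self.rho_s, rho_c=self.rho_c)


class GridSection(_Strict):
    L: float = 200.0
    nx: int = 128

    def to_grid(self) -> Grid1D:
        return Grid1D(L=self.L, nx=self.nx)


class RunSection(_Strict):
    dt: float | None = None
    T: float = 60.0


class CycleSection(_Strict):
    T_cc: float = 40.0
    n_cycles: int = 8
    reset_fraction: float = 0.05
    recentre: bool = True
    seed: int = 0

    def to_cycle(self) -> CycleConfig:
        return CycleConfig(T_cc=self.T_cc, n_cycles=self.n_cycles,
                           reset_fraction=self.reset_fraction,
                           recentre=self.recentre)


class AgentSection(_Strict):
    v_p: float = 10.0
    theta: float = 1.0
    k_nuc: float = 50.0
    k_branch: float = 0.0
    n_nucleators: int = 100000
    sigma_branch: float = 10.0
    d_inh: float = 0.0
    f_inh: float = 1.0
    slab: tuple[float, float, float] = (300.0, 120.0, 10.0)
    separation: float = 150.0
    dt: float = 0.1
    seed: int = 0


class SynthSection(_Strict):
    kind: str = "tracks"
    n_tracks: int = 500
    n_lifetimes: int = 1000
    frames: int = 60
    loc_sigma: float = 0.03
    profile_noise: float = 0.05
    dM_frac: float = 0.1


class RunSpec(_Strict):
    model: ModelSection = ModelSection()
    grid: GridSection = GridSection()
    run: RunSection = RunSection()
    cycle: CycleSection = CycleSection()
    agents: AgentSection = AgentSection()
    synth: SynthSection = SynthSection()

    @model_validator(mode="after")
    def _check_cfl(self):
        if self.run.dt is not None:
            dx = self.grid.L / self.grid.nx
            if self.model.v_p * self.run.dt / dx > 1.0:
                raise ValueError(
                    f"run.dt: CFL violation (v_p*dt/dx = "
                    f"{self.model.v_p * self.run.dt / dx:.3f} > 1)")
        return self


def read_config(path) -> RunSpec:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as err:
        raise ParseError(f"cannot parse {path}: {err}") from err
    if raw is None:
        raw = {}
    try:
        return RunSpec.model_validate(raw)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigurationError(
            f"invalid config {path}: {loc}: {first['msg']}") from err
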