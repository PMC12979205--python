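"""Readers/writers for the tidy CSV/TSV interchange formats.

All tables are long-format CSV with units encoded in the headers
(``t_min``, ``x_um``, ...).  Round trips are lossless: unknown columns are
preserved on read and written back unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .profiles import DensityProfile
from .tracking import Track
from .turnover import FrapCurve, LifetimeSample

__all__ = [
    "read_tracks", "write_tracks",
    "read_profile", "write_profile",
    "read_lifetimes", "write_lifetimes",
    "read_frap", "write_frap",
    "write_trajectory",
    "RunManifest",
]

TRACK_COLUMNS = ["track_id", "t_min", "x_um", "y_um"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        return pd.read_csv(path, sep=sep)
    except Exception as err:
        raise ParseError(f"cannot parse {path}: {err}") from err


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


def read_tracks(path) -> list[Track]:
    """Read plus-end tracks (columns track_id, t_min, x_um, y_um
    [, aster_id]); extra columns are ignored for the Track objects but
    survive a frame-level round trip."""
    df = _read_table(path)
    _require(df, TRACK_COLUMNS, path)
    tracks = []
    has_aster = "aster_id" in df.columns
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_min")
        if len(g) < 2:
            continue
        if (np.diff(g["t_min"].to_numpy()) <= 0).any():
            raise ParseError(
                f"{path}: track {tid} has non-increasing times")
        aster = int(g["aster_id"].iloc[0]) if has_aster else None
        tracks.append(Track(int(tid), g["t_min"].to_numpy(),
                            g["x_um"].to_numpy(), g["y_um"].to_numpy(),
                            aster_id=aster))
    return tracks


def write_tracks(tracks, path) -> None:
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            row = {"track_id": tr.track_id, "t_min": tr.t[k],
                   "x_um": tr.x[k], "y_um": tr.y[k]}
            if tr.aster_id is not None:
                row["aster_id"] = tr.aster_id
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profile(path) -> DensityProfile:
    df = _read_table(path)
    _require(df, ["x_um", "rho1", "rho2"], path)

    def col(name):
        return df[name].to_numpy() if name in df.columns else None

    return DensityProfile(x=df["x_um"].to_numpy(),
                          rho1=df["rho1"].to_numpy(),
                          rho2=df["rho2"].to_numpy(),
                          sem1=col("sem1"), sem2=col("sem2"),
                          polarity=col("polarity"))


def write_profile(profile: DensityProfile, path) -> None:
    data = {"x_um": profile.x, "rho1": profile.rho1, "rho2": profile.rho2}
    for name in ("sem1", "sem2", "polarity"):
        v = getattr(profile, name)
        if v is not None:
            data[name] = v
    pd.DataFrame(data).to_csv(path, index=False)


def read_lifetimes(path) -> LifetimeSample:
    df = _read_table(path)
    _require(df, ["duration_min", "censored"], path)
    t_obs = float(df["t_obs_min"].iloc[0]) if "t_obs_min" in df.columns \
        else np.inf
    return LifetimeSample(durations=df["duration_min"].to_numpy(),
                          censored=df["censored"].to_numpy().astype(bool),
                          t_obs=t_obs)


def write_lifetimes(sample: LifetimeSample, path) -> None:
    df = pd.DataFrame({"duration_min": sample.durations,
                       "censored": sample.censored.astype(int)})
    if np.isfinite(sample.t_obs):
        df["t_obs_min"] = sample.t_obs
    df.to_csv(path, index=False)


def read_frap(path) -> FrapCurve:
    df = _read_table(path)
    _require(df, ["t_min", "recovery"], path)
    return FrapCurve(times=df["t_min"].to_numpy(),
                     recovery=df["recovery"].to_numpy())


def write_frap(curve: FrapCurve, path) -> None:
    pd.DataFrame({"t_min": curve.times,
                  "recovery": curve.recovery}).to_csv(path, index=False)


def write_trajectory(traj, path) -> None:
    """Long-format CSV (t_min, x_um, aster_id, rho) of a solver run."""
    traj.to_frame().to_csv(path, index=False)


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    command: str
    seed: int | None = None
    config_path: str | None = None
    config_sha256: str | None = None
    inputs: list = dataclasses.field(default_factory=list)
    outputs: list = dataclasses.field(default_factory=list)
    package_version: str = ""
    python: str = dataclasses.field(default_factory=platform.python_version)
    started: str = ""
    finished: str = ""

    @staticmethod
    def now() -> str:
        return datetime.now(timezone.utc).isoformat()

    @classmethod
    def start(cls, command: str, seed=None, config_path=None) -> "RunManifest":
        from . import __version__

        sha = None
        if config_path is not None:
            sha = hashlib.sha256(
                Path(config_path).read_bytes()).hexdigest()
        return cls(command=command, seed=seed,
                   config_path=str(config_path) if config_path else None,
                   config_sha256=sha, package_version=__version__,
                   started=cls.now())

    def finish(self, path) -> None:
        self.finished = self.now()
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2) + "\n")
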