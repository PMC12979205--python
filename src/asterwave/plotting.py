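"""Matplotlib views of profiles, trajectories and the phase diagram."""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_profile_fit",
    "plot_trajectory",
    "plot_phase_diagram",
    "plot_phase_portrait",
]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_profile_fit(results, replicate: int = 0, ax=None):
    """Data vs fitted steady profiles for one replicate."""
    ax = _ax(ax)
    prof = results.model.profiles[replicate]
    m1, m2 = results.fittedvalues(replicate)
    ax.errorbar(prof.x, prof.rho1, yerr=prof.sem1, fmt=".", color="0.4",
                label="aster 1 (data)")
    ax.errorbar(prof.x, prof.rho2, yerr=prof.sem2, fmt=".", color="seagreen",
                label="aster 2 (data)")
    ax.plot(prof.x, m1, color="darkorange", label="global fit")
    ax.plot(prof.x, m2, color="darkorange")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("plus-end density (1/µm)")
    ax.legend(frameon=False)
    return ax


def plot_trajectory(traj, n_times: int = 6, ax=None):
    """Density snapshots of a pair/multi-aster run, coloured by time."""
    ax = _ax(ax)
    idx = np.linspace(0, len(traj.t) - 1, n_times).astype(int)
    import matplotlib.cm as cm

    for frac, k in zip(np.linspace(0.3, 1.0, n_times), idx):
        for i in range(traj.n_asters):
            ax.plot(traj.grid.x, traj.rho[k, i],
                    color=cm.viridis(frac) if i == 0 else cm.magma(frac),
                    lw=1, label=f"t={traj.t[k]:.0f} min" if i == 0 else None)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("density (1/µm)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_phase_diagram(points, ellipses=(), ax=None):
    """(theta, alpha' - theta) plane with the alpha' = theta boundary.

    ``points`` is a sequence of (theta, alpha_eff, label); ``ellipses``
    optional PhaseEllipse objects drawn as 95% confidence contours.
    """
    from matplotlib.patches import Ellipse

    ax = _ax(ax)
    thetas = [p[0] for p in points] or [0.1, 0.3]
    tmax = 1.2 * max(thetas)
    ax.axhline(0.0, color="k", lw=1)
    ax.fill_between([0, tmax], 0, -tmax, color="tab:orange", alpha=0.15)
    ax.fill_between([0, tmax], 0, tmax, color="tab:blue", alpha=0.15)
    for th, ae, label in points:
        ax.plot(th, ae - th, "o", label=label)
    for ell in ellipses:
        th, ae = ell.mean
        ax.add_patch(Ellipse((th, ae - th), 2 * ell.axes[0],
                             2 * ell.axes[1],
                             angle=np.degrees(ell.angle), fill=False,
                             color="k", lw=1))
    ax.set_xlabel(r"$\theta$ (1/min)")
    ax.set_ylabel(r"$\alpha' - \theta$ (1/min)")
    if points:
        ax.legend(frameon=False, fontsize=8)
    return ax


def plot_phase_portrait(series, lag: float = 8.0, ax=None, **kwargs):
    """A(t)/A0 against A(t + lag)/A0 with the identity diagonal."""
    from .compartments import phase_portrait

    ax = _ax(ax)
    a0, a1 = phase_portrait(series, lag)
    ax.plot(a0, a1, ".-", **kwargs)
    lim = max(1.05, a1.max() * 1.05)
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("A(t) / A$_0$")
    ax.set_ylabel(f"A(t + {lag:g} min) / A$_0$")
    return ax
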