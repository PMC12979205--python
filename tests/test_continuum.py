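"""Continuum solver: closed-form limits, symmetry, conservation,
stability criterion and invasion dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import asterwave as aw
from asterwave.continuum import (
    PairState,
    interface_position,
    single_aster_profile,
    solve_multi_aster,
    solve_pair,
    symmetric_pair_profile,
)
from asterwave.exceptions import (
    ConfigurationError,
    InvalidParameterError,
    NoInvasionError,
)
from asterwave.params import CycleConfig, Grid1D, ModelParams


# ---------------------------------------------------------------------------
# stability algebra
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("alpha,rho_int,rho_s,expected", [
    (3.0, 1.0, 1.0, 1.0),          # alpha/(1 + 2) with rho_int = rho_s
    (2.0, 0.0, 1.0, 2.0),          # no interface density: criterion is theta > alpha
    (0.4, 0.5, 1.0, 0.2),          # alpha = 2 theta, rho_int = rho_s/2 -> marginal
])
def test_effective_autocatalysis_values(alpha, rho_int, rho_s, expected):
    assert aw.effective_autocatalysis(alpha, rho_int, rho_s) == pytest.approx(expected)


def test_effective_autocatalysis_rejects_bad_rho_s():
    with pytest.raises(InvalidParameterError):
        aw.effective_autocatalysis(1.0, 0.5, 0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(alpha=st.floats(0.01, 10), rho_int=st.floats(0, 100),
       rho_s=st.floats(0.01, 10))
def test_effective_autocatalysis_bounded_by_alpha(alpha, rho_int, rho_s):
    a_eff = aw.effective_autocatalysis(alpha, rho_int, rho_s)
    assert 0 <= a_eff <= alpha


def test_stability_margin_dominated_regimes(grid):
    p = ModelParams(v_p=10, alpha=0.5, theta=1.0, lam=1.0, rho_s=1.0,
                    rho_c=0.5)
    # alpha' <= alpha < theta regardless of the interface density
    assert aw.stability_margin(p, rho_int=0.0).stable
    assert aw.stability_margin(p, rho_int=5.0).stable
    a = aw.stability_margin(
        ModelParams(v_p=10, alpha=0.3, theta=0.1, lam=0.1, rho_s=1.0,
                    rho_c=0.5), rho_int=0.5)
    assert a.alpha_eff == pytest.approx(0.15)
    assert a.margin == pytest.approx(0.05)
    assert not a.stable


# ---------------------------------------------------------------------------
# single-aster closed forms
# ---------------------------------------------------------------------------

def test_low_density_profile_slope_matches_closed_form():
    """Decaying branch: rho(x) ~ exp((alpha - theta) x / v_p)."""
    p = ModelParams(v_p=10, alpha=0.1, theta=0.2, lam=0.2, rho_s=1.0,
                    rho_c=1e-4)
    g = Grid1D(200.0, 256)
    prof = single_aster_profile(p, g)
    slope = np.polyfit(g.x[2:120], np.log(prof[2:120]), 1)[0]
    assert slope == pytest.approx((p.alpha - p.theta) / p.v_p, rel=0.02)


def test_flat_profile_at_alpha_equals_theta():
    p = ModelParams(v_p=10, alpha=0.2, theta=0.2, lam=0.2, rho_s=1.0,
                    rho_c=1e-4)
    g = Grid1D(200.0, 128)
    prof = single_aster_profile(p, g)
    assert np.all(np.abs(prof / p.rho_c - 1) < 0.01)


def test_growing_profile_plateau_value():
    """Far-field fixed point rho* = rho_s (alpha/theta - 1)."""
    p = ModelParams(v_p=10, alpha=0.5, theta=0.2, lam=0.2, rho_s=1.0,
                    rho_c=0.5)
    g = Grid1D(600.0, 384)
    prof = single_aster_profile(p, g)
    plateau = p.rho_s * (p.alpha / p.theta - 1)
    assert prof[-4] == pytest.approx(plateau, rel=0.01)


def test_pure_turnover_mass_decay(grid):
    """With growth, inhibition and advection off, M(t) = M0 exp(-theta t)."""
    p = ModelParams(v_p=0.0, alpha=0.0, theta=0.2, lam=0.0, rho_s=1.0,
                    rho_c=0.0)
    init = np.exp(-((grid.x - 100) / 30) ** 2)
    traj = solve_pair(p, (init, init), grid, dt=0.002, T=3 / p.theta,
                      anchored=False, reflect=True)
    masses = traj.masses()[:, 0]
    expected = masses[0] * np.exp(-p.theta * traj.t)
    assert np.max(np.abs(masses / expected - 1)) < 1e-3


def test_mass_conservation_reflecting_walls(grid):
    """Pure advection in a closed box conserves mass to round-off."""
    p = ModelParams(v_p=10.0, alpha=0.0, theta=0.0, lam=0.0, rho_s=1.0,
                    rho_c=0.0)
    init = np.exp(-((grid.x - 60) / 20) ** 2)
    traj = solve_pair(p, (init, init[::-1]), grid, T=50.0,
                      anchored=False, reflect=True)
    # finite-volume mass (dx * sum): the scheme conserves it exactly even
    # when the pulse piles up against a wall cell
    masses = traj.rho.sum(axis=(1, 2)) * grid.dx
    assert np.max(np.abs(masses / masses[0] - 1)) < 1e-10


# ---------------------------------------------------------------------------
# pair dynamics
# ---------------------------------------------------------------------------

def test_mirror_symmetry_preserved(unstable_params, grid,
                                   steady_pair_unstable):
    """Symmetric data under symmetric parameters stay symmetric >= 100 min."""
    r1, r2 = steady_pair_unstable
    traj = solve_pair(unstable_params, (r1, r2), grid, T=100.0)
    final = traj.rho[-1]
    assert np.allclose(final[0], final[1][::-1], rtol=1e-9, atol=1e-12)


def test_cfl_violation_rejected(unstable_params, grid):
    with pytest.raises(ConfigurationError, match="CFL"):
        solve_pair(unstable_params, (np.zeros(grid.nx), np.zeros(grid.nx)),
                   grid, dt=1.0, T=10.0)


def test_negative_initial_density_rejected(unstable_params, grid):
    bad = -np.ones(grid.nx)
    with pytest.raises(InvalidParameterError):
        solve_pair(unstable_params, (bad, bad), grid, T=1.0)


def test_densities_remain_nonnegative_and_finite(unstable_params, grid):
    rng = np.random.default_rng(3)
    init = rng.uniform(0, 1.0, (2, grid.nx))
    traj = solve_pair(unstable_params, (init[0], init[1]), grid, T=50.0)
    assert np.all(np.isfinite(traj.rho))
    assert np.all(traj.rho >= 0)


def test_interface_position_symmetric_and_linear(grid):
    x = grid.x
    state = PairState(0.0, x, x[::-1])
    assert interface_position(state, grid) == pytest.approx(grid.L / 2)
    # exact crossing of two straight lines, linearly interpolated
    state = PairState(0.0, 2 * (1 - x / grid.L), 2 * x / grid.L)
    assert interface_position(state, grid) == pytest.approx(grid.L / 2)


def test_interface_position_signals_completion(grid):
    state = PairState(0.0, np.full(grid.nx, 2.0), np.full(grid.nx, 1.0))
    with pytest.raises(NoInvasionError):
        interface_position(state, grid)


def test_interface_tracks_brute_force_argmin(unstable_params, grid,
                                             steady_pair_unstable):
    """Drifting interface agrees with a dense |rho1-rho2| scan within dx."""
    r1, r2 = steady_pair_unstable
    traj = solve_pair(unstable_params, (r1 * 1.05, r2 * 0.95), grid, T=40.0)
    prev = None
    for k in range(0, len(traj.t), 5):
        state = traj.state(k)
        xi = interface_position(state, grid, previous=prev)
        fine = np.linspace(0, grid.L, 4001)
        d = np.abs(np.interp(fine, grid.x, state.rho1)
                   - np.interp(fine, grid.x, state.rho2))
        assert abs(xi - fine[np.argmin(d)]) <= grid.dx
        prev = xi


def test_invasion_runs_to_winner_take_all(unstable_params, grid,
                                          steady_pair_unstable):
    """A 1% mass asymmetry ends with the loser below 10% of its start."""
    r1, r2 = steady_pair_unstable
    traj = solve_pair(unstable_params, (r1 * 1.005, r2 * 0.995), grid,
                      T=250.0)
    masses = traj.masses()
    assert masses[-1, 1] < 0.1 * masses[0, 1]
    assert masses[-1, 0] > masses[0, 0]


def test_interface_position_grid_converged(unstable_params):
    """Invasion trajectory matches a 2x-finer-grid run within 2% of L."""
    coarse, fine = Grid1D(200.0, 96), Grid1D(200.0, 192)
    xs = {}
    for g in (coarse, fine):
        r1, r2 = symmetric_pair_profile(unstable_params, g)
        traj = solve_pair(unstable_params, (r1 * 1.1, r2 * 0.9), g, T=40.0,
                          save_every=max(1, int(10.0 / (0.5 * g.dx / 10.0))))
        prev = None
        pos = []
        for k in range(len(traj.t)):
            prev = interface_position(traj.state(k), g, previous=prev)
            pos.append(prev)
        xs[g.nx] = np.interp([10, 20, 30, 40], traj.t, pos)
    assert np.all(np.abs(xs[96] - xs[192]) < 0.02 * 200.0)


# ---------------------------------------------------------------------------
# invasion-time prediction
# ---------------------------------------------------------------------------

def test_invasion_time_decreases_with_mass_difference(unstable_params, grid):
    taus = [aw.predict_invasion_time(unstable_params, dm, grid).tau
            for dm in (0.05, 0.2)]
    assert taus[0] > taus[1]


def test_invasion_time_diverges_toward_symmetry(unstable_params, grid):
    """tau grows without bound as the initial asymmetry vanishes: the
    linear-growth phase contributes ln(1/dM)/g, so equal factors in dM
    add equal time increments (log divergence), and near the boundary
    (small g) every increment stretches."""
    alpha = aw.calibrate_alpha(1.1, unstable_params, grid)
    near = unstable_params.replace(alpha=alpha)
    taus = {dm: aw.predict_invasion_time(near, dm, grid, t_max=4000).tau
            for dm in (0.0125, 0.05, 0.2)}
    inc1 = taus[0.0125] - taus[0.05]
    inc2 = taus[0.05] - taus[0.2]
    assert inc1 > 0 and inc2 > 0
    assert inc1 == pytest.approx(inc2, rel=0.25)
    # near the boundary the same asymmetry takes far longer to resolve
    tau_deep = aw.predict_invasion_time(unstable_params, 0.05, grid).tau
    assert taus[0.05] > 2 * tau_deep


def test_stable_parameters_signal_no_invasion(stable_params, grid):
    with pytest.raises(NoInvasionError) as err:
        aw.predict_invasion_time(stable_params, 0.1, grid)
    assert err.value.decay_time is not None
    assert err.value.decay_time > 0


def test_invalid_mass_fraction_rejected(unstable_params):
    with pytest.raises(InvalidParameterError):
        aw.predict_invasion_time(unstable_params, 1.5)


# ---------------------------------------------------------------------------
# numerical stability classification
# ---------------------------------------------------------------------------

def test_classification_deep_in_each_regime(grid):
    base = ModelParams(v_p=10, alpha=0.1, theta=0.2, lam=1.0, rho_s=1.0,
                       rho_c=0.5)
    assert aw.classify_stability_numerical(base, grid) == "stable"
    alpha = aw.calibrate_alpha(1.3, base, grid)
    assert aw.classify_stability_numerical(
        base.replace(alpha=alpha), grid) == "unstable"


def test_calibrated_alpha_hits_target_ratio(grid):
    base = ModelParams(v_p=10, alpha=0.3, theta=0.2, lam=1.0, rho_s=1.0,
                       rho_c=0.5)
    alpha = aw.calibrate_alpha(1.3, base, grid)
    a = aw.stability_margin(base.replace(alpha=alpha), grid=grid)
    assert a.alpha_eff / base.theta == pytest.approx(1.3, rel=1e-3)


# ---------------------------------------------------------------------------
# multi-aster generalization
# ---------------------------------------------------------------------------

def test_two_asters_at_ends_reduce_to_pair(unstable_params, grid,
                                           steady_pair_unstable):
    r1, r2 = steady_pair_unstable
    init = np.stack([r1, r2])
    t_pair = solve_pair(unstable_params, (r1, r2), grid, T=20.0)
    t_multi = solve_multi_aster(unstable_params, [0.0, grid.L], grid,
                                T=20.0, init=init)
    assert np.array_equal(t_pair.rho, t_multi.rho)


def test_three_asters_symmetric_configuration(unstable_params):
    """Equally spaced asters from symmetric data: the middle aster's mass
    centroid stays at the domain centre and the outer masses stay equal.
    (Odd cell count so that the layout is exactly mirror-symmetric.)"""
    g = Grid1D(600.0, 129)
    centres = g.x[[12, 64, 116]]
    traj = solve_multi_aster(unstable_params, centres, g, T=60.0)
    masses = traj.masses()
    assert np.allclose(masses[:, 0], masses[:, 2], rtol=1e-9)
    mid = traj.rho[-1, 1]
    centroid = np.sum(g.x * mid) / np.sum(mid)
    assert centroid == pytest.approx(300.0, abs=g.dx)


def test_unstable_multi_aster_coarsens(unstable_params):
    """Random perturbations: the number of surviving asters decreases."""
    g = Grid1D(1000.0, 320)
    centres = (np.arange(5) + 0.5) * 200.0
    rng = np.random.default_rng(1)
    init = np.zeros((5, g.nx))
    rc = unstable_params.rho_c * (1 + 0.05 * rng.standard_normal(5))
    traj = solve_multi_aster(unstable_params, centres, g, T=300.0,
                             init=init, rho_c_per_aster=rc)
    masses = traj.masses()
    surviving = lambda m: int((m > 0.1 * m.mean()).sum())
    assert surviving(masses[-1]) < surviving(masses[len(masses) // 6])


def test_overlapping_centres_rejected(unstable_params, grid):
    with pytest.raises(ConfigurationError):
        solve_multi_aster(unstable_params, [50.0, 50.2], grid, T=1.0)


# ---------------------------------------------------------------------------
# cell-cycle coupling
# ---------------------------------------------------------------------------

def test_full_reset_fraction_is_noop(stable_params):
    """reset_fraction = 1 without recentring reproduces the plain run."""
    g = Grid1D(400.0, 128)
    centres = [100.0, 300.0]
    cyc = CycleConfig(T_cc=10.0, n_cycles=3, reset_fraction=1.0,
                      recentre=False)
    res = aw.run_cycling(stable_params, centres, g, cyc, seed=0,
                         amp_noise=0.0)
    traj = solve_multi_aster(stable_params, centres, g, T=30.0)
    final_masses = traj.masses()[-1]
    assert np.allclose(res.summaries[-1].masses, final_masses, rtol=1e-10)


def test_stable_cycling_sizes_stationary(stable_params):
    g = Grid1D(800.0, 256)
    centres = (np.arange(4) + 0.5) * 200.0
    for tcc in (10.0, 40.0):
        res = aw.run_cycling(stable_params, centres, g,
                             CycleConfig(T_cc=tcc, n_cycles=4), seed=2)
        for s in res.summaries:
            assert s.n_alive == 4
            assert np.all(np.abs(s.sizes_norm - 1) < 0.2)
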