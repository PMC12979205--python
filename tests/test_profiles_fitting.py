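"""Profile reconstruction from tracks and global model fitting."""

import numpy as np
import pytest

import asterwave as aw
from asterwave import studies, synth
from asterwave.continuum import symmetric_pair_profile
from asterwave.exceptions import ConfigurationError, InvalidParameterError
from asterwave.fitting import ProfileFitModel, bootstrap_phase
from asterwave.params import Grid1D
from asterwave.tracking import Track


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def test_all_rightward_tracks_fill_only_aster1():
    t = np.arange(3.0)
    tracks = [Track(i, t, 20.0 * i + 5 * t, np.zeros(3)) for i in range(4)]
    prof = aw.reconstruct_profiles(tracks, ((0, 0), (100, 0)), binwidth=10.0)
    assert prof.rho2.sum() == 0
    pol = prof.polarity[np.isfinite(prof.polarity)]
    assert np.all(pol == 1.0)


def test_mirror_symmetric_tracks_give_mirror_profiles():
    rng = np.random.default_rng(5)
    t = np.arange(4.0) * 0.1
    tracks = []
    for i in range(300):
        x0 = rng.uniform(0, 40)
        tracks.append(Track(2 * i, t, x0 + 10 * t, np.zeros(4)))
        tracks.append(Track(2 * i + 1, t, 100 - x0 - 10 * t, np.zeros(4)))
    prof = aw.reconstruct_profiles(tracks, ((0, 0), (100, 0)), binwidth=10.0)
    # Poisson-level agreement between rho1(x) and rho2(L - x)
    diff = prof.counts1 - prof.counts2[::-1]
    assert np.all(np.abs(diff) <= 4 * np.sqrt(prof.counts1 + 1))


def test_reconstruction_preserves_counts():
    cfg = synth.SynthConfig(n_tracks=200, frames=30)
    data = synth.gen_profile_tracks(cfg, seed=2)
    prof = aw.reconstruct_profiles(data.tracks, ((0, 0), (200, 0)),
                                   binwidth=5.0)
    n_samples = sum(np.sum((tr.x >= 0) & (tr.x < prof.span))
                    for tr in data.tracks)
    assert prof.counts1.sum() + prof.counts2.sum() == n_samples


def test_reconstruction_closure_against_generator():
    """Noiseless generator output reproduces the generating profile with
    cluster-robust chi2/dof ~ 1 (samples within a track are correlated,
    so the track is the independent unit)."""
    cfg = synth.SynthConfig(n_tracks=800, frames=60, loc_sigma=0.0,
                            speed_sigma=0.0)
    data = synth.gen_profile_tracks(cfg, seed=1)
    edges = np.arange(0.0, 205.0, 5.0)
    for aster in (1, 2):
        trs = [t for t in data.tracks if t.aster_id == aster]
        per = np.stack([np.histogram(t.x, bins=edges)[0]
                        for t in trs]).astype(float)
        obs = per.sum(axis=0)
        dens = np.interp(0.5 * (edges[:-1] + edges[1:]), data.grid.x,
                         data.rho[aster - 1])
        exp = dens / dens.sum() * obs.sum()
        var = (per ** 2).sum(axis=0) - per.sum(axis=0) ** 2 / len(per)
        keep = (exp >= 10) & (var > 0)
        chi2 = np.sum((obs[keep] - exp[keep]) ** 2 / var[keep]) / keep.sum()
        assert 0.2 < chi2 < 2.0


def test_midzone_polarity_is_unidirectional():
    cfg = synth.SynthConfig(n_tracks=500, frames=60)
    data = synth.gen_profile_tracks(cfg, seed=3)
    prof = aw.reconstruct_profiles(data.tracks, ((0, 0), (200, 0)),
                                   binwidth=10.0)
    # near aster 1's centre almost all plus ends move +x, near aster 2 -x
    assert prof.polarity[1] > 0.9
    assert prof.polarity[-2] < 0.1


def test_coincident_centres_rejected():
    with pytest.raises(ConfigurationError):
        aw.reconstruct_profiles([], ((5, 5), (5, 5)), binwidth=1.0)


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def test_noiseless_fit_recovers_generating_parameters(unstable_params):
    grid = Grid1D(200.0, 96)
    profs = studies.make_replicate_profiles(unstable_params, 2, 0.0, 1,
                                            grid)
    res = ProfileFitModel(profs, unstable_params.v_p,
                          unstable_params.theta, grid=grid).fit(seed=0)
    for name in ("alpha", "lam", "rho_s"):
        assert res.params[name] == pytest.approx(
            getattr(unstable_params, name), rel=0.01)


def test_noisy_fit_within_stated_tolerances(stable_params):
    """Stable truth at 5% noise: alpha within 10%, lam within 20% (rho_s
    is pinned by the plateau only for unstable truths)."""
    grid = Grid1D(200.0, 96)
    profs = studies.make_replicate_profiles(stable_params, 8, 0.05, 2, grid)
    res = ProfileFitModel(profs, stable_params.v_p,
                          stable_params.theta, grid=grid).fit(seed=0)
    assert res.params["alpha"] == pytest.approx(stable_params.alpha,
                                                rel=0.10)
    assert res.params["lam"] == pytest.approx(stable_params.lam, rel=0.20)


def test_misspecified_theta_costs_more(unstable_params):
    """Residual at 2x the true turnover strictly exceeds the true one."""
    grid = Grid1D(200.0, 96)
    profs = studies.make_replicate_profiles(unstable_params, 3, 0.02, 3,
                                            grid)
    good = ProfileFitModel(profs, unstable_params.v_p,
                           unstable_params.theta, grid=grid).fit(seed=0)
    bad = ProfileFitModel(profs, unstable_params.v_p,
                          2 * unstable_params.theta, grid=grid).fit(seed=0)
    assert bad.cost > good.cost


def test_covariance_is_symmetric_psd(unstable_params):
    grid = Grid1D(200.0, 96)
    profs = studies.make_replicate_profiles(unstable_params, 3, 0.05, 4,
                                            grid)
    res = ProfileFitModel(profs, unstable_params.v_p,
                          unstable_params.theta, grid=grid).fit(seed=0)
    cov = res.cov_params()
    assert np.allclose(cov, cov.T)
    assert np.all(np.linalg.eigvalsh(cov) > -1e-12)
    assert np.all(res.bse >= 0)


def test_summary_reports_estimates_and_phase(unstable_params):
    grid = Grid1D(200.0, 96)
    profs = studies.make_replicate_profiles(unstable_params, 2, 0.02, 5,
                                            grid)
    res = ProfileFitModel(profs, unstable_params.v_p,
                          unstable_params.theta, grid=grid).fit(seed=0)
    text = res.summary()
    assert "alpha" in text and "rho_s" in text and "unstable" in text


def test_fit_requires_profiles():
    with pytest.raises(InvalidParameterError):
        ProfileFitModel([], v_p=10.0, theta=0.2)


# ---------------------------------------------------------------------------
# bootstrap phase placement
# ---------------------------------------------------------------------------

def test_identical_replicates_give_degenerate_ellipse(unstable_params):
    grid = Grid1D(200.0, 96)
    prof = studies.make_replicate_profiles(unstable_params, 1, 0.02, 6,
                                           grid)[0]
    ell = bootstrap_phase([prof] * 4, unstable_params.v_p,
                          unstable_params.theta, B=20, seed=0, grid=grid)
    assert ell.area == pytest.approx(0.0, abs=1e-8)
    assert ell.margin > 0  # truth is unstable


def test_bootstrap_side_matches_truth_for_stable_set(stable_params):
    grid = Grid1D(200.0, 96)
    profs = studies.make_replicate_profiles(stable_params, 6, 0.05, 7, grid)
    ell = bootstrap_phase(profs, stable_params.v_p, stable_params.theta,
                          B=30, seed=1, grid=grid)
    assert ell.frac_stable >= 0.95
    assert ell.margin < 0


def test_bootstrap_ellipse_area_converges_in_B(unstable_params):
    grid = Grid1D(200.0, 96)
    profs = studies.make_replicate_profiles(unstable_params, 8, 0.05, 8,
                                            grid)
    warm = ProfileFitModel(profs, unstable_params.v_p,
                           unstable_params.theta, grid=grid).fit(seed=0)
    a_small = warm.bootstrap_phase(B=60, seed=2).area
    a_big = warm.bootstrap_phase(B=240, seed=3).area
    assert a_big == pytest.approx(a_small, rel=0.35)


def test_bootstrap_needs_three_replicates(unstable_params):
    grid = Grid1D(200.0, 96)
    profs = studies.make_replicate_profiles(unstable_params, 2, 0.05, 9,
                                            grid)
    with pytest.raises(InvalidParameterError):
        bootstrap_phase(profs, unstable_params.v_p, unstable_params.theta,
                        B=10, grid=grid)


# ---------------------------------------------------------------------------
# parameter propagation
# ---------------------------------------------------------------------------

def test_param_shift_identity(unstable_params):
    shifted, meta = aw.predict_param_shift(0.0, unstable_params)
    assert shifted == unstable_params
    assert meta["alpha"] == 1.0


def test_param_shift_twenty_percent_rule(unstable_params):
    shifted, meta = aw.predict_param_shift(-0.2, unstable_params)
    assert shifted.v_p == pytest.approx(0.8 * unstable_params.v_p)
    assert shifted.alpha == pytest.approx(0.8 * unstable_params.alpha)
    assert shifted.rho_s == pytest.approx(1.25 * unstable_params.rho_s)
    assert shifted.theta == unstable_params.theta
    assert shifted.lam == unstable_params.lam
    assert meta["rule"] == "length"


def test_param_shift_flips_near_marginal_system(unstable_params, grid):
    """A -20% polymerization shift moves a near-marginal unstable set
    across the alpha' = theta boundary (the MCAK-style rescue)."""
    alpha = aw.calibrate_alpha(1.05, unstable_params, grid)
    near = unstable_params.replace(alpha=alpha)
    before = aw.stability_margin(near, grid=grid)
    shifted, _ = aw.predict_param_shift(-0.2, near)
    after = aw.stability_margin(shifted, grid=grid)
    assert before.margin > 0 > after.margin


def test_param_shift_rejects_total_collapse(unstable_params):
    with pytest.raises(InvalidParameterError):
        aw.predict_param_shift(-1.0, unstable_params)
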