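"""Detection model, state space, likelihood and sampler behaviour."""

import datetime as dt
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import scr_camtrap as sc
from scr_camtrap import synthetic_data as syn
from scr_camtrap.scr_core import _update_psi, _update_z, rpsv
from scr_camtrap.types import SCRParams

from conftest import make_history

D0 = dt.date(2020, 11, 1)


# --- detection function ----------------------------------------------------


def test_detection_prob_values():
    assert sc.detection_prob(0.3, 1.5, 0.0) == pytest.approx(0.3)
    assert sc.detection_prob(0.1, 2.0, 2.0) == pytest.approx(0.1 * math.exp(-0.5))
    assert sc.detection_prob(0.0, 1.0, 3.7) == 0.0


def test_detection_prob_invalid_inputs():
    with pytest.raises(ValueError):
        sc.detection_prob(0.1, 0.0, 1.0)
    with pytest.raises(ValueError):
        sc.detection_prob(1.2, 1.0, 1.0)
    with pytest.raises(ValueError):
        sc.detection_prob(0.1, 1.0, -1.0)


@given(
    g0=st.floats(0.0, 1.0),
    sigma=st.floats(0.05, 50.0),
    d=st.floats(0.0, 100.0),
    delta=st.floats(0.0, 100.0),
)
def test_detection_prob_monotone_in_distance_and_scale(g0, sigma, d, delta):
    p = sc.detection_prob(g0, sigma, d)
    assert 0.0 <= p <= g0
    assert sc.detection_prob(g0, sigma, d + delta) <= p
    # smaller sigma (larger 1/sigma) can only decrease detection
    assert sc.detection_prob(g0, sigma / 2.0, d) <= p + 1e-15


# --- state space and buffer ------------------------------------------------


def test_state_space_from_trap_bounding_box():
    xy = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0], [5.0, 5.0]])
    ss = sc.make_state_space(xy, 5.0)
    assert ss.bounds == (-5.0, -5.0, 15.0, 15.0)
    assert ss.area_km2 == pytest.approx(400.0)


def test_state_space_single_trap():
    ss = sc.make_state_space(np.array([[0.0, 0.0]]), 13.0)
    assert (ss.xmax - ss.xmin, ss.ymax - ss.ymin) == (26.0, 26.0)
    assert ss.area_km2 == pytest.approx(676.0)


def test_state_space_requires_positive_buffer():
    with pytest.raises(ValueError):
        sc.make_state_space(np.array([[0.0, 0.0]]), 0.0)


def _history_two_sites_apart():
    y = np.zeros((1, 2, 2), dtype=int)
    y[0, 0, 0] = 1
    y[0, 1, 1] = 1
    return make_history(y, np.ones((2, 2)), [[0.0, 0.0], [2.0, 0.0]])


def test_suggest_buffer_hand_case():
    h = _history_two_sites_apart()
    assert rpsv(h) == pytest.approx(1.0)
    assert sc.suggest_buffer(h) == pytest.approx(4.0)


def test_suggest_buffer_without_movement_information():
    y = np.zeros((2, 2, 3), dtype=int)
    y[0, 0, :2] = 1  # recaptured, but always the same site
    y[1, 1, 0] = 1
    h = make_history(y, np.ones((2, 3)), [[0.0, 0.0], [2.0, 0.0]])
    with pytest.raises(ValueError, match="manual"):
        sc.suggest_buffer(h)


def test_rpsv_recovers_movement_scale_under_heavy_sampling():
    sim = replace(syn.standard_scenario(), fixed_N=40, density=None, g0=0.15)
    data = syn.simulate_survey(sim, seed=7)
    records, log = sc.apply_exclusions(data.detections)
    config = syn.survey_config_for(sim)
    h = sc.build_capture_history(records, data.traps, config, log)
    assert rpsv(h) == pytest.approx(sim.sigma, rel=0.2)


# --- likelihood ------------------------------------------------------------


def _params(M, g0=0.3, sigma=2.0, psi=0.6, s=None, z=None):
    return SCRParams(
        g0=g0,
        sigma=sigma,
        psi=psi,
        z=np.ones(M, dtype=int) if z is None else z,
        s=np.zeros((M, 2)) if s is None else s,
    )


def test_conditional_loglik_zero_when_nothing_detectable():
    h = make_history(np.zeros((1, 1, 3), dtype=int), np.ones((1, 3)), [[0.0, 0.0]])
    ss = sc.make_state_space(h.trap_xy, 1.0)
    assert sc.log_likelihood(h, _params(1, g0=0.0), ss, conditional_only=True) == 0.0


def test_conditional_loglik_single_capture_closed_form():
    h = make_history(np.ones((1, 1, 1), dtype=int), np.ones((1, 1)), [[0.0, 0.0]])
    ss = sc.make_state_space(h.trap_xy, 1.0)
    ll = sc.log_likelihood(h, _params(2, g0=0.2), ss, conditional_only=True)
    assert ll == pytest.approx(math.log(0.2), abs=1e-12)


def test_certain_detection_with_zero_history_gives_neg_inf():
    y = np.zeros((1, 1, 2), dtype=int)
    y[0, 0, 0] = 1  # second occasion is a miss at p = 1
    h = make_history(y, np.ones((1, 2)), [[0.0, 0.0]])
    ss = sc.make_state_space(h.trap_xy, 1.0)
    ll = sc.log_likelihood(h, _params(1, g0=1.0), ss, conditional_only=True)
    assert ll == -np.inf


def _brute_force(h, params, conditional=False):
    total = 0.0
    M = params.z.shape[0]
    for i in range(h.n if conditional else M):
        if params.z[i] == 1:
            for j in range(h.J):
                d = math.dist(params.s[i], h.trap_xy[j])
                p = sc.detection_prob(params.g0, params.sigma, d)
                for k in range(h.K):
                    if h.usage[j, k]:
                        obs = h.y[i, j, k] if i < h.n else 0
                        total += math.log(p if obs else 1.0 - p)
        if not conditional:
            total += math.log(params.psi if params.z[i] == 1 else 1.0 - params.psi)
    return total


@pytest.mark.parametrize("trial", range(6))
def test_loglik_matches_bruteforce_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    n, J, K = rng.integers(1, 4, 3)
    M = int(n + rng.integers(1, 4))
    usage = rng.integers(0, 2, (J, K))
    usage[:, 0] = 1
    y = (rng.random((n, J, K)) < 0.4).astype(int) & usage[None, :, :]
    xy = rng.uniform(0.0, 10.0, (J, 2))
    h = make_history(y, usage, xy)
    ss = sc.make_state_space(xy, 5.0)
    z = np.ones(M, dtype=int)
    z[n:] = rng.integers(0, 2, M - n)
    s = np.column_stack(
        [rng.uniform(ss.xmin, ss.xmax, M), rng.uniform(ss.ymin, ss.ymax, M)]
    )
    params = _params(M, g0=0.3, sigma=2.0, psi=0.6, s=s, z=z)
    assert sc.log_likelihood(h, params, ss) == pytest.approx(
        _brute_force(h, params), abs=1e-10
    )
    assert sc.log_likelihood(h, params, ss, conditional_only=True) == pytest.approx(
        _brute_force(h, params, conditional=True), abs=1e-10
    )


def test_unused_site_contributes_nothing():
    y = np.zeros((1, 2, 3), dtype=int)
    y[0, 0, 0] = 1
    usage = np.array([[1, 1, 1], [0, 0, 0]])
    h2 = make_history(y, usage, [[0.0, 0.0], [4.0, 0.0]])
    h1 = make_history(y[:, :1, :], usage[:1], [[0.0, 0.0]])
    ss = sc.make_state_space(np.array([[0.0, 0.0], [4.0, 0.0]]), 3.0)
    p2 = _params(2)
    ll2 = sc.log_likelihood(h2, p2, ss, conditional_only=True)
    ll1 = sc.log_likelihood(h1, p2, ss, conditional_only=True)
    assert ll2 == pytest.approx(ll1, abs=1e-12)


# --- sampler ---------------------------------------------------------------


def test_run_mcmc_input_validation(demo_run):
    _, _, result = demo_run
    h = result.history
    ss = result.state_space
    with pytest.raises(ValueError, match="M"):
        sc.run_mcmc(h, sc.MCMCConfig(n_iter=20, burn_in=10), ss, M=h.n)
    dead = make_history(
        np.zeros((1, 1, 2), dtype=int), np.zeros((1, 2)), [[0.0, 0.0]]
    )
    with pytest.raises(ValueError, match="usage"):
        sc.run_mcmc(dead, sc.MCMCConfig(n_iter=20, burn_in=10), ss, M=10)


def test_population_size_never_below_detected(demo_run):
    _, _, result = demo_run
    chains = result.chains
    assert (chains.params["N"] >= chains.n_detected).all()
    for draws in chains.map_draws:
        assert all(d.shape[0] >= chains.n_detected for d in draws)


def test_density_is_exact_transform_of_population_size(demo_run):
    _, _, result = demo_run
    chains = result.chains
    np.testing.assert_allclose(
        chains.params["D"], chains.params["N"] / chains.area_km2 * 100.0, rtol=1e-12
    )


def test_psi_gibbs_matches_beta_conditional():
    rng = np.random.default_rng(5)
    z = np.zeros(100)
    z[:30] = 1
    draws = np.array([_update_psi(rng, z, 100) for _ in range(4000)])
    assert stats.kstest(draws, stats.beta(31, 71).cdf).pvalue > 0.01


def test_z_gibbs_probability_balances_prior_and_likelihood():
    rng = np.random.default_rng(6)
    ll_zero = np.full(20000, math.log(0.25))
    psi = 0.4
    frac = _update_z(rng, ll_zero, psi).mean()
    expected = psi * 0.25 / (psi * 0.25 + (1 - psi))
    assert frac == pytest.approx(expected, abs=3 * math.sqrt(expected / 20000) + 0.01)


def test_metropolis_acceptance_rates_in_band(standard_run):
    _, _, result = standard_run
    for name, rate in result.chains.acceptance.items():
        assert 0.1 < rate < 0.6, (name, rate)


def test_map_draw_thinning_windows():
    y = np.zeros((1, 1, 4), dtype=int)
    y[0, 0, 0] = 1
    h = make_history(y, np.ones((1, 4)), [[0.0, 0.0]])
    ss = sc.make_state_space(h.trap_xy, 3.0)
    post = sc.run_mcmc(h, sc.MCMCConfig(n_iter=100, burn_in=40, thin_maps=10), ss, M=5)
    assert len(post.map_draws[0]) == 6  # iterations 40, 50, ..., 90
    full = sc.run_mcmc(
        h,
        sc.MCMCConfig(n_iter=100, burn_in=40, thin_maps=10, map_from_start=True),
        ss,
        M=5,
    )
    assert len(full.map_draws[0]) == 10  # iterations 0, 10, ..., 90


def test_same_seed_reproduces_chains(demo_run):
    sim, data, result = demo_run
    cfg = syn.survey_config_for(
        sim, mcmc=sc.MCMCConfig(n_iter=2000, burn_in=500), seed=11
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        again = sc.run_analysis(cfg, data.traps, data.detections)
    for name, arr in result.chains.params.items():
        assert np.array_equal(arr, again.chains.params[name]), name
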