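"""Ideal/optimal observer: weights, link matrix, iteration, decisions, dynamics."""

import math

import numpy as np
import pytest

from afcontour.af import AFParams, DegenerateGeometryError, Edge, af_density
from afcontour.observer import (ContourObserver, EccParams, SOAMap,
                                brute_force_likelihood, contour_likelihood_dynamics,
                                decide_2afc, hemifield_evidence, link_matrix,
                                n_iterations_for_soa, salience_weights,
                                starting_likelihoods)
from afcontour.stimuli import Stimulus


def test_salience_weights_special_cases():
    ecc = EccParams(amplitude=0.0, gamma=2.0)
    x = np.array([0.0, 3.0, 10.0])
    assert np.all(salience_weights(x, np.zeros(3), ecc) == 1.0)
    ecc2 = EccParams(amplitude=0.7, gamma=1.5)
    w = salience_weights(np.array([0.0]), np.array([0.0]), ecc2)
    assert w[0] == 1.0
    eps = np.linspace(0, 16.66, 50)
    w = salience_weights(eps, np.zeros(50), ecc2)
    assert np.all(np.diff(w) <= 0)
    assert np.all((w > 0) & (w <= 1))


def test_salience_clamps_beyond_eps_max():
    ecc = EccParams(amplitude=0.5, gamma=1.0, eps_max=10.0)
    with pytest.warns(UserWarning):
        w = salience_weights(np.array([12.0]), np.array([0.0]), ecc)
    assert w[0] == pytest.approx(0.5)


def test_ecc_params_validation():
    with pytest.raises(ValueError):
        EccParams(amplitude=1.0)
    with pytest.raises(ValueError):
        EccParams(gamma=0.0)


def test_link_matrix_entries_and_symmetries():
    af = AFParams(0.3, 0.4)
    x = np.array([0.0, 2.0, 3.0])
    y = np.array([0.0, 0.5, -1.0])
    t = np.array([0.1, 0.7, 2.0])
    Q = link_matrix(x, y, t, af)
    assert np.all(np.diag(Q) == 0)
    assert Q[0, 1] == pytest.approx(af_density(Edge(0, 0, 0.1), Edge(2, 0.5, 0.7), af))
    Q2 = link_matrix(x + 5, y - 3, t, af)  # translation invariance
    assert np.allclose(Q, Q2, rtol=1e-12)
    # reversal: transpose of the reversed-direction set
    Qr = link_matrix(x, y, t + np.pi, af)
    assert np.allclose(Q, Qr.T, rtol=1e-12)


def test_link_matrix_coincident_error():
    with pytest.raises(DegenerateGeometryError):
        link_matrix([0, 0], [1, 1], [0, 2], AFParams(0.3, 0.3))


def test_starting_likelihoods_single_step():
    rng = np.random.default_rng(2)
    Q = rng.random((5, 5))
    np.fill_diagonal(Q, 0)
    w = rng.uniform(0.3, 1.0, 5)
    b = starting_likelihoods(Q, w, 2)
    assert np.allclose(b[1], w * (Q @ w))
    assert np.array_equal(b[0], w)


def test_weighted_reduces_to_unweighted_exactly():
    rng = np.random.default_rng(3)
    Q = rng.random((6, 6))
    np.fill_diagonal(Q, 0)
    ones = np.ones(6)
    b = starting_likelihoods(Q, ones, 4)
    expect = ones.copy()
    for _ in range(3):
        expect = Q @ expect
    assert np.array_equal(b[-1], expect)  # bitwise


def test_brute_force_is_oracle_for_matrix_iteration():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = int(rng.integers(5, 9))
        L = int(rng.integers(2, 5))
        x, y = rng.uniform(-6, 6, (2, n))
        t = rng.uniform(0, 2 * np.pi, n)
        af = AFParams(rng.uniform(0.15, 0.5), rng.uniform(0.2, 0.7))
        ecc = EccParams(rng.uniform(0, 0.8), rng.uniform(0.5, 2))
        bf = brute_force_likelihood(x, y, t, af, ecc, L)
        mi = starting_likelihoods(link_matrix(x, y, t, af),
                                  salience_weights(x, y, ecc), L)[-1]
        assert np.allclose(bf, mi, rtol=1e-10)


def test_brute_force_label_invariance_and_distinct_mode():
    rng = np.random.default_rng(5)
    n, L = 6, 4
    x, y = rng.uniform(-4, 4, (2, n))
    t = rng.uniform(0, 2 * np.pi, n)
    af = AFParams(0.3, 0.4)
    ecc = EccParams()
    base = brute_force_likelihood(x, y, t, af, ecc, L)
    perm = rng.permutation(n)
    permuted = brute_force_likelihood(x[perm], y[perm], t[perm], af, ecc, L)
    assert np.allclose(permuted, base[perm], rtol=1e-12)
    # tuples of pairwise-distinct edges are a strict subset of the matrix paths
    distinct = brute_force_likelihood(x, y, t, af, ecc, L, distinct=True)
    assert np.all(distinct <= base + 1e-300)
    assert not np.allclose(distinct, base, rtol=1e-6, atol=0.0)


def test_brute_force_guard():
    with pytest.raises(ValueError):
        brute_force_likelihood(np.zeros(20), np.zeros(20), np.zeros(20),
                               AFParams(0.3, 0.3), EccParams(), 3)


def _stimulus_from(xl, yl, tl, xr, yr, tr, target="left", L=3):
    x = np.concatenate([xl, xr])
    y = np.concatenate([yl, yr])
    t = np.concatenate([tl, tr])
    n = len(x)
    return Stimulus(x=x, y=y, theta=t, role=np.array(["background"] * n, dtype=object),
                    contour_order=np.full(n, -1), target_side=target, L=L)


def test_decide_2afc_symmetric_stimulus_is_fair_coin():
    """Hemifields with identical relative geometry give an exact evidence tie,
    resolved by a fair seeded coin."""
    rng = np.random.default_rng(6)
    # exactly representable coordinates: the right hemifield is a pure
    # translation of the left, so pair geometry is bitwise identical
    xl = -np.round(rng.uniform(2, 8, 8) * 4) / 4
    yl = np.round(rng.uniform(-5, 5, 8) * 4) / 4
    tl = rng.uniform(0, 2 * np.pi, 8)
    stim = _stimulus_from(xl, yl, tl, xl + 12.0, yl, tl)
    af, ecc = AFParams(0.3, 0.4), EccParams()  # amplitude 0: no ecc asymmetry
    _, (bl, br) = decide_2afc(stim, af, ecc, 3, np.random.default_rng(0))
    assert bl == br
    responses = [decide_2afc(stim, af, ecc, 3, np.random.default_rng(s))[0]
                 for s in range(100)]
    n_left = responses.count("left")
    assert 30 <= n_left <= 70


def test_decide_2afc_strong_signal():
    af = AFParams(0.05, 0.05)
    ecc = EccParams()
    rng = np.random.default_rng(7)
    correct = 0
    for _ in range(50):
        xl = np.arange(-8.0, -2.0)  # colinear 6-chain
        yl = np.full(6, rng.uniform(-3, 3))
        tl = np.zeros(6)
        xr = rng.uniform(2, 8, 6)
        yr = rng.uniform(-5, 5, 6)
        tr = rng.uniform(0, 2 * np.pi, 6)
        stim = _stimulus_from(xl, yl, tl, xr, yr, tr, target="left", L=4)
        resp, _ = decide_2afc(stim, af, ecc, 4, rng)
        correct += resp == "left"
    assert correct >= 49


def test_configuration_count_normalisation_cancels_at_equal_n():
    rng = np.random.default_rng(8)
    xl = -rng.uniform(1, 8, 7)
    xr = rng.uniform(1, 8, 7)
    stim = _stimulus_from(xl, rng.uniform(-5, 5, 7), rng.uniform(0, 2 * np.pi, 7),
                          xr, rng.uniform(-5, 5, 7), rng.uniform(0, 2 * np.pi, 7))
    af, ecc = AFParams(0.3, 0.4), EccParams()
    _, (bl, br) = decide_2afc(stim, af, ecc, 3, rng)
    # unnormalised sums order the same way because M_X is a common factor
    m = math.perm(7, 3)
    assert (bl * m > br * m) == (bl > br)


def test_hemifield_too_small_error():
    stim = _stimulus_from(np.array([-1.0, -2.0]), np.zeros(2), np.zeros(2),
                          np.array([1.0, 2.0, 3.0]), np.zeros(3), np.zeros(3), L=3)
    with pytest.raises(ValueError):
        hemifield_evidence(*stim.hemifield("left"), AFParams(0.3, 0.3), EccParams(), 3)


def test_soa_mapping_largest_soa_gives_full_iterations():
    for L in (5, 8, 13):
        d_bar = 13.9 / (L - 1)
        assert n_iterations_for_soa(200.0, L, SOAMap(d_bar=d_bar)) == L - 1
        assert n_iterations_for_soa(1.0, L, SOAMap(d_bar=d_bar)) == 1


def test_dynamics_contour_above_background(small_ensemble):
    spec, stims = small_ensemble
    traj = contour_likelihood_dynamics(stims, spec.af, EccParams(), "unidirectional")
    assert traj.shape == (spec.L, spec.L + 1)
    assert traj[-1, spec.L] < traj[-1, :spec.L].mean()


def test_observer_estimator_api(small_ensemble):
    spec, stims = small_ensemble
    obs = ContourObserver(sigma_align=0.25, sigma_curv=0.35)
    params = obs.get_params()
    assert params["sigma_align"] == 0.25
    obs.set_params(amplitude=0.3)
    obs.fit()
    resp = obs.predict(stims)
    assert set(resp) <= {"left", "right"}
    assert 0.0 <= obs.score(stims) <= 1.0
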