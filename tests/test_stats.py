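"""Identical-response null, mid-p excess correlation, prototypes, shuffles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from afcontour.stats import (DECISION_COLUMNS, identical_responses, null_pmf,
                             null_pmf_enumerated, performance_score,
                             phi_human_human, phi_model_human, phi_pair,
                             prototype_observers, shuffle_significance,
                             validate_decision_table)


def _table(rows):
    return pd.DataFrame(rows, columns=DECISION_COLUMNS)


def _block(obs, responses, targets, cond="c0", soa=200.0):
    return _table([
        {"observer_id": obs, "condition": cond, "stimulus_id": f"s{i}", "soa": soa,
         "response": r, "correct": int(r == t)}
        for i, (r, t) in enumerate(zip(responses, targets))
    ])


def test_null_pmf_worked_example():
    n = null_pmf(4, 3, 2)
    assert list(n.support) == [1, 3]
    assert np.allclose(n.pmf, [0.5, 0.5])
    assert phi_pair(3, n) == pytest.approx(0.75)
    assert phi_pair(1, n) == pytest.approx(0.25)


def test_null_pmf_degenerate_all_correct():
    n = null_pmf(6, 6, 4)
    assert list(n.support) == [4]
    assert n.pmf[0] == pytest.approx(1.0)
    # single-atom null: phi is 0.5 by the continuity correction
    assert phi_pair(4, n) == pytest.approx(0.5)


def test_null_pmf_invalid_counts():
    with pytest.raises(ValueError):
        null_pmf(4, 5, 2)


@given(st.integers(1, 50), st.data())
@settings(deadline=None, max_examples=60, derandomize=True)
def test_null_pmf_parity_and_normalisation(S, data):
    n_a = data.draw(st.integers(0, S))
    n_b = data.draw(st.integers(0, S))
    null = null_pmf(S, n_a, n_b)
    assert null.pmf.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all((null.support - (S - n_a - n_b)) % 2 == 0)
    assert null.support.max() <= S


@given(st.integers(1, 40), st.data())
@settings(deadline=None, max_examples=40, derandomize=True)
def test_mid_p_expectation_is_half(S, data):
    n_a = data.draw(st.integers(0, S))
    n_b = data.draw(st.integers(0, S))
    null = null_pmf(S, n_a, n_b)
    e = sum(p * phi_pair(k, null) for k, p in zip(null.support, null.pmf))
    assert e == pytest.approx(0.5, abs=1e-12)


def test_null_pmf_matches_enumeration_spot():
    for S, n_a, n_b in [(5, 2, 4), (7, 3, 3), (8, 6, 1)]:
        a, b = null_pmf(S, n_a, n_b), null_pmf_enumerated(S, n_a, n_b)
        assert np.array_equal(a.support, b.support)
        assert np.allclose(a.pmf, b.pmf, atol=1e-12)


def test_identical_responses_examples():
    t = ["left", "left", "right", "right"]
    a = _block("a", ["left", "left", "right", "left"], t)
    b = _block("b", ["left", "left", "right", "right"], t)
    assert identical_responses(a, a) == 4
    assert identical_responses(a, b) == 3
    comp = _block("c", ["right", "right", "left", "right"], t)
    assert identical_responses(a, comp) == 0


def test_performance_score_examples():
    targets = ["left", "right"] * 3
    rows = []
    for cond, (model_correct, human_correct) in zip("abc", [(6, 4), (5, 5), (2, 6)]):
        model_resp = [t if i < model_correct else ("right" if t == "left" else "left")
                      for i, t in enumerate(targets)]
        human_resp = [t if i < human_correct else ("right" if t == "left" else "left")
                      for i, t in enumerate(targets)]
        for obs, resp in (("model", model_resp), ("h1", human_resp)):
            for i, (r, t) in enumerate(zip(resp, targets)):
                rows.append({"observer_id": obs, "condition": cond, "stimulus_id": f"s{i}",
                             "soa": 200.0, "response": r, "correct": int(r == t)})
    table = _table(rows)
    model = table[table.observer_id == "model"]
    humans = table[table.observer_id == "h1"]
    assert performance_score(model, humans) == pytest.approx(2 / 3)  # win, tie, loss
    assert performance_score(humans, humans) == 1.0  # ties count as reaching


def _random_panel(rng, n_obs=4, n_cond=30, S=24, p_correct=0.7, prefix="h"):
    rows = []
    for c in range(n_cond):
        targets = rng.choice(["left", "right"], S)
        for m in range(n_obs):
            correct = rng.random(S) < p_correct
            resp = np.where(correct, targets,
                            np.where(targets == "left", "right", "left"))
            for i in range(S):
                rows.append({"observer_id": f"{prefix}{m}", "condition": f"c{c}",
                             "stimulus_id": f"c{c}s{i}", "soa": 200.0,
                             "response": resp[i], "correct": int(correct[i])})
    return _table(rows)


def test_independent_observers_phi_near_half():
    table = _random_panel(np.random.default_rng(0), n_obs=4, n_cond=60, S=24)
    phi, pair = phi_human_human(table)
    assert phi == pytest.approx(0.5, abs=0.02)
    assert np.allclose(pair.to_numpy(), pair.to_numpy().T, equal_nan=True)


def test_model_copy_of_human_has_high_phi():
    humans = _random_panel(np.random.default_rng(1), n_obs=3, n_cond=20, S=24)
    model = humans[humans.observer_id == "h0"].copy()
    model["observer_id"] = "model"
    assert phi_model_human(model, humans) > 0.6


def test_prototypes_identical_observers():
    rng = np.random.default_rng(2)
    base = _random_panel(rng, n_obs=1, n_cond=10, S=16, prefix="x")
    parts = []
    for m in range(3):
        t = base.copy()
        t["observer_id"] = f"h{m}"
        parts.append(t)
    humans = pd.concat(parts, ignore_index=True)
    protos, benchmark = prototype_observers(humans, rng)
    # prototypes equal the observers; Phi = 1 - 0.5*P(k=S) per condition
    expect = []
    for _, block in humans[humans.observer_id == "h0"].groupby("condition"):
        n = null_pmf(len(block), int(block.correct.sum()), int(block.correct.sum()))
        expect.append(1.0 - 0.5 * n.pmf[n.support == len(block)].sum())
    assert benchmark == pytest.approx(np.mean(expect), abs=1e-12)


def test_prototypes_beat_single_humans_on_shared_structure():
    """Majority prototypes are a noise-reduced benchmark on correlated panels."""
    rng = np.random.default_rng(3)
    n_cond, S = 25, 24
    rows = []
    for c in range(n_cond):
        targets = rng.choice(["left", "right"], S)
        shared = rng.random(S) < 0.75  # latent per-stimulus difficulty
        base = np.where(shared, targets, np.where(targets == "left", "right", "left"))
        for m in range(5):
            flip = rng.random(S) < 0.15
            resp = np.where(flip, np.where(base == "left", "right", "left"), base)
            for i in range(S):
                rows.append({"observer_id": f"h{m}", "condition": f"c{c}",
                             "stimulus_id": f"c{c}s{i}", "soa": 200.0,
                             "response": resp[i], "correct": int(resp[i] == targets[i])})
    humans = _table(rows)
    _, benchmark = prototype_observers(humans, rng)
    phi_hh, _ = phi_human_human(humans)
    assert benchmark > phi_hh > 0.5


def test_shuffle_preserves_counts_and_centres_phi():
    rng = np.random.default_rng(4)
    humans = _random_panel(rng, n_obs=3, n_cond=15, S=16)
    before = humans.groupby(["condition", "observer_id"])["correct"].sum()
    threshold, surrogates = shuffle_significance(humans, humans, 120, 0.05, rng)
    after = humans.groupby(["condition", "observer_id"])["correct"].sum()
    assert before.equals(after)  # input untouched
    assert np.mean(surrogates) == pytest.approx(0.5, abs=0.02)
    assert threshold > 0.5


def test_validate_rejects_mismatched_stimulus_sets():
    t = ["left", "right"]
    a = _block("a", ["left", "right"], t)
    b = _block("b", ["left", "right"], t)
    b.loc[1, "stimulus_id"] = "sX"
    with pytest.raises(ValueError):
        validate_decision_table(pd.concat([a, b], ignore_index=True))
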