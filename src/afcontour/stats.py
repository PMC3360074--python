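"""Decision-correlation statistics for 2-AFC contour detection.

Decision tables are pandas DataFrames with one row per (observer, stimulus):
columns ``observer_id``, ``condition``, ``stimulus_id``, ``soa``,
``response`` ("left"/"right") and ``correct`` (0/1).  All statistics operate
per condition, where every observer saw the same stimulus set.

The central quantity is the excess correlation Phi: for two observers with
n_a and n_b correct responses out of S trials, the independence null places
the two correct-sets uniformly at random, so the both-correct overlap m is
hypergeometric and the identical-response count is k = S - n_a - n_b + 2*m
(both-correct *and* both-wrong stimuli yield identical responses in 2-AFC).
Phi is the mid-p probability that the null produces fewer identical
responses than observed; its expectation under the null is exactly 1/2, so
Phi > 1/2 signals stimulus-locked agreement beyond what performance alone
explains.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "DECISION_COLUMNS",
    "IdenticalResponseNull",
    "validate_decision_table",
    "performance_score",
    "identical_responses",
    "null_pmf",
    "null_pmf_enumerated",
    "phi_pair",
    "phi_between_tables",
    "phi_human_human",
    "phi_model_human",
    "prototype_observers",
    "shuffle_significance",
]

DECISION_COLUMNS = ["observer_id", "condition", "stimulus_id", "soa", "response", "correct"]


class AlignmentError(ValueError):
    """Observer blocks do not share the same stimulus set."""


@dataclass(frozen=True)
class IdenticalResponseNull:
    """Exact null over the identical-response count k of two observers.

    Support satisfies k = S - n_a - n_b + 2*m with hypergeometric overlap m,
    hence the parity constraint k == S - n_a - n_b (mod 2).
    """

    S: int
    n_a: int
    n_b: int
    support: np.ndarray
    pmf: np.ndarray


def validate_decision_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and the shared-stimulus-set invariant; return the table."""
    missing = [c for c in DECISION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"decision table missing column(s): {', '.join(missing)}")
    for (cond, soa), block in table.groupby(["condition", "soa"]):
        sets = block.groupby("observer_id")["stimulus_id"].apply(frozenset)
        if sets.nunique() > 1:
            raise AlignmentError(
                f"observers saw different stimulus sets in condition {cond!r}, soa {soa!r}"
            )
    return table


def _condition_counts(table: pd.DataFrame) -> pd.DataFrame:
    return table.groupby(["condition", "soa", "observer_id"])["correct"].sum().reset_index()


def performance_score(model: pd.DataFrame, humans: pd.DataFrame) -> float:
    """Fraction of conditions where the model reaches or surpasses mean human
    correct counts (ties count as reaching)."""
    mc = model.groupby(["condition", "soa"])["correct"].sum()
    hc = humans.groupby(["condition", "soa", "observer_id"])["correct"].sum()
    hmean = hc.groupby(["condition", "soa"]).mean()
    joined = pd.concat([mc.rename("model"), hmean.rename("human")], axis=1)
    if joined.isna().any().any():
        raise AlignmentError("model and human tables cover different conditions")
    return float((joined["model"] >= joined["human"]).mean())


def identical_responses(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Number of stimuli on which two observer blocks gave the same response."""
    am = a.set_index("stimulus_id")["response"]
    bm = b.set_index("stimulus_id")["response"]
    if set(am.index) != set(bm.index):
        raise AlignmentError("observer blocks cover different stimuli")
    bm = bm.reindex(am.index)
    return int((am == bm).sum())


def null_pmf(S: int, n_a: int, n_b: int) -> IdenticalResponseNull:
    """Exact independence null over identical-response counts.

    The overlap m of the two uniformly random correct-sets follows
    hypergeom(S, n_a, n_b); k = S - n_a - n_b + 2*m.
    """
    if not (0 <= n_a <= S and 0 <= n_b <= S):
        raise ValueError("correct counts must lie in [0, S]")
    m_lo = max(0, n_a + n_b - S)
    m_hi = min(n_a, n_b)
    m = np.arange(m_lo, m_hi + 1)
    pmf = hypergeom.pmf(m, S, n_a, n_b)
    pmf = pmf / pmf.sum()
    k = S - n_a - n_b + 2 * m
    return IdenticalResponseNull(S=S, n_a=n_a, n_b=n_b, support=k, pmf=pmf)


def null_pmf_enumerated(S: int, n_a: int, n_b: int) -> IdenticalResponseNull:
    """Brute-force oracle: enumerate all C(S,n_a)*C(S,n_b) correct-set placements."""
    if S > 12:
        raise ValueError("enumeration oracle restricted to S <= 12")
    counts: dict[int, int] = {}
    total = 0
    trials = range(S)
    for A in itertools.combinations(trials, n_a):
        sa = set(A)
        for B in itertools.combinations(trials, n_b):
            m = len(sa.intersection(B))
            k = S - n_a - n_b + 2 * m
            counts[k] = counts.get(k, 0) + 1
            total += 1
    ks = np.array(sorted(counts))
    pmf = np.array([counts[k] / total for k in ks])
    return IdenticalResponseNull(S=S, n_a=n_a, n_b=n_b, support=ks, pmf=pmf)


def phi_pair(k_observed: int, null: IdenticalResponseNull) -> float:
    """Mid-p excess correlation: P(k' < k_obs) + 0.5 * P(k' = k_obs).

    The continuity correction makes the expectation exactly 1/2 when k is
    drawn from the null itself.
    """
    k = int(k_observed)
    if k < null.support.min() or k > null.support.max():
        warnings.warn("observed identical-response count outside null support range; clamped",
                      stacklevel=2)
        k = int(np.clip(k, null.support.min(), null.support.max()))
    # k may fall between support atoms (parity miss, e.g. for shuffled
    # surrogates where responses are decoupled from stimuli); the point mass
    # is then simply zero
    below = null.pmf[null.support < k].sum()
    at = null.pmf[null.support == k].sum()
    return float(below + 0.5 * at)


def _phi_one_pair_block(a: pd.DataFrame, b: pd.DataFrame) -> float:
    S = len(a)
    k = identical_responses(a, b)
    null = null_pmf(S, int(a["correct"].sum()), int(b["correct"].sum()))
    return phi_pair(k, null)


def phi_between_tables(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Mean phi_pair over all (observer-in-a, observer-in-b) pairs and conditions."""
    vals = []
    for (cond, soa), block_a in table_a.groupby(["condition", "soa"]):
        block_b = table_b[(table_b["condition"] == cond) & (table_b["soa"] == soa)]
        if block_b.empty:
            continue
        for oa, ga in block_a.groupby("observer_id"):
            for ob, gb in block_b.groupby("observer_id"):
                vals.append(_phi_one_pair_block(ga, gb))
    if not vals:
        raise AlignmentError("tables share no conditions")
    return float(np.mean(vals))


def phi_human_human(humans: pd.DataFrame):
    """Mean excess correlation over all unordered human pairs, plus the
    per-pair matrix (a symmetric DataFrame, as reported pairwise in studies)."""
    observers = sorted(humans["observer_id"].unique())
    if len(observers) < 2:
        raise ValueError("need at least two observers")
    pair_means = pd.DataFrame(np.nan, index=observers, columns=observers)
    all_vals = []
    for oa, ob in itertools.combinations(observers, 2):
        vals = []
        for (cond, soa), block in humans.groupby(["condition", "soa"]):
            ga = block[block["observer_id"] == oa]
            gb = block[block["observer_id"] == ob]
            if ga.empty or gb.empty:
                continue
            vals.append(_phi_one_pair_block(ga, gb))
        m = float(np.mean(vals))
        pair_means.loc[oa, ob] = pair_means.loc[ob, oa] = m
        all_vals.extend(vals)
    return float(np.mean(all_vals)), pair_means


def phi_model_human(model: pd.DataFrame, humans: pd.DataFrame) -> float:
    """Mean excess correlation between one model and every human observer."""
    return phi_between_tables(model, humans)


def prototype_observers(humans: pd.DataFrame, rng: np.random.Generator):
    """Leave-one-out majority-vote prototypes and their benchmark correlation.

    For each observer m, prototype m responds with the stimulus-wise majority
    of the other observers (ties broken by a seeded coin flip).  The
    benchmark is the mean phi_pair between each prototype and its own human
    counterpart — the noise-reduced ceiling a noise-free model can reach.
    """
    observers = sorted(humans["observer_id"].unique())
    if len(observers) < 3:
        raise ValueError("need at least three observers for leave-one-out prototypes")
    proto_rows = []
    vals = []
    n_ties = 0
    for m in observers:
        others = humans[humans["observer_id"] != m]
        for (cond, soa), block in others.groupby(["condition", "soa"]):
            pivot = block.pivot(index="stimulus_id", columns="observer_id", values="response")
            n_left = (pivot == "left").sum(axis=1)
            n_right = (pivot == "right").sum(axis=1)
            resp = np.where(n_left > n_right, "left",
                            np.where(n_right > n_left, "right", ""))
            ties = resp == ""
            n_ties += int(ties.sum())
            if ties.any():
                coin = rng.random(int(ties.sum())) < 0.5
                resp[ties] = np.where(coin, "left", "right")
            own = humans[(humans["observer_id"] == m)
                         & (humans["condition"] == cond) & (humans["soa"] == soa)]
            # the true target side is recovered from any observer's
            # (response, correct) pair; used to score the prototype
            own_idx = own.set_index("stimulus_id")
            proto = pd.Series(resp, index=pivot.index).reindex(own_idx.index)
            truth = np.where(own_idx["correct"].astype(bool),
                             own_idx["response"],
                             np.where(own_idx["response"] == "left", "right", "left"))
            proto_block = pd.DataFrame({
                "observer_id": f"proto_{m}",
                "condition": cond,
                "stimulus_id": own_idx.index,
                "soa": soa,
                "response": proto.values,
                "correct": (proto.values == truth).astype(int),
            })
            proto_rows.append(proto_block)
            own_block = own_idx.reset_index()
            own_block["observer_id"] = m
            vals.append(_phi_one_pair_block(proto_block, own_block))
    prototypes = pd.concat(proto_rows, ignore_index=True)
    prototypes.attrs["n_ties"] = n_ties
    return prototypes, float(np.mean(vals))


def shuffle_significance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                         n_surrogates: int, alpha: float,
                         rng: np.random.Generator):
    """Permutation threshold Phi_sig for excess correlations.

    Each surrogate shuffles every observer's decisions across the stimuli
    within each condition: the correctness pattern is permuted and the
    left/right response re-derived from each stimulus's true target side, so
    per-observer per-condition correct counts are preserved exactly while
    any stimulus-locked agreement is destroyed.  Returns the (1 - alpha)
    quantile and the surrogate values.
    """
    if n_surrogates < 100:
        warnings.warn("fewer than 100 surrogates: threshold estimate is coarse",
                      stacklevel=2)

    flip = {"left": "right", "right": "left"}

    def shuffled(table):
        parts = []
        for _, block in table.groupby(["condition", "soa", "observer_id"]):
            block = block.copy()
            target = np.where(block["correct"].astype(bool), block["response"],
                              block["response"].map(flip))
            correct = block["correct"].to_numpy()[rng.permutation(len(block))]
            block["correct"] = correct
            block["response"] = np.where(correct.astype(bool), target,
                                         pd.Series(target).map(flip))
            parts.append(block)
        return pd.concat(parts, ignore_index=True)

    surrogate_phis = np.array([
        phi_between_tables(shuffled(table_a), shuffled(table_b))
        for _ in range(n_surrogates)
    ])
    threshold = float(np.quantile(surrogate_phis, 1.0 - alpha))
    return threshold, surrogate_phis
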