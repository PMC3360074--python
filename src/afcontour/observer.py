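"""Ideal and optimal contour observers.

Inference inverts the generative contour process.  For each edge i of a
hemifield one computes the likelihood b_i that i is the starting edge of an
L-element contour; summing over starting edges and normalising by the count
of ordered edge configurations gives the hemifield evidence compared in the
2-AFC decision.

The likelihoods are accumulated by iterating the link matrix Q (pairwise AF
densities) L-1 times:

    b(0) = w,    b(n) = W Q b(n-1)        (W = diag(w))

where w are per-edge salience weights modelling eccentricity-dependent edge
visibility, w(eps) = 1 - a*(eps/eps_max)**gamma.  With a = 0 the weights are
identically 1 and the iteration reduces exactly to the unweighted ideal
observer.  Each matrix multiplication extends every candidate path by one
edge, so n iterations accumulate evidence for contours of n+1 elements; the
mapping to stimulus-onset asynchrony assumes a constant propagation speed so
that one iteration costs the time to bridge the mean element distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .af import (
    AFParams,
    DEFAULT_D_MAX,
    DegenerateGeometryError,
    angular_density,
    pairwise_geometry,
    radial_density,
)

__all__ = [
    "EccParams",
    "SOAMap",
    "salience_weights",
    "link_matrix",
    "starting_likelihoods",
    "brute_force_likelihood",
    "hemifield_evidence",
    "decide_2afc",
    "n_iterations_for_soa",
    "soa_performance_curve",
    "contour_likelihood_dynamics",
    "ContourObserver",
]

#: Maximum eccentricity of the default setup, DVA.
DEFAULT_EPS_MAX = 16.66

#: Propagation speed of the default SOA mapping: 13.9 DVA (the average
#: contour length) per 200 ms (the largest SOA).
DEFAULT_SPEED = 13.9 / 200.0


@dataclass(frozen=True)
class EccParams:
    """Eccentricity scaling of edge salience.

    ``amplitude`` (a) sets how strongly salience drops towards the maximum
    eccentricity; ``gamma`` sets the concavity (gamma < 1 concave down,
    gamma > 1 concave up); ``eps_max`` is the largest eccentricity of the
    display in DVA.
    """

    amplitude: float = 0.0
    gamma: float = 1.0
    eps_max: float = DEFAULT_EPS_MAX

    def __post_init__(self):
        if not (0.0 <= self.amplitude < 1.0):
            raise ValueError("amplitude must lie in [0, 1)")
        if not self.gamma > 0:
            raise ValueError("gamma must be strictly positive")

    def to_dict(self) -> dict:
        return {"amplitude": self.amplitude, "gamma": self.gamma, "eps_max": self.eps_max}


@dataclass(frozen=True)
class SOAMap:
    """Maps stimulus-onset asynchrony to an iteration depth.

    One matrix iteration bridges the mean element distance ``d_bar`` at
    propagation speed ``v`` (DVA/ms), so an SOA of t ms corresponds to
    ``round(t * v / d_bar)`` iterations, clamped to [1, L-1].
    """

    v: float = DEFAULT_SPEED
    d_bar: float = 2.0

    def __post_init__(self):
        if not self.v > 0:
            raise ValueError("propagation speed must be strictly positive")


def salience_weights(x, y, ecc: EccParams) -> np.ndarray:
    """Per-edge salience w = 1 - a*(eps/eps_max)**gamma, in (0, 1]."""
    eps = np.hypot(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    if np.any(eps > ecc.eps_max):
        warnings.warn("eccentricities beyond eps_max clamped", stacklevel=2)
        eps = np.minimum(eps, ecc.eps_max)
    w = 1.0 - ecc.amplitude * (eps / ecc.eps_max) ** ecc.gamma
    return np.clip(w, np.finfo(float).tiny, 1.0)


def link_matrix(x, y, theta, af: AFParams, d_max: float = DEFAULT_D_MAX) -> np.ndarray:
    """Matrix Q of pairwise AF densities, Q[i, j] = af_density(e_i -> e_j).

    The diagonal is zero (an edge never links to itself).  Coincident
    distinct edges make the geometry degenerate and raise an error.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two edges")
    D, PHI, DTHETA = pairwise_geometry(x, y, theta)
    off = ~np.eye(n, dtype=bool)
    if np.any(D[off] == 0.0):
        i, j = np.argwhere((D == 0.0) & off)[0]
        raise DegenerateGeometryError(f"edges {i} and {j} coincide")
    Q = radial_density(D, af, d_max) * angular_density(PHI, DTHETA, af)
    np.fill_diagonal(Q, 0.0)
    return Q


def starting_likelihoods(Q: np.ndarray, w: np.ndarray, L: int) -> np.ndarray:
    """All iterates b(0)..b(L-1) of the weighted matrix iteration.

    Returns an array of shape (L, n); row n holds the per-edge likelihoods of
    being the starting edge of a contour of n+1 elements.  With w == 1 this
    is the plain unweighted iteration of the ideal observer.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    w = np.asarray(w, dtype=float)
    if Q.shape[0] != Q.shape[1] or Q.shape[0] != w.shape[0]:
        raise ValueError("shape mismatch between Q and w")
    out = np.empty((L, w.shape[0]))
    out[0] = w
    for n in range(1, L):
        out[n] = w * (Q @ out[n - 1])
    return out


def brute_force_likelihood(
    x, y, theta, af: AFParams, ecc: EccParams, L: int,
    d_max: float = DEFAULT_D_MAX, distinct: bool = False,
) -> np.ndarray:
    """Starting-edge likelihoods by explicit path enumeration.

    Sums the weighted product of transition densities over all ordered
    L-tuples of edges with no immediately repeated element — exactly the
    paths accumulated by the matrix iteration (whose diagonal is zero) — and
    aggregates by starting edge.  ``distinct=True`` restricts to tuples of
    pairwise-distinct edges, the stricter generative enumeration; for
    contours much shorter than the edge count the two nearly coincide.

    Guarded to small instances (N <= 12, L <= 5); this is the independent
    oracle for :func:`starting_likelihoods`, not a production path.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n > 12 or L > 5:
        raise ValueError("brute force restricted to N <= 12, L <= 5")
    Q = link_matrix(x, y, theta, af, d_max)
    w = salience_weights(x, y, ecc)
    out = np.zeros(n)

    def extend(path_weight: float, last: int, depth: int, first: int, used):
        if depth == L:
            out[first] += path_weight
            return
        for nxt in range(n):
            if nxt == last:
                continue
            if distinct and nxt in used:
                continue
            extend(path_weight * Q[last, nxt] * w[nxt], nxt, depth + 1, first,
                   used | {nxt} if distinct else used)

    for i in range(n):
        extend(w[i], i, 1, i, {i} if distinct else None)
    return out


def _ordered_configuration_count(n: int, L: int) -> float:
    """M_X = N*(N-1)*...*(N-L+1), the number of ordered contour configurations."""
    if n < L:
        raise ValueError(f"hemifield with {n} edges cannot hold an {L}-element contour")
    return float(math.perm(n, L))


def hemifield_evidence(x, y, theta, af, ecc, L, n_iter=None, d_max=DEFAULT_D_MAX) -> float:
    """Normalised evidence for one hemifield: sum_i b_i(n) / M_X."""
    n_iter = L - 1 if n_iter is None else int(n_iter)
    if not (1 <= n_iter <= L - 1):
        raise ValueError("n_iter must lie in [1, L-1]")
    Q = link_matrix(x, y, theta, af, d_max)
    w = salience_weights(x, y, ecc)
    b = starting_likelihoods(Q, w, n_iter + 1)[-1]
    return float(b.sum() / _ordered_configuration_count(len(b), L))


def decide_2afc(stimulus, af: AFParams, ecc: EccParams, L: int, rng, n_iter=None,
                d_max: float = DEFAULT_D_MAX):
    """2-AFC decision: which hemifield more likely contains the contour.

    Returns ``(response, (B_left, B_right))`` with response "left"/"right";
    an exact tie is broken by a fair coin from ``rng``.
    """
    evidence = {}
    for side in ("left", "right"):
        xs, ys, ts = stimulus.hemifield(side)
        evidence[side] = hemifield_evidence(xs, ys, ts, af, ecc, L, n_iter, d_max)
    if evidence["left"] > evidence["right"]:
        resp = "left"
    elif evidence["right"] > evidence["left"]:
        resp = "right"
    else:
        resp = "left" if rng.random() < 0.5 else "right"
    return resp, (evidence["left"], evidence["right"])


def n_iterations_for_soa(soa_ms: float, L: int, soa_map: SOAMap) -> int:
    """Iteration depth for a given SOA: round(SOA*v/d_bar), clamped to [1, L-1]."""
    n = int(round(soa_ms * soa_map.v / soa_map.d_bar))
    return int(np.clip(n, 1, L - 1))


def soa_performance_curve(stimuli, af, ecc, L, soa_list, soa_map: SOAMap, rng,
                          d_max: float = DEFAULT_D_MAX):
    """Fraction of correct 2-AFC decisions at each SOA."""
    fractions = []
    for soa in soa_list:
        n_iter = n_iterations_for_soa(soa, L, soa_map)
        correct = 0
        for stim in stimuli:
            resp, _ = decide_2afc(stim, af, ecc, L, rng, n_iter, d_max)
            correct += resp == stim.target_side
        fractions.append(correct / len(stimuli))
    return np.array(fractions)


def contour_likelihood_dynamics(stimuli, af: AFParams, ecc: EccParams, mode: str = "unidirectional",
                                d_max: float = DEFAULT_D_MAX):
    """Average per-edge likelihood time courses grouped by contour position.

    For each stimulus, the link matrix of the target hemifield is iterated
    L-1 times; likelihoods are averaged within each contour position 1..L and
    over background edges.  ``mode="bidirectional"`` symmetrises the link
    matrix, Q <- (Q + Q.T)/2, making the interaction invariant to the
    traversal direction of each edge pair.

    Returns an (L, L+1) array: rows are iterations 0..L-1, the first L
    columns the contour positions, the last column the background mean.
    """
    if mode not in ("unidirectional", "bidirectional"):
        raise ValueError("mode must be 'unidirectional' or 'bidirectional'")
    acc = None
    for stim in stimuli:
        side = stim.target_side
        sel = stim.hemifield_mask(side)
        xs, ys, ts = stim.x[sel], stim.y[sel], stim.theta[sel]
        order = stim.contour_order[sel]
        L = int(order.max()) + 1
        Q = link_matrix(xs, ys, ts, af, d_max)
        if mode == "bidirectional":
            Q = 0.5 * (Q + Q.T)
        w = salience_weights(xs, ys, ecc)
        b = starting_likelihoods(Q, w, L)  # (L, n)
        traj = np.empty((L, L + 1))
        for pos in range(L):
            traj[:, pos] = b[:, order == pos].mean(axis=1)
        traj[:, L] = b[:, order < 0].mean(axis=1)
        acc = traj if acc is None else acc + traj
    return acc / len(stimuli)


class ContourObserver(BaseEstimator):
    """Probabilistic contour observer as a scikit-learn style classifier.

    A fixed-parameter member of the ideal-observer model class: an
    association field (``sigma_align``, ``sigma_curv``, ``lambda_radial``),
    an eccentricity scaling (``amplitude``, ``gamma``, ``eps_max``), and an
    optional iteration depth ``n_iter`` (``None`` = full, L-1 iterations).
    ``predict`` maps stimuli to "left"/"right" hemifield responses; with
    parameters matching the generating process it is the ideal observer.
    """

    def __init__(self, sigma_align=0.25, sigma_curv=0.35, lambda_radial=10.0,
                 amplitude=0.0, gamma=1.0, eps_max=DEFAULT_EPS_MAX,
                 n_iter=None, d_max=DEFAULT_D_MAX, seed=0):
        self.sigma_align = sigma_align
        self.sigma_curv = sigma_curv
        self.lambda_radial = lambda_radial
        self.amplitude = amplitude
        self.gamma = gamma
        self.eps_max = eps_max
        self.n_iter = n_iter
        self.d_max = d_max
        self.seed = seed

    def fit(self, X=None, y=None):
        """Validate parameters and freeze them into fitted attributes.

        The observer has no free parameters to estimate from data — fitting
        in the model-selection sense happens in
        :class:`afcontour.search.ObserverGridSearch`.
        """
        self.af_ = AFParams(self.sigma_align, self.sigma_curv, self.lambda_radial)
        self.ecc_ = EccParams(self.amplitude, self.gamma, self.eps_max)
        self.rng_ = np.random.default_rng(self.seed)
        return self

    def _ensure_fitted(self):
        if not hasattr(self, "af_"):
            self.fit()

    def decision_likelihoods(self, stimulus, L=None):
        """(B_left, B_right) hemifield evidence pair for one stimulus."""
        self._ensure_fitted()
        L = stimulus.L if L is None else L
        _, pair = decide_2afc(stimulus, self.af_, self.ecc_, L, self.rng_, self.n_iter, self.d_max)
        return pair

    def predict(self, stimuli):
        """Respond "left"/"right" for each stimulus."""
        self._ensure_fitted()
        out = []
        for stim in stimuli:
            resp, _ = decide_2afc(stim, self.af_, self.ecc_, stim.L, self.rng_,
                                  self.n_iter, self.d_max)
            out.append(resp)
        return np.array(out)

    def score(self, stimuli, y=None):
        """Fraction of stimuli whose target hemifield is identified correctly."""
        resp = self.predict(stimuli)
        target = np.array([s.target_side for s in stimuli])
        return float(np.mean(resp == target))
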