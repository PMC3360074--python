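"""Four-parameter search for the optimal contour-integration model.

The optimal model is the fixed-parameter member of the ideal-observer class
(association-field scales sigma_align, sigma_curv; eccentricity scaling
amplitude a and exponent gamma) that best reproduces a set of reference
2-AFC decisions.  Candidates are scored on a grid by two criteria computed
from a single decision pass per candidate:

* ``P_perf`` — fraction of conditions where the candidate reaches or
  surpasses the reference observers' mean correct count;
* ``Phi_MH`` — mean mid-p excess correlation between the candidate's and the
  reference decisions.

Candidates whose performance score falls below ``min_performance_score``
are inadmissible (the performance criterion is necessary: high decision
correlation alone does not guarantee human-level performance); among the
admissible ones the candidate maximising Phi_MH wins.

The per-stimulus pair geometry (distances and the two angular cosines) does
not depend on the candidate, so it is computed once per hemifield and reused
across the whole grid; each candidate evaluation is then a single
exponential over the cached arrays plus L-1 mat-vec products.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0e
from sklearn.base import BaseEstimator

from .af import DEFAULT_D_MAX, pairwise_geometry
from .observer import DEFAULT_EPS_MAX
from .stats import DECISION_COLUMNS, performance_score, phi_model_human

__all__ = ["StimulusCache", "ObserverGridSearch", "decide_cached"]


@dataclass
class StimulusCache:
    """Candidate-independent geometry of one stimulus."""

    sides: dict  # side -> dict(cos_align, cos_curv, d, eps, n)
    target_side: str
    L: int
    condition: str
    stimulus_id: str


def build_cache(stimulus, d_max: float = DEFAULT_D_MAX) -> StimulusCache:
    sides = {}
    for side in ("left", "right"):
        xs, ys, ts = stimulus.hemifield(side)
        D, PHI, DTH = pairwise_geometry(xs, ys, ts)
        off = ~np.eye(len(xs), dtype=bool)
        sides[side] = {
            "cos_align": np.cos((DTH - 2.0 * PHI) / 2.0),
            "cos_curv": np.cos(DTH),
            "d": D,
            "off": off,
            "eps": np.hypot(xs, ys),
            "n": len(xs),
        }
    return StimulusCache(sides=sides, target_side=stimulus.target_side, L=stimulus.L,
                         condition=stimulus.ensemble_id, stimulus_id=stimulus.stimulus_id)


def _evidence(side_cache, kappa1, kappa2, norm_ang, lam, z_rad, a, gamma,
              eps_max, L, d_max) -> float:
    n = side_cache["n"]
    Q = np.exp(
        kappa1 * (side_cache["cos_align"] - 1.0)
        + kappa2 * (side_cache["cos_curv"] - 1.0)
        - side_cache["d"] / lam
    ) * (norm_ang / z_rad)
    Q[side_cache["d"] > d_max] = 0.0
    np.fill_diagonal(Q, 0.0)
    eps = np.minimum(side_cache["eps"], eps_max)
    w = np.clip(1.0 - a * (eps / eps_max) ** gamma, np.finfo(float).tiny, 1.0)
    b = w.copy()
    for _ in range(L - 1):
        b = w * (Q @ b)
    return float(b.sum() / math.perm(n, L))


def decide_cached(cache: StimulusCache, sigma_align, sigma_curv, lam, a, gamma,
                  eps_max=DEFAULT_EPS_MAX, d_max=DEFAULT_D_MAX, rng=None) -> str:
    """2-AFC decision from cached geometry (identical to the observer path)."""
    kappa1 = 4.0 / sigma_align**2  # half-angle alignment factor
    kappa2 = 1.0 / sigma_curv**2
    norm_ang = 1.0 / (4.0 * np.pi**2 * i0e(kappa1) * i0e(kappa2))
    z_rad = lam * (1.0 - math.exp(-d_max / lam))
    ev = {
        side: _evidence(cache.sides[side], kappa1, kappa2, norm_ang, lam, z_rad,
                        a, gamma, eps_max, cache.L, d_max)
        for side in ("left", "right")
    }
    if ev["left"] > ev["right"]:
        return "left"
    if ev["right"] > ev["left"]:
        return "right"
    if rng is None:
        return "left"
    return "left" if rng.random() < 0.5 else "right"


class ObserverGridSearch(BaseEstimator):
    """Grid search over (sigma_align, sigma_curv, amplitude, gamma).

    ``fit(stimuli, reference)`` runs every candidate observer over all
    stimuli (full iteration depth per condition), scores ``Phi_MH`` and
    ``P_perf`` against the reference decision table, and exposes:

    ``phi_map_`` and ``perf_map_``
        4-d arrays indexed (align, curv, amplitude, gamma).
    ``admissible_``
        boolean map of candidates with ``P_perf >= min_performance_score``.
    ``best_params_``, ``best_index_``, ``best_phi_``
        the admissible candidate maximising Phi_MH.  If no candidate is
        admissible the global Phi_MH maximiser is returned with
        ``best_admissible_ = False``.
    """

    def __init__(self, sigma_align_grid=(0.1, 0.2, 0.3, 0.4),
                 sigma_curv_grid=(0.15, 0.3, 0.45, 0.6),
                 amplitude_grid=(0.0, 0.4, 0.8),
                 gamma_grid=(0.5, 1.0, 2.0),
                 lambda_radial=10.0, eps_max=DEFAULT_EPS_MAX,
                 d_max=DEFAULT_D_MAX, min_performance_score=0.5, seed=0):
        self.sigma_align_grid = sigma_align_grid
        self.sigma_curv_grid = sigma_curv_grid
        self.amplitude_grid = amplitude_grid
        self.gamma_grid = gamma_grid
        self.lambda_radial = lambda_radial
        self.eps_max = eps_max
        self.d_max = d_max
        self.min_performance_score = min_performance_score
        self.seed = seed

    def fit(self, stimuli, reference: pd.DataFrame):
        rng = np.random.default_rng(self.seed)
        caches = [build_cache(s, self.d_max) for s in stimuli]
        soa = float(reference["soa"].iloc[0])
        shape = (len(self.sigma_align_grid), len(self.sigma_curv_grid),
                 len(self.amplitude_grid), len(self.gamma_grid))
        self.phi_map_ = np.empty(shape)
        self.perf_map_ = np.empty(shape)
        axes = [self.sigma_align_grid, self.sigma_curv_grid,
                self.amplitude_grid, self.gamma_grid]
        for idx in itertools.product(*(range(len(ax)) for ax in axes)):
            s1 = self.sigma_align_grid[idx[0]]
            s2 = self.sigma_curv_grid[idx[1]]
            a = self.amplitude_grid[idx[2]]
            g = self.gamma_grid[idx[3]]
            rows = []
            for cache in caches:
                resp = decide_cached(cache, s1, s2, self.lambda_radial, a, g,
                                     self.eps_max, self.d_max, rng)
                rows.append({
                    "observer_id": "model",
                    "condition": cache.condition,
                    "stimulus_id": cache.stimulus_id,
                    "soa": soa,
                    "response": resp,
                    "correct": int(resp == cache.target_side),
                })
            model_table = pd.DataFrame(rows, columns=DECISION_COLUMNS)
            self.phi_map_[idx] = phi_model_human(model_table, reference)
            self.perf_map_[idx] = performance_score(model_table, reference)
        self.admissible_ = self.perf_map_ >= self.min_performance_score
        if self.admissible_.any():
            masked = np.where(self.admissible_, self.phi_map_, -np.inf)
            flat = int(np.argmax(masked))
            self.best_admissible_ = True
        else:
            flat = int(np.argmax(self.phi_map_))
            self.best_admissible_ = False
        self.best_index_ = np.unravel_index(flat, shape)
        self.best_phi_ = float(self.phi_map_[self.best_index_])
        self.best_params_ = {
            "sigma_align": self.sigma_align_grid[self.best_index_[0]],
            "sigma_curv": self.sigma_curv_grid[self.best_index_[1]],
            "amplitude": self.amplitude_grid[self.best_index_[2]],
            "gamma": self.gamma_grid[self.best_index_[3]],
        }
        return self
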