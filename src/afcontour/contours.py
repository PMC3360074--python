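"""Sampling finite contours from the Markov process defined by the AF.

A contour of length L starts with an edge placed uniformly in a region with a
uniform direction; each further edge is drawn from the association-field
density conditioned on its predecessor.  Sampling of the relative step
(d, phi, dtheta) is exact:

* ``dtheta`` — its marginal under the angular AF factor is von Mises with
  concentration ``1/sigma_curv**2``;
* ``phi``   — conditioned on ``dtheta``, the half-deviation
  ``psi = (dtheta - 2*phi)/2`` from the forward co-circular continuation is
  von Mises with concentration ``4/sigma_align**2``, and ``phi`` follows
  directly;
* ``d``     — truncated exponential via inverse-CDF.

Steps whose end point leaves the region are resampled (not reflected), which
keeps the angular statistics unbiased; a proposal budget guards against
pathological regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .af import AFParams, DEFAULT_D_MAX, wrap_angle, wrap_direction

__all__ = [
    "Contour",
    "SamplingError",
    "RepairError",
    "sample_step",
    "sample_contour",
    "rebuild_from_steps",
    "repair_overlaps",
]


class SamplingError(RuntimeError):
    """Rejection budget exhausted while sampling a contour."""

    def __init__(self, message: str, attempts: int):
        super().__init__(f"{message} (after {attempts} proposals)")
        self.attempts = attempts


class RepairError(RuntimeError):
    """Permutation budget exhausted while repairing overlaps."""


@dataclass
class Contour:
    """Directed sequence of edges sampled from one association field."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    params_id: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = wrap_direction(np.asarray(self.theta, dtype=float))
        if len(self.x) < 2:
            raise ValueError("a contour needs at least two edges")

    def __len__(self) -> int:
        return len(self.x)

    def steps(self):
        """Relative configurations (d, phi, dtheta) of consecutive pairs."""
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        d = np.hypot(dx, dy)
        phi = wrap_angle(np.arctan2(dy, dx) - self.theta[:-1])
        dtheta = wrap_angle(np.diff(self.theta))
        return d, phi, dtheta

    def reversed(self) -> "Contour":
        """The same contour traversed backwards (directions flipped by pi)."""
        return Contour(
            self.x[::-1].copy(),
            self.y[::-1].copy(),
            wrap_direction(self.theta[::-1] + np.pi),
            self.params_id,
        )


def _truncated_exp(lam: float, lo: float, hi: float, rng: np.random.Generator, size=None):
    """Inverse-CDF draw from exp(-d/lam) restricted to [lo, hi]."""
    a = math.exp(-lo / lam)
    b = math.exp(-hi / lam)
    u = rng.random(size)
    return -lam * np.log(a - u * (a - b))


def sample_step(theta_source, params: AFParams, rng: np.random.Generator, d_range=None, size=None):
    """Draw relative step(s) (d, phi, dtheta) from the AF density.

    ``d_range`` restricts the radial draw to a band (used to pin the mean
    inter-edge spacing of an ensemble); default is (0, DEFAULT_D_MAX].
    """
    lo, hi = d_range if d_range is not None else (0.0, DEFAULT_D_MAX)
    dtheta = rng.vonmises(0.0, params.kappa_curv, size)
    # half-deviation psi = (dtheta - 2*phi)/2 is von Mises; phi single-valued
    psi = rng.vonmises(0.0, params.kappa_align, size)
    phi = wrap_angle(dtheta / 2.0 - psi)
    d = _truncated_exp(params.lambda_radial, lo, hi, rng, size)
    return d, phi, dtheta


def _in_region(x, y, region) -> bool:
    x0, y0, x1, y1 = region
    return (x0 <= x <= x1) and (y0 <= y <= y1)


def sample_contour(
    L: int,
    params: AFParams,
    region,
    rng: np.random.Generator,
    d_range=None,
    start=None,
    max_attempts: int = 100_000,
    params_id: str = "",
) -> Contour:
    """Sample an L-edge contour inside ``region = (x0, y0, x1, y1)``.

    The first edge is uniform in the region with uniform direction unless
    ``start = (x, y, theta)`` is given; each subsequent edge is drawn from
    the AF conditioned on its predecessor, resampling steps that would leave
    the region.
    """
    if L < 2:
        raise ValueError("contour length must be >= 2")
    x0, y0, x1, y1 = region
    if not (x1 > x0 and y1 > y0):
        raise ValueError("region must be non-empty")

    def fresh_start():
        if start is None:
            return rng.uniform(x0, x1), rng.uniform(y0, y1), rng.uniform(0.0, 2.0 * np.pi)
        return start

    # a contour headed into a wall with a concentrated AF may never turn back;
    # after a per-step budget the whole contour is restarted from a new start
    step_budget = 500
    attempts = 0
    while attempts < max_attempts:
        sx, sy, st = fresh_start()
        xs = [sx]
        ys = [sy]
        ts = [st]
        stuck = 0
        while len(xs) < L and attempts < max_attempts:
            d, phi, dtheta = sample_step(ts[-1], params, rng, d_range)
            ang = ts[-1] + phi
            nx = xs[-1] + d * math.cos(ang)
            ny = ys[-1] + d * math.sin(ang)
            attempts += 1
            if _in_region(nx, ny, region):
                xs.append(nx)
                ys.append(ny)
                ts.append(ts[-1] + dtheta)
                stuck = 0
            else:
                stuck += 1
                if stuck >= step_budget:
                    break
        if len(xs) == L:
            return Contour(np.array(xs), np.array(ys), np.array(ts), params_id)
    raise SamplingError("contour step rejection budget exhausted", attempts)


def rebuild_from_steps(start, d, phi, dtheta, params_id: str = "") -> Contour:
    """Reconstruct a contour from a starting edge and a step sequence."""
    sx, sy, st = start
    d = np.asarray(d, dtype=float)
    phi = np.asarray(phi, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    theta = st + np.concatenate([[0.0], np.cumsum(dtheta)])
    ang = theta[:-1] + phi
    x = sx + np.concatenate([[0.0], np.cumsum(d * np.cos(ang))])
    y = sy + np.concatenate([[0.0], np.cumsum(d * np.sin(ang))])
    return Contour(x, y, theta, params_id)


def _min_nonconsecutive_distance(contour: Contour) -> float:
    pts = np.column_stack([contour.x, contour.y])
    dm = squareform(pdist(pts))
    n = len(contour)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n - 1):
        mask[i, i + 1] = mask[i + 1, i] = False
    return float(dm[mask].min()) if mask.any() else np.inf


def repair_overlaps(
    contour: Contour,
    min_separation: float,
    rng: np.random.Generator,
    max_permutations: int = 2000,
) -> Contour:
    """Remove overlaps between non-consecutive edges by permuting the steps.

    Shuffles the sequence of relative (d, phi, dtheta) steps and rebuilds the
    contour from the same starting edge until every non-consecutive pair is
    at least ``min_separation`` apart.  The multiset of consecutive relative
    configurations — the pairwise statistics implied by the AF — is conserved
    exactly.
    """
    if _min_nonconsecutive_distance(contour) >= min_separation:
        return contour
    d, phi, dtheta = contour.steps()
    start = (contour.x[0], contour.y[0], contour.theta[0])
    n = len(d)
    for _ in range(max_permutations):
        perm = rng.permutation(n)
        cand = rebuild_from_steps(start, d[perm], phi[perm], dtheta[perm], contour.params_id)
        if _min_nonconsecutive_distance(cand) >= min_separation:
            return cand
    raise RepairError(
        f"no overlap-free permutation found in {max_permutations} attempts "
        f"(min separation {min_separation})"
    )
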