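"""Association-field geometry and density.

The association field (AF) is the conditional link probability between two
oriented edge elements.  By translation, rotation and reversal symmetry it
reduces to a density over three relative coordinates:

* ``d``      — Euclidean pair distance (degrees of visual angle, DVA),
* ``phi``    — viewing angle: the angle under which an observer sitting on
  the source edge and looking along its direction sees the target edge,
* ``dtheta`` — difference between the two edge directions.

The density factorises into a radial part ``R(d)`` (truncated exponential
decay with constant ``lambda_radial``) and an angular part ``A(phi, dtheta)``,
a product of two von-Mises factors:

* alignment: ``dtheta`` should be close to the co-circular continuation
  ``2*phi`` (two edges tangent to a common circle), with angular scale
  ``sigma_align``;
* curvature: ``dtheta`` itself should be small, with scale ``sigma_curv``.

Directions are full-circle (0..2*pi), not orientations modulo pi, so that a
contour-creation process cannot silently turn around by 180 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

__all__ = [
    "DEFAULT_D_MAX",
    "Edge",
    "RelativeConfig",
    "AFParams",
    "DegenerateGeometryError",
    "wrap_angle",
    "wrap_direction",
    "relative_coordinates",
    "pairwise_geometry",
    "von_mises_density",
    "angular_density",
    "radial_density",
    "af_density",
]

#: Default radial normalisation domain: the diagonal of the stimulus field,
#: twice the maximum eccentricity of 16.66 DVA.
DEFAULT_D_MAX = 2.0 * 16.66


class DegenerateGeometryError(ValueError):
    """Raised when two edges coincide and the viewing angle is undefined."""


def wrap_angle(x):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x), 2.0 * np.pi)


def wrap_direction(x):
    """Wrap direction(s) to [0, 2*pi)."""
    return np.mod(np.asarray(x), 2.0 * np.pi)


@dataclass(frozen=True)
class Edge:
    """An oriented edge element: position in DVA (screen-centred, y up) and
    a full-circle direction in radians, stored wrapped to [0, 2*pi)."""

    x: float
    y: float
    theta: float

    def __post_init__(self):
        object.__setattr__(self, "theta", float(wrap_direction(self.theta)))

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.x, self.y)

    def reverse(self) -> "Edge":
        """Same element traversed in the opposite direction."""
        return Edge(self.x, self.y, self.theta + math.pi)


@dataclass(frozen=True)
class RelativeConfig:
    """Relative coordinates of an ordered edge pair (invariant under joint
    translation and rotation)."""

    d: float
    phi: float
    dtheta: float


@dataclass(frozen=True)
class AFParams:
    """Shape of the association field.

    Parameters
    ----------
    sigma_align : float
        Angular scale (radians) of the deviation of ``dtheta`` from the
        co-circular continuation ``2*phi``.
    sigma_curv : float
        Angular scale (radians) of the direction difference ``dtheta``
        (penalises curvature).
    lambda_radial : float
        Radial decay constant in DVA.
    """

    sigma_align: float
    sigma_curv: float
    lambda_radial: float = 10.0

    def __post_init__(self):
        for name in ("sigma_align", "sigma_curv", "lambda_radial"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kappa_align(self) -> float:
        """Concentration of the half-angle alignment factor (kappa = 4/sigma^2)."""
        return 4.0 / self.sigma_align**2

    @property
    def kappa_curv(self) -> float:
        return 1.0 / self.sigma_curv**2

    def to_dict(self) -> dict:
        return {
            "sigma_align": self.sigma_align,
            "sigma_curv": self.sigma_curv,
            "lambda_radial": self.lambda_radial,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AFParams":
        return cls(**{k: d[k] for k in ("sigma_align", "sigma_curv", "lambda_radial")})


def relative_coordinates(source: Edge, target: Edge) -> RelativeConfig:
    """Relative coordinates (d, phi, dtheta) of the ordered pair source -> target."""
    dx = target.x - source.x
    dy = target.y - source.y
    d = math.hypot(dx, dy)
    if d == 0.0:
        raise DegenerateGeometryError(
            f"coincident edge positions ({source.x}, {source.y}); viewing angle undefined"
        )
    phi = float(wrap_angle(math.atan2(dy, dx) - source.theta))
    dtheta = float(wrap_angle(target.theta - source.theta))
    return RelativeConfig(d=d, phi=phi, dtheta=dtheta)


def pairwise_geometry(x, y, theta):
    """Relative coordinates for all ordered pairs of an edge set.

    Returns (D, PHI, DTHETA), each an ``(n, n)`` array whose ``[i, j]`` entry
    describes the pair i -> j.  Diagonals are 0 (D) and undefined-but-finite
    (PHI); callers mask the diagonal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    dx = x[None, :] - x[:, None]
    dy = y[None, :] - y[:, None]
    D = np.hypot(dx, dy)
    PHI = wrap_angle(np.arctan2(dy, dx) - theta[:, None])
    DTHETA = wrap_angle(theta[None, :] - theta[:, None])
    return D, PHI, DTHETA


def von_mises_density(x, mu, sigma):
    """Von-Mises density with concentration kappa = 1/sigma**2.

    ``exp(kappa*cos(x - mu)) / (2*pi*I0(kappa))``, evaluated stably through
    the exponentially scaled Bessel function; integrates to 1 over any
    interval of length 2*pi.
    """
    if not sigma > 0:
        raise ValueError("sigma must be strictly positive")
    kappa = 1.0 / float(sigma) ** 2
    x = np.asarray(x, dtype=float)
    return np.exp(kappa * (np.cos(x - mu) - 1.0)) / (2.0 * np.pi * i0e(kappa))


def half_angle_von_mises_density(x, sigma):
    """Von-Mises-type density on a 4*pi-periodic deviation variable.

    ``exp(kappa*cos(x/2)) / (4*pi*I0(kappa))`` with ``kappa = 4/sigma**2``;
    integrates to 1 over any interval of length 4*pi in x, and approaches a
    Gaussian of width ``sigma`` in x for small sigma.  Used for the
    co-circularity deviation, whose natural period in the viewing angle is a
    full turn: a plain 2*pi-periodic factor would put a second, retrograde
    mode at phi = pi (a step placed *behind* the source edge), which the
    full-circle direction convention of the contour process exists to
    forbid.
    """
    if not sigma > 0:
        raise ValueError("sigma must be strictly positive")
    kappa = 4.0 / float(sigma) ** 2
    x = np.asarray(x, dtype=float)
    return np.exp(kappa * (np.cos(x / 2.0) - 1.0)) / (4.0 * np.pi * i0e(kappa))


def angular_density(phi, dtheta, params: AFParams):
    """Angular AF factor A(phi, dtheta).

    Product of a half-angle von-Mises factor in ``dtheta - 2*phi``
    (deviation from the forward co-circular continuation, scale
    ``sigma_align``) and a von-Mises factor in ``dtheta`` (curvature, scale
    ``sigma_curv``).  The product integrates to exactly 1 over
    ``(phi, dtheta) in (-pi, pi]^2``, so the normalisation constant is 1,
    and it is exactly symmetric under reversal of the edge pair.
    """
    phi = np.asarray(phi, dtype=float)
    dtheta = np.asarray(dtheta, dtype=float)
    # the half-angle factor integrates to 1/2 per 2*pi of x = dtheta - 2*phi,
    # but x sweeps 4*pi as phi crosses its 2*pi range, restoring total mass 1
    return 2.0 * half_angle_von_mises_density(dtheta - 2.0 * phi, params.sigma_align) * \
        von_mises_density(dtheta, 0.0, params.sigma_curv)


def radial_density(d, params: AFParams, d_max: float = DEFAULT_D_MAX):
    """Radial AF factor: exponential decay, normalised on [0, d_max]."""
    lam = params.lambda_radial
    z = lam * (1.0 - math.exp(-d_max / lam))
    d = np.asarray(d, dtype=float)
    out = np.exp(-d / lam) / z
    return np.where(d <= d_max, out, 0.0)


def af_density(source: Edge, target: Edge, params: AFParams, d_max: float = DEFAULT_D_MAX) -> float:
    """Association-field density for the ordered pair source -> target."""
    rc = relative_coordinates(source, target)
    return float(
        radial_density(rc.d, params, d_max) * angular_density(rc.phi, rc.dtheta, params)
    )
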