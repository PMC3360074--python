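"""Hiding contours among distractors and assembling stimulus ensembles.

A 2-AFC stimulus shows a contour in one hemifield, hidden in a field of
randomly oriented background edges.  The only cue allowed to reveal the
contour is the relative alignment of its edges, so all first-order cues —
local density, inter-edge distances — must be removed.  This is done by a
Brownian relaxation of the background (a hard-core gas at the contour's
density) plus an outer loop that redraws the contour's step lengths from the
measured background nearest-neighbour (NN) distribution until the three NN
distance distributions (background-background, background-contour,
contour-contour) are statistically indistinguishable.  A decoy path with
contour positional statistics but random directions on the opposite
hemifield removes residual higher-order positional cues, and a mask redraws
every direction at the same positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from .af import AFParams, wrap_direction
from .contours import Contour, rebuild_from_steps, repair_overlaps, sample_contour

__all__ = [
    "Stimulus",
    "EnsembleSpec",
    "GaborRenderParams",
    "EmbeddingError",
    "embed_contour",
    "add_decoy_path",
    "make_mask",
    "build_ensemble",
    "render_gabor_image",
    "nn_distance_stats",
    "density_side_classifier",
]


class EmbeddingError(RuntimeError):
    """Distance matching failed to converge; carries the final KS statistics."""

    def __init__(self, ks_stats):
        super().__init__(f"distance matching did not converge: KS stats {ks_stats}")
        self.ks_stats = ks_stats


@dataclass
class Stimulus:
    """Two hemifields of labelled edges.

    Roles are "contour" (the ordered target, ``contour_order`` 0..L-1 on
    ``target_side``), "decoy" (contour-like positions, random directions, on
    the opposite side) and "background".  The hemifield split is at x = 0.
    """

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    role: np.ndarray
    contour_order: np.ndarray
    target_side: str
    L: int
    ensemble_id: str = ""
    stimulus_id: str = ""
    is_mask: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = wrap_direction(np.asarray(self.theta, dtype=float))
        self.role = np.asarray(self.role, dtype=object)
        self.contour_order = np.asarray(self.contour_order, dtype=int)

    def __len__(self):
        return len(self.x)

    def hemifield_mask(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        return self.x < 0 if side == "left" else self.x >= 0

    def hemifield(self, side: str):
        m = self.hemifield_mask(side)
        return self.x[m], self.y[m], self.theta[m]


@dataclass(frozen=True)
class GaborRenderParams:
    """Raster parameters for rendering edges as Gabor patches.

    Defaults reconstruct an 1152-pixel-wide display spanning 26.6 DVA:
    8-pixel envelope extent and 16-pixel wavelength.
    """

    envelope_sigma: float = 0.09
    wavelength: float = 0.37
    contrast: float = 0.9
    mean_luminance: float = 0.5
    pixels_per_dva: float = 43.3

    def __post_init__(self):
        for name in ("envelope_sigma", "wavelength", "contrast", "mean_luminance", "pixels_per_dva"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EnsembleSpec:
    """One stimulus condition: an AF shape plus a contour-length/spacing pair.

    ``spacing`` is the target mean inter-edge distance in DVA; the field is a
    ``field_width x field_height`` rectangle centred on fixation, split into
    hemifields at x = 0.  The ``profile`` selects the embedding effort:
    "default" runs the full relaxation and matching loop, "fast" a reduced
    one for large simulation campaigns.
    """

    af: AFParams
    L: int
    spacing: float
    n_stimuli: int = 48
    field_width: float = 26.6
    field_height: float = 20.0
    min_separation: float = 0.2
    ensemble_id: str = ""
    profile: str = "default"

    def __post_init__(self):
        if self.n_stimuli % 2:
            raise ValueError("n_stimuli must be even (balanced left/right targets)")
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.profile not in ("default", "fast"):
            raise ValueError("profile must be 'default' or 'fast'")

    @property
    def d_range(self):
        """Radial sampling band that pins the mean step near ``spacing``."""
        return (0.7 * self.spacing, 1.3 * self.spacing)

    def hemifield_region(self, side: str, margin: float | None = None):
        margin = self.spacing * 0.75 if margin is None else margin
        hw, hh = self.field_width / 2.0, self.field_height / 2.0
        if side == "left":
            return (-hw + margin, -hh + margin, -margin, hh - margin)
        return (margin, -hh + margin, hw - margin, hh - margin)


# ---------------------------------------------------------------------------
# Brownian background relaxation

def _initial_background(spec: EnsembleSpec, fixed_pts: np.ndarray, rng) -> np.ndarray:
    hw, hh = spec.field_width / 2.0, spec.field_height / 2.0
    s = spec.spacing
    gx = np.arange(-hw + s / 2, hw, s)
    gy = np.arange(-hh + s / 2, hh, s)
    X, Y = np.meshgrid(gx, gy)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    pts += rng.uniform(-0.3 * s, 0.3 * s, size=pts.shape)
    if len(fixed_pts):
        # seed no background inside the path's typical NN shell: grid points
        # surviving a bare hard-core cull crowd the path boundary and bias
        # the path-to-background distances low
        excl = max(spec.min_separation, 0.4 * s)
        d, _ = cKDTree(fixed_pts).query(pts)
        pts = pts[d >= excl]
    return pts


def _relax_epochs(bg: np.ndarray, fixed_pts: np.ndarray, spec: EnsembleSpec, rng,
                  n_epochs: int) -> np.ndarray:
    """Brownian hard-core relaxation; Jacobi-style vectorised updates."""
    hw, hh = spec.field_width / 2.0, spec.field_height / 2.0
    step = 0.1 * spec.spacing
    sep = spec.min_separation
    n_fixed = len(fixed_pts)
    prev_mean = None
    stable = 0
    for _ in range(n_epochs):
        prop = bg + rng.normal(0.0, step, size=bg.shape)
        np.clip(prop[:, 0], -hw, hw, out=prop[:, 0])
        np.clip(prop[:, 1], -hh, hh, out=prop[:, 1])
        current = np.vstack([fixed_pts, bg]) if n_fixed else bg
        tree = cKDTree(current)
        dd, ii = tree.query(prop, k=2)
        self_idx = np.arange(len(bg)) + n_fixed
        nearest_other = np.where(ii[:, 0] == self_idx, dd[:, 1], dd[:, 0])
        ok = nearest_other >= sep
        moved = np.where(ok[:, None], prop, bg)
        # simultaneous moves can collide with each other: revert one of each pair
        pairs = cKDTree(moved).query_pairs(sep, output_type="ndarray")
        if len(pairs):
            revert = np.unique(pairs[:, 1])
            moved[revert] = bg[revert]
        bg = moved
        # stationarity: drift of the mean NN distance
        dnn, _ = cKDTree(bg).query(bg, k=2)
        m = dnn[:, 1].mean()
        if prev_mean is not None and abs(m - prev_mean) < 0.01 * prev_mean:
            stable += 1
            if stable >= 3:
                break
        else:
            stable = 0
        prev_mean = m
    return bg


def _nn_within(pts: np.ndarray) -> np.ndarray:
    if len(pts) < 2:
        return np.empty(0)
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


def _nn_between(src: np.ndarray, other: np.ndarray) -> np.ndarray:
    if len(src) == 0 or len(other) == 0:
        return np.empty(0)
    d, _ = cKDTree(other).query(src)
    return d


def nn_distance_stats(stimulus: Stimulus):
    """Pooled NN distance samples per class: bb, bc, cc.

    bb — background edge to nearest background edge; cc — path edge (contour
    or decoy) to nearest edge of the same path; bc — path edge to nearest
    background edge.
    """
    bg = stimulus.role == "background"
    bg_pts = np.column_stack([stimulus.x[bg], stimulus.y[bg]])
    bb = _nn_within(bg_pts)
    cc, bc = [], []
    for r in ("contour", "decoy"):
        sel = stimulus.role == r
        if sel.sum() >= 2:
            pts = np.column_stack([stimulus.x[sel], stimulus.y[sel]])
            cc.append(_nn_within(pts))
            bc.append(_nn_between(pts, bg_pts))
    cc = np.concatenate(cc) if cc else np.empty(0)
    bc = np.concatenate(bc) if bc else np.empty(0)
    return bb, bc, cc


def _redraw_gaps(path: Contour, bb_sample: np.ndarray, region, rng) -> Contour:
    """Redraw the path's step lengths from the measured background NN sample.

    Interior steps are drawn from the distribution H with
    1 - H = (1 - G)**(1/2), so the minimum of two adjacent steps — an
    interior path edge's within-path NN — has the background NN distribution
    G; the two end steps use exponent 3/4, splitting the residual bias
    between the end edges (whose NN is a single step) and their neighbours.
    Drawn via the empirical quantile transform.  The rebuilt path is
    translated back into its hemifield region, with a mild uniform shrink as
    a last resort.
    """
    d, phi, dtheta = path.steps()
    u = rng.random(len(d))
    expo = np.full(len(d), 2.0)
    if len(d) > 2:
        expo[[0, -1]] = 4.0 / 3.0
    new_d = np.quantile(bb_sample, 1.0 - (1.0 - u) ** expo)
    start = (path.x[0], path.y[0], path.theta[0])
    for _ in range(50):
        cand = rebuild_from_steps(start, new_d, phi, dtheta, path.params_id)
        x0, y0, x1, y1 = region
        sx = _shift_into(cand.x, x0, x1)
        sy = _shift_into(cand.y, y0, y1)
        if sx is not None and sy is not None:
            return Contour(cand.x + sx, cand.y + sy, cand.theta, cand.params_id)
        new_d = new_d * 0.97
    raise EmbeddingError({"reason": "path does not fit hemifield after regapping"})


def _shift_into(v: np.ndarray, lo: float, hi: float):
    if v.max() - v.min() > hi - lo:
        return None
    s = 0.0
    if v.min() + s < lo:
        s = lo - v.min()
    if v.max() + s > hi:
        s = hi - v.max()
    return s if (v.min() + s >= lo - 1e-9) else None


def _profile_knobs(spec: EnsembleSpec):
    if spec.profile == "fast":
        return {"epochs": 10, "outer": 1, "post_epochs": 4}
    return {"epochs": 25, "outer": 2, "post_epochs": 8}


def _assemble(contour: Contour, decoy: Contour | None, bg: np.ndarray,
              spec: EnsembleSpec, target_side: str, rng, meta) -> Stimulus:
    parts_x = [contour.x]
    parts_y = [contour.y]
    parts_t = [contour.theta]
    roles = [np.array(["contour"] * len(contour), dtype=object)]
    orders = [np.arange(len(contour))]
    if decoy is not None:
        parts_x.append(decoy.x)
        parts_y.append(decoy.y)
        parts_t.append(rng.uniform(0.0, 2.0 * np.pi, size=len(decoy)))
        roles.append(np.array(["decoy"] * len(decoy), dtype=object))
        orders.append(np.full(len(decoy), -1))
    parts_x.append(bg[:, 0])
    parts_y.append(bg[:, 1])
    parts_t.append(rng.uniform(0.0, 2.0 * np.pi, size=len(bg)))
    roles.append(np.array(["background"] * len(bg), dtype=object))
    orders.append(np.full(len(bg), -1))
    return Stimulus(
        x=np.concatenate(parts_x),
        y=np.concatenate(parts_y),
        theta=np.concatenate(parts_t),
        role=np.concatenate(roles),
        contour_order=np.concatenate(orders),
        target_side=target_side,
        L=spec.L,
        ensemble_id=spec.ensemble_id,
        meta=meta,
    )


def embed_contour(contour: Contour, spec: EnsembleSpec, rng: np.random.Generator,
                  decoy: Contour | None = None, max_outer: int | None = None,
                  tol: float = 0.25) -> Stimulus:
    """Hide a contour (and optional decoy path) among distance-matched distractors.

    Background edges start on a regular grid at the contour's density, are
    relaxed by hard-core Brownian motion to a stationary state, and the
    contour's (and decoy's) step lengths are then iteratively redrawn from
    the measured background NN distribution.  The returned stimulus carries
    the final KS statistics in ``meta["ks"]``; ``tol`` is the per-stimulus
    convergence criterion on them (generous, because a single stimulus
    contributes only ~L contour NN samples).
    """
    knobs = _profile_knobs(spec)
    outer = knobs["outer"] if max_outer is None else max_outer
    target_side = "left" if contour.x.mean() < 0 else "right"
    region = spec.hemifield_region(target_side)
    decoy_region = spec.hemifield_region("right" if target_side == "left" else "left")

    ks = None
    bg = None
    for it in range(max(outer, 1) + 1):
        fixed = [np.column_stack([contour.x, contour.y])]
        if decoy is not None:
            fixed.append(np.column_stack([decoy.x, decoy.y]))
        fixed_pts = np.vstack(fixed)
        if bg is None:
            bg = _initial_background(spec, fixed_pts, rng)
            bg = _relax_epochs(bg, fixed_pts, spec, rng, knobs["epochs"])
        else:
            # paths moved: drop colliding background edges, re-relax briefly
            d = _nn_between(bg, fixed_pts)
            bg = bg[d >= spec.min_separation]
            bg = _relax_epochs(bg, fixed_pts, spec, rng, knobs["post_epochs"])
        bb = _nn_within(bg)
        cc = _nn_within(np.column_stack([contour.x, contour.y]))
        bc = _nn_between(np.column_stack([contour.x, contour.y]), bg)
        ks = {
            "bb_cc": float(ks_2samp(bb, cc).statistic),
            "bb_bc": float(ks_2samp(bb, bc).statistic),
        }
        if it >= outer or max(ks.values()) < tol:
            break
        contour = _redraw_gaps(contour, bb, region, rng)
        if decoy is not None:
            decoy = _redraw_gaps(decoy, bb, decoy_region, rng)
    meta = {"ks": ks, "spacing": spec.spacing}
    return _assemble(contour, decoy, bg, spec, target_side, rng, meta)


def add_decoy_path(stimulus: Stimulus, contour_template: Contour,
                   rng: np.random.Generator, min_separation: float = 0.2) -> Stimulus:
    """Place a decoy path on the hemifield opposite to the target.

    The template's positions are mirrored across the vertical midline if
    needed (conserving its step lengths exactly); directions are drawn
    uniformly at random and background edges colliding with the new path are
    removed.
    """
    other = "right" if stimulus.target_side == "left" else "left"
    tx = contour_template.x.copy()
    on_other = (tx < 0).all() if other == "left" else (tx >= 0).all()
    if not on_other:
        tx = -tx
    pts = np.column_stack([tx, contour_template.y])
    keep = np.ones(len(stimulus), dtype=bool)
    bg = stimulus.role == "background"
    bg_pts = np.column_stack([stimulus.x[bg], stimulus.y[bg]])
    if len(bg_pts):
        d = _nn_between(bg_pts, pts)
        drop = np.where(bg)[0][d < min_separation]
        keep[drop] = False
    return Stimulus(
        x=np.concatenate([stimulus.x[keep], pts[:, 0]]),
        y=np.concatenate([stimulus.y[keep], pts[:, 1]]),
        theta=np.concatenate([stimulus.theta[keep],
                              rng.uniform(0.0, 2.0 * np.pi, size=len(pts))]),
        role=np.concatenate([stimulus.role[keep],
                             np.array(["decoy"] * len(pts), dtype=object)]),
        contour_order=np.concatenate([stimulus.contour_order[keep], np.full(len(pts), -1)]),
        target_side=stimulus.target_side,
        L=stimulus.L,
        ensemble_id=stimulus.ensemble_id,
        stimulus_id=stimulus.stimulus_id,
        meta=dict(stimulus.meta),
    )


def make_mask(stimulus: Stimulus, rng: np.random.Generator) -> Stimulus:
    """Mask: same edge positions, all directions redrawn uniformly, roles erased."""
    n = len(stimulus)
    return Stimulus(
        x=stimulus.x.copy(),
        y=stimulus.y.copy(),
        theta=rng.uniform(0.0, 2.0 * np.pi, size=n),
        role=np.array(["background"] * n, dtype=object),
        contour_order=np.full(n, -1),
        target_side=stimulus.target_side,
        L=stimulus.L,
        ensemble_id=stimulus.ensemble_id,
        stimulus_id=stimulus.stimulus_id + "_mask" if stimulus.stimulus_id else "",
        is_mask=True,
        meta={},
    )


def build_ensemble(spec: EnsembleSpec, rng: np.random.Generator, with_masks: bool = True):
    """Generate one ensemble: n_stimuli stimuli, targets balanced left/right,
    each with a decoy path and (optionally) a mask in ``meta["mask"]``."""
    stimuli = []
    for i in range(spec.n_stimuli):
        side = "left" if i < spec.n_stimuli // 2 else "right"
        other = "right" if side == "left" else "left"
        contour = _sample_fitted_contour(spec, side, rng)
        decoy = _sample_fitted_contour(spec, other, rng)
        stim = embed_contour(contour, spec, rng, decoy=decoy)
        stim.stimulus_id = f"{spec.ensemble_id}_s{i:03d}"
        if with_masks:
            stim.meta["mask"] = make_mask(stim, rng)
        stimuli.append(stim)
    return stimuli


def _sample_fitted_contour(spec: EnsembleSpec, side: str, rng) -> Contour:
    region = spec.hemifield_region(side)
    for _ in range(200):
        try:
            c = sample_contour(spec.L, spec.af, region, rng,
                               d_range=spec.d_range, max_attempts=2000,
                               params_id=spec.ensemble_id)
        except Exception:
            continue
        try:
            return repair_overlaps(c, spec.min_separation, rng, max_permutations=200)
        except Exception:
            continue
    raise EmbeddingError({"reason": f"could not place a contour in the {side} hemifield"})


def density_side_classifier(stimulus: Stimulus) -> str:
    """Guess the target side from local density alone (mean NN distance).

    Used to verify that first-order cues are removed: on properly matched
    stimuli this classifier performs at chance.
    """
    means = {}
    for side in ("left", "right"):
        m = stimulus.hemifield_mask(side)
        pts = np.column_stack([stimulus.x[m], stimulus.y[m]])
        nn = _nn_within(pts)
        means[side] = nn.mean() if len(nn) else np.inf
    return "left" if means["left"] < means["right"] else "right"


def render_gabor_image(stimulus: Stimulus, params: GaborRenderParams,
                       rng: np.random.Generator, phases=None) -> np.ndarray:
    """Render the stimulus as a grey-level image in [0, 1].

    Each edge contributes a Gaussian-enveloped cosine grating oriented along
    its direction, with an independent uniform random phase (or fixed phases
    if ``phases`` is given); values are clipped to [0, 1] (overlapping
    envelopes trigger a warning, not an error).
    """
    import warnings as _warnings

    ppd = params.pixels_per_dva
    # field extent from the edge positions plus a margin
    if len(stimulus) == 0:
        return np.full((8, 8), params.mean_luminance)
    margin = 4 * params.envelope_sigma
    x0, x1 = stimulus.x.min() - margin, stimulus.x.max() + margin
    y0, y1 = stimulus.y.min() - margin, stimulus.y.max() + margin
    W = max(8, int(math.ceil((x1 - x0) * ppd)))
    H = max(8, int(math.ceil((y1 - y0) * ppd)))
    img = np.zeros((H, W))
    half = int(math.ceil(3 * params.envelope_sigma * ppd))
    if phases is None:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(stimulus))
    else:
        phases = np.broadcast_to(np.asarray(phases, dtype=float), (len(stimulus),))
    for xe, ye, te, phase in zip(stimulus.x, stimulus.y, stimulus.theta, phases):
        cx = (xe - x0) * ppd
        cy = (y1 - ye) * ppd  # raster rows grow downward
        ix, iy = int(round(cx)), int(round(cy))
        r0, r1 = max(0, iy - half), min(H, iy + half + 1)
        c0, c1 = max(0, ix - half), min(W, ix + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dx = (xx - cx) / ppd
        dy = (cy - yy) / ppd
        perp = -dx * math.sin(te) + dy * math.cos(te)
        env = np.exp(-(dx**2 + dy**2) / (2.0 * params.envelope_sigma**2))
        img[r0:r1, c0:c1] += params.contrast * env * np.cos(
            2.0 * np.pi * perp / params.wavelength + phase
        )
    out = params.mean_luminance + img
    if out.min() < 0.0 or out.max() > 1.0:
        _warnings.warn("luminance clipped: overlapping Gabor envelopes", stacklevel=2)
    return np.clip(out, 0.0, 1.0)
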