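"""Synthetic 2-AFC observers with shared difficulty and independent noise.

Emulates a panel of human observers: all share the decisions of one base
contour-integration model (the common, stimulus-dependent difficulty
structure), and each flips every decision independently with a lapse
probability eta.  This produces excess correlations above the independence
null among observers — eta = 0 makes them identical, eta = 0.5 makes them
pure coin-flippers.  A softmax mode grades the flip probability by the
log-evidence difference instead of using a constant lapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .af import AFParams
from .observer import ContourObserver, EccParams
from .stats import DECISION_COLUMNS, validate_decision_table

__all__ = [
    "SyntheticObserverSpec",
    "simulate_observers",
    "write_decisions",
    "read_decisions",
]


@dataclass(frozen=True)
class SyntheticObserverSpec:
    """Panel of synthetic observers sharing one base model.

    ``lapse_rates`` gives each observer's independent flip probability
    (eta in [0, 0.5]); ``mode`` is "lapse" (constant flip probability) or
    "softmax" (flip probability graded by the evidence difference with
    inverse temperature ``beta``).
    """

    af: AFParams
    ecc: EccParams = field(default_factory=EccParams)
    lapse_rates: tuple = (0.15, 0.15, 0.15, 0.15, 0.15)
    mode: str = "lapse"
    beta: float = 1.0

    def __post_init__(self):
        if not all(0.0 <= e <= 0.5 for e in self.lapse_rates):
            raise ValueError("lapse rates must lie in [0, 0.5]")
        if self.mode not in ("lapse", "softmax"):
            raise ValueError("mode must be 'lapse' or 'softmax'")

    @property
    def n_observers(self) -> int:
        return len(self.lapse_rates)


def simulate_observers(spec: SyntheticObserverSpec, stimuli, rng: np.random.Generator,
                       soa: float = 200.0) -> pd.DataFrame:
    """Decision table of the synthetic panel on a stimulus list.

    The base model decides each stimulus once (shared difficulty); each
    observer's response is that decision, flipped independently with its
    lapse probability (or, in softmax mode, with a probability shrinking in
    the evidence margin).
    """
    obs = ContourObserver(
        sigma_align=spec.af.sigma_align, sigma_curv=spec.af.sigma_curv,
        lambda_radial=spec.af.lambda_radial, amplitude=spec.ecc.amplitude,
        gamma=spec.ecc.gamma, eps_max=spec.ecc.eps_max,
        seed=int(rng.integers(2**31)),
    ).fit()
    base = obs.predict(stimuli)
    if spec.mode == "softmax":
        margins = np.array([
            abs(np.log(max(bl, 1e-300)) - np.log(max(br, 1e-300)))
            for bl, br in (obs.decision_likelihoods(s) for s in stimuli)
        ])
        graded = 0.5 / (1.0 + np.exp(spec.beta * margins))  # in (0, 0.5]

    rows = []
    flip_to = {"left": "right", "right": "left"}
    for m, eta in enumerate(spec.lapse_rates):
        p_flip = graded * (2.0 * eta) if spec.mode == "softmax" else np.full(len(stimuli), eta)
        flips = rng.random(len(stimuli)) < p_flip
        for stim, resp, fl in zip(stimuli, base, flips):
            r = flip_to[resp] if fl else resp
            rows.append({
                "observer_id": f"synth_{m}",
                "condition": stim.ensemble_id,
                "stimulus_id": stim.stimulus_id,
                "soa": soa,
                "response": r,
                "correct": int(r == stim.target_side),
            })
    return pd.DataFrame(rows, columns=DECISION_COLUMNS)


def write_decisions(table: pd.DataFrame, path) -> None:
    """Write a decision table to CSV (schema-validated first)."""
    validate_decision_table(table)
    table.to_csv(path, index=False, columns=DECISION_COLUMNS)


def read_decisions(path) -> pd.DataFrame:
    """Read and validate a decision-table CSV.

    Raises a descriptive error naming any missing column or the first
    invariant violation (observers with mismatched stimulus sets).
    """
    table = pd.read_csv(path)
    missing = [c for c in DECISION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    bad = table["response"].isin(["left", "right"])
    if not bad.all():
        row = int(np.argmax(~bad.to_numpy()))
        raise ValueError(f"{path}: row {row}: response must be 'left' or 'right'")
    return validate_decision_table(table)
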