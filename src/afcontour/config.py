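"""Default experiment configuration and JSON (de)serialisation.

The default design mirrors the scale of the original study: 6 association-
field jitter pairs x 7 contour-length conditions = 42 ensembles, 48 stimuli
each (2016 per observer-session at one SOA), SOAs of 20/30/60/100/200 ms,
maximum eccentricity 16.66 DVA.  Conditions are defined by 7 geometrically
spaced target mean inter-edge distances spanning 1.2-3.6 DVA; the contour
element count follows from holding the contour extent approximately constant
at 13.9 DVA.  The published jitter values are not recoverable, so the six
pairs below are reconstructions spanning straight/aligned to
curved/jittered; see docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .af import AFParams
from .observer import DEFAULT_EPS_MAX, SOAMap
from .stimuli import EnsembleSpec

__all__ = ["ExperimentConfig", "default_experiment_config", "load_config", "save_config"]

#: Mean contour extent in DVA (anchors the SOA propagation-speed mapping).
CONTOUR_EXTENT = 13.9

#: Reconstructed AF jitter pairs (sigma_align, sigma_curv) in degrees.
DEFAULT_JITTER_PAIRS_DEG = [
    (8.0, 8.0),
    (8.0, 25.0),
    (15.0, 15.0),
    (15.0, 35.0),
    (25.0, 25.0),
    (35.0, 45.0),
]

#: Seven target mean inter-edge distances, geometric from 1.2 to 3.6 DVA.
DEFAULT_SPACINGS = [round(1.2 * (3.0 ** (i / 6.0)), 3) for i in range(7)]

DEFAULT_SOAS = [20.0, 30.0, 60.0, 100.0, 200.0]


def _length_for_spacing(spacing: float) -> int:
    return max(4, int(round(CONTOUR_EXTENT / spacing)) + 1)


@dataclass
class ExperimentConfig:
    """Full experiment grid: ensembles, SOA list, master seed."""

    ensembles: list
    soas: list = field(default_factory=lambda: list(DEFAULT_SOAS))
    eps_max: float = DEFAULT_EPS_MAX
    master_seed: int = 0

    @property
    def n_conditions(self) -> int:
        return len(self.ensembles)

    @property
    def n_stimuli_per_session(self) -> int:
        return sum(e.n_stimuli for e in self.ensembles)

    def spacings(self):
        return sorted({e.spacing for e in self.ensembles})

    def soa_map_for(self, spec: EnsembleSpec) -> SOAMap:
        return SOAMap(d_bar=spec.spacing)

    def to_dict(self) -> dict:
        return {
            "soas": self.soas,
            "eps_max": self.eps_max,
            "master_seed": self.master_seed,
            "ensembles": [
                {
                    "af": e.af.to_dict(),
                    "L": e.L,
                    "spacing": e.spacing,
                    "n_stimuli": e.n_stimuli,
                    "field_width": e.field_width,
                    "field_height": e.field_height,
                    "min_separation": e.min_separation,
                    "ensemble_id": e.ensemble_id,
                    "profile": e.profile,
                }
                for e in self.ensembles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        ensembles = [
            EnsembleSpec(
                af=AFParams.from_dict(e["af"]),
                L=e["L"],
                spacing=e["spacing"],
                n_stimuli=e.get("n_stimuli", 48),
                field_width=e.get("field_width", 26.6),
                field_height=e.get("field_height", 20.0),
                min_separation=e.get("min_separation", 0.2),
                ensemble_id=e.get("ensemble_id", ""),
                profile=e.get("profile", "default"),
            )
            for e in d["ensembles"]
        ]
        return cls(
            ensembles=ensembles,
            soas=d.get("soas", list(DEFAULT_SOAS)),
            eps_max=d.get("eps_max", DEFAULT_EPS_MAX),
            master_seed=d.get("master_seed", 0),
        )


def default_experiment_config(master_seed: int = 0, n_stimuli: int = 48,
                              profile: str = "default") -> ExperimentConfig:
    """The default 42-ensemble grid (6 AF jitter pairs x 7 spacings)."""
    ensembles = []
    for j, (s1, s2) in enumerate(DEFAULT_JITTER_PAIRS_DEG):
        af = AFParams(math.radians(s1), math.radians(s2))
        for spacing in DEFAULT_SPACINGS:
            L = _length_for_spacing(spacing)
            ensembles.append(EnsembleSpec(
                af=af, L=L, spacing=spacing, n_stimuli=n_stimuli,
                ensemble_id=f"af{j}_d{spacing:.2f}", profile=profile,
            ))
    return ExperimentConfig(ensembles=ensembles, master_seed=master_seed)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(json.load(fh))
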