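"""CSV/PNG serialisation of stimuli.

Stimulus files hold one row per edge: stimulus_id, ensemble_id, hemifield,
role, contour_order, x_dva, y_dva, theta_rad.  Masks are stored in the same
schema in a sibling table.  Coordinates are DVA, screen-centred, y up;
angles radians.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stimuli import Stimulus

__all__ = ["STIMULUS_COLUMNS", "stimuli_to_frame", "frame_to_stimuli",
           "write_stimuli", "read_stimuli", "save_png"]

STIMULUS_COLUMNS = ["stimulus_id", "ensemble_id", "hemifield", "role",
                    "contour_order", "x_dva", "y_dva", "theta_rad"]


def stimuli_to_frame(stimuli) -> pd.DataFrame:
    rows = []
    for stim in stimuli:
        hemi = np.where(stim.x < 0, "left", "right")
        for i in range(len(stim)):
            rows.append({
                "stimulus_id": stim.stimulus_id,
                "ensemble_id": stim.ensemble_id,
                "hemifield": hemi[i],
                "role": stim.role[i],
                "contour_order": int(stim.contour_order[i]),
                "x_dva": stim.x[i],
                "y_dva": stim.y[i],
                "theta_rad": stim.theta[i],
            })
    return pd.DataFrame(rows, columns=STIMULUS_COLUMNS)


def frame_to_stimuli(frame: pd.DataFrame, target_sides: dict, L_by_ensemble: dict):
    """Rebuild Stimulus objects from an edge table.

    ``target_sides`` maps stimulus_id -> "left"/"right"; ``L_by_ensemble``
    maps ensemble_id -> contour length (both stored in the JSON sidecar).
    """
    out = []
    for sid, block in frame.groupby("stimulus_id", sort=False):
        eid = block["ensemble_id"].iloc[0]
        out.append(Stimulus(
            x=block["x_dva"].to_numpy(),
            y=block["y_dva"].to_numpy(),
            theta=block["theta_rad"].to_numpy(),
            role=block["role"].to_numpy(dtype=object),
            contour_order=block["contour_order"].to_numpy(),
            target_side=target_sides[sid],
            L=int(L_by_ensemble[eid]),
            ensemble_id=eid,
            stimulus_id=sid,
        ))
    return out


def write_stimuli(stimuli, path) -> None:
    stimuli_to_frame(stimuli).to_csv(path, index=False)


def read_stimuli(path, target_sides: dict, L_by_ensemble: dict):
    return frame_to_stimuli(pd.read_csv(path), target_sides, L_by_ensemble)


def save_png(image: np.ndarray, path) -> None:
    """Write a [0, 1] grey-level array as an 8-bit PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(image) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
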