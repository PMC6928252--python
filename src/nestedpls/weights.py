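"""Weight-coordinate bookkeeping shared by the null-model and resampling ensembles.

A model's comparable coordinates are grouped by axis:

* ``x_time`` / ``x_var`` — factored independent-block weights (w);
* ``y_time`` / ``y_var`` — factored dependent-block weights (q);
* ``x_combined`` / ``y_combined`` — the flattened unfolded weights;
* ``t`` / ``u`` — condition scores.

Each entry is an ``n_lvs x dim`` array.  Sign alignment between a model and a
reference is decided per LV from the inner product of the concatenated
(w, q) combined weights; a negative product flips the whole LV (w, q, t, u
and the time parts of the factored weights), which leaves predictions
untouched.
"""

from __future__ import annotations

import numpy as np

from .npls import NPLSModel

AXES = ("x_time", "x_var", "y_time", "y_var", "x_combined", "y_combined", "t", "u")

# axes whose sign follows the whole-LV flip (variable parts keep their
# largest-entry-positive convention, so they do not flip)
FLIP_AXES = ("x_time", "y_time", "x_combined", "y_combined", "t", "u")


def weight_coordinates(model: NPLSModel) -> dict[str, np.ndarray]:
    """Stack each axis over LVs into an ``n_lvs x dim`` array."""
    lvs = model.latent_variables
    return {
        "x_time": np.array([lv.w_time for lv in lvs]),
        "x_var": np.array([lv.w_var for lv in lvs]),
        "y_time": np.array([lv.q_time for lv in lvs]),
        "y_var": np.array([lv.q_var for lv in lvs]),
        "x_combined": np.array([lv.w for lv in lvs]),
        "y_combined": np.array([lv.q for lv in lvs]),
        "t": np.array([lv.t for lv in lvs]),
        "u": np.array([lv.u for lv in lvs]),
    }


def alignment_signs(
    coords: dict[str, np.ndarray], reference: dict[str, np.ndarray]
) -> np.ndarray:
    """Per-LV signs (+1/-1) aligning ``coords`` with ``reference``."""
    wq = np.concatenate([coords["x_combined"], coords["y_combined"]], axis=1)
    wq_ref = np.concatenate([reference["x_combined"], reference["y_combined"]], axis=1)
    dots = np.sum(wq * wq_ref, axis=1)
    signs = np.where(dots < 0, -1.0, 1.0)
    return signs


def apply_signs(coords: dict[str, np.ndarray], signs: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for axis, arr in coords.items():
        if axis in FLIP_AXES:
            out[axis] = arr * signs[:, None]
        else:
            out[axis] = arr.copy()
    return out


def axis_labels(
    axis: str,
    x_times: tuple[float, ...],
    x_vars: tuple[str, ...],
    y_times: tuple[float, ...],
    y_vars: tuple[str, ...],
) -> list[str]:
    """Human-readable labels for one axis' coordinates."""
    if axis == "x_time":
        return [str(t) for t in x_times]
    if axis == "x_var":
        return list(x_vars)
    if axis == "y_time":
        return [str(t) for t in y_times]
    if axis == "y_var":
        return list(y_vars)
    if axis == "x_combined":
        return [f"{t}|{v}" for t in x_times for v in x_vars]
    if axis == "y_combined":
        return [f"{t}|{v}" for t in y_times for v in y_vars]
    raise KeyError(axis)
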