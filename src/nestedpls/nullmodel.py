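"""Randomization null models for weight significance.

Raw (pre-standardization) averaged tensors are shuffled within mode 1 — the
time x variable entries of each condition slab are permuted uniformly, in
both blocks independently — re-standardized and refitted.  Repeating this
(default 500 iterations) yields per-coordinate null means and SDs; a weight
of the real model is significant when it lies strictly more than one null SD
from the null mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import TensorPair
from .npls import FitSettings, NPLSError, NPLSModel, fit
from .standardize import StandardizationSpec, standardize
from .weights import AXES, alignment_signs, apply_signs, axis_labels, weight_coordinates

__all__ = [
    "NullDistribution",
    "shuffle_within_mode1",
    "build_null",
    "classify_significant",
    "null_summary_table",
]

WEIGHT_AXES = ("x_time", "x_var", "y_time", "y_var", "x_combined", "y_combined")


def shuffle_within_mode1(
    tensors: TensorPair, rng: np.random.Generator, preserve_rows: bool = False
) -> TensorPair:
    """Permute entries within each condition slab of each block.

    With ``preserve_rows=True`` whole time rows are permuted instead of all
    (time, variable) entries.
    """
    out = tensors.copy()
    for arr in (out.X, out.Y):
        for c in range(arr.shape[0]):
            slab = arr[c]
            if preserve_rows:
                arr[c] = slab[rng.permutation(slab.shape[0])]
            else:
                flat = slab.ravel()
                arr[c] = flat[rng.permutation(flat.size)].reshape(slab.shape)
    return out


@dataclass
class NullDistribution:
    mean: dict[str, np.ndarray]  # axis -> n_lvs x dim
    sd: dict[str, np.ndarray]
    n_iterations: int
    n_failed: int
    seed: int


def build_null(
    raw_tensors: TensorPair,
    spec: StandardizationSpec,
    settings: FitSettings,
    reference_model: NPLSModel,
    n_iter: int = 500,
    seed: int = 0,
    preserve_rows: bool = False,
) -> NullDistribution:
    """Accumulate the shuffled-data weight distribution.

    Every iteration shuffles, re-standardizes (leniently, so a degenerate
    shuffle cannot abort the run), fits with the global model's LV count and
    sign-aligns to the reference before accumulation.
    """
    rng = np.random.default_rng(seed)
    ref_coords = weight_coordinates(reference_model)
    lenient = spec.with_zero_variance("lenient")
    sums: dict[str, np.ndarray] = {}
    sqsums: dict[str, np.ndarray] = {}
    n_ok = 0
    n_failed = 0
    for _ in range(n_iter):
        shuffled = shuffle_within_mode1(raw_tensors, rng, preserve_rows=preserve_rows)
        try:
            std, _ = standardize(shuffled, lenient)
            model = fit(std.X, std.Y, settings)
        except (NPLSError, ValueError):
            n_failed += 1
            continue
        coords = apply_signs(
            weight_coordinates(model),
            alignment_signs(weight_coordinates(model), ref_coords),
        )
        for axis in WEIGHT_AXES:
            arr = coords[axis]
            if axis not in sums:
                sums[axis] = np.zeros_like(arr)
                sqsums[axis] = np.zeros_like(arr)
            sums[axis] += arr
            sqsums[axis] += arr**2
        n_ok += 1
    if n_ok == 0:
        raise NPLSError("every null iteration failed")
    mean = {axis: sums[axis] / n_ok for axis in sums}
    sd = {
        axis: np.sqrt(np.maximum(sqsums[axis] / n_ok - mean[axis] ** 2, 0.0))
        for axis in sums
    }
    return NullDistribution(mean=mean, sd=sd, n_iterations=n_ok, n_failed=n_failed, seed=seed)


def classify_significant(
    model: NPLSModel, null: NullDistribution
) -> dict[str, np.ndarray]:
    """One-SD rule: flag coordinates strictly beyond one null SD of the null mean."""
    coords = weight_coordinates(model)
    mask: dict[str, np.ndarray] = {}
    for axis in WEIGHT_AXES:
        if axis not in null.mean:
            raise NPLSError(f"null distribution lacks axis {axis!r}")
        if coords[axis].shape != null.mean[axis].shape:
            raise NPLSError(f"coordinate shape mismatch on axis {axis!r}")
        mask[axis] = np.abs(coords[axis] - null.mean[axis]) > null.sd[axis]
    return mask


def null_summary_table(
    model: NPLSModel,
    null: NullDistribution,
    tensors: TensorPair,
) -> pd.DataFrame:
    """Long summary: block, lv, axis, label, global weight, null mean/SD, flag."""
    coords = weight_coordinates(model)
    mask = classify_significant(model, null)
    rows = []
    for axis in WEIGHT_AXES:
        labels = axis_labels(
            axis, tensors.x_times, tensors.x_vars, tensors.y_times, tensors.y_vars
        )
        block = "X" if axis.startswith("x") else "Y"
        for n in range(model.n_lvs):
            for idx, label in enumerate(labels):
                rows.append(
                    {
                        "block": block,
                        "lv": n + 1,
                        "axis": axis,
                        "label": label,
                        "global_weight": coords[axis][n, idx],
                        "null_mean": null.mean[axis][n, idx],
                        "null_sd": null.sd[axis][n, idx],
                        "significant": bool(mask[axis][n, idx]),
                    }
                )
    return pd.DataFrame(rows)
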