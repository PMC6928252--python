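"""Tensor standardization with persisted state for fold-wise reuse and inversion.

Two study-specific recipes are supported:

* baseline subtraction + mode-3 variance scaling (aortic remodeling study):
  each entry has its condition/variable baseline-time entry subtracted, then
  every variable slab is divided by its scaling SD;
* modes-2-and-3 variance scaling (intestinal / HT-29 studies): variable slabs
  are scaled first (mode 3), then time slabs (mode 2).

The order of operations is fixed: baseline subtraction happens before any
scaling.  The scaling SD is the uncentered root-mean-square of the slab when
centering is off (the default), or the mean-centered sample SD when on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .dataset import TensorPair

__all__ = [
    "BlockSpec",
    "StandardizationSpec",
    "BlockState",
    "StandardizationState",
    "StandardizationError",
    "standardize",
    "apply_state",
    "invert_predictions",
    "bersi_spec",
    "modes23_spec",
]


class StandardizationError(ValueError):
    pass


@dataclass(frozen=True)
class BlockSpec:
    """What to do to one block."""

    baseline_time: float | None = None
    scale_modes: tuple[int, ...] = ()  # subset of (2, 3); applied 3 then 2
    center: bool = False

    def __post_init__(self) -> None:
        bad = set(self.scale_modes) - {2, 3}
        if bad:
            raise StandardizationError(f"scale_modes must be within {{2, 3}}, got {bad}")


@dataclass(frozen=True)
class StandardizationSpec:
    x: BlockSpec
    y: BlockSpec
    zero_variance: Literal["strict", "lenient"] = "strict"

    def block(self, name: str) -> BlockSpec:
        return self.x if name == "X" else self.y

    def with_zero_variance(self, policy: str) -> "StandardizationSpec":
        return StandardizationSpec(self.x, self.y, policy)  # type: ignore[arg-type]


def bersi_spec(zero_variance: str = "strict") -> StandardizationSpec:
    """Day-0 subtraction + mode-3 scaling on both blocks."""
    b = BlockSpec(baseline_time=0.0, scale_modes=(3,))
    return StandardizationSpec(x=b, y=b, zero_variance=zero_variance)  # type: ignore[arg-type]


def modes23_spec(zero_variance: str = "strict", center: bool = False) -> StandardizationSpec:
    """Variance scaling across modes 2 and 3 on both blocks (no baseline)."""
    b = BlockSpec(baseline_time=None, scale_modes=(2, 3), center=center)
    return StandardizationSpec(x=b, y=b, zero_variance=zero_variance)  # type: ignore[arg-type]


@dataclass
class BlockState:
    spec: BlockSpec
    baseline: np.ndarray | None  # i x n_vars values subtracted (audit + inversion)
    mode3: np.ndarray | None  # per-variable factors, length k
    mode2: np.ndarray | None  # per-time factors, length j
    zero_variance_slabs: list[str] = field(default_factory=list)


@dataclass
class StandardizationState:
    x: BlockState
    y: BlockState

    def block(self, name: str) -> BlockState:
        return self.x if name == "X" else self.y

    def to_json(self) -> str:
        def conv(bs: BlockState) -> dict:
            return {
                "spec": asdict(bs.spec),
                "baseline": None if bs.baseline is None else bs.baseline.tolist(),
                "mode3": None if bs.mode3 is None else bs.mode3.tolist(),
                "mode2": None if bs.mode2 is None else bs.mode2.tolist(),
                "zero_variance_slabs": bs.zero_variance_slabs,
            }

        return json.dumps({"X": conv(self.x), "Y": conv(self.y)}, indent=1)


def _scaling_sd(slab: np.ndarray, center: bool) -> float:
    flat = slab.ravel()
    if center:
        return float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0
    return float(np.sqrt(np.mean(flat**2)))


def _standardize_block(
    arr: np.ndarray,
    times: tuple[float, ...],
    spec: BlockSpec,
    policy: str,
    block_name: str,
    frozen: BlockState | None = None,
) -> tuple[np.ndarray, BlockState]:
    out = np.array(arr, dtype=float, copy=True)
    baseline = None
    if spec.baseline_time is not None:
        if spec.baseline_time not in times:
            raise StandardizationError(
                f"{block_name}: baseline time {spec.baseline_time} not in time grid {times}"
            )
        t0 = times.index(spec.baseline_time)
        baseline = out[:, t0, :].copy()  # i x n_vars, per condition & variable
        out -= baseline[:, None, :]

    zero_slabs: list[str] = []

    def factors_for(mode: int, current: np.ndarray) -> np.ndarray:
        axis_len = current.shape[2] if mode == 3 else current.shape[1]
        fac = np.empty(axis_len)
        for a in range(axis_len):
            slab = current[:, :, a] if mode == 3 else current[:, a, :]
            sd = _scaling_sd(slab, spec.center)
            if sd == 0.0:
                name = f"{block_name} mode-{mode} slab {a}"
                if policy == "strict":
                    raise StandardizationError(
                        f"zero-variance slab under strict handling: {name}"
                    )
                zero_slabs.append(name)
                sd = 1.0
            fac[a] = sd
        return fac

    mode3 = mode2 = None
    if 3 in spec.scale_modes:
        mode3 = frozen.mode3 if frozen is not None else factors_for(3, out)
        out /= mode3[None, None, :]
    if 2 in spec.scale_modes:
        mode2 = frozen.mode2 if frozen is not None else factors_for(2, out)
        out /= mode2[None, :, None]

    state = BlockState(
        spec=spec, baseline=baseline, mode3=mode3, mode2=mode2,
        zero_variance_slabs=zero_slabs,
    )
    return out, state


def standardize(
    tensors: TensorPair, spec: StandardizationSpec
) -> tuple[TensorPair, StandardizationState]:
    """Apply the spec to both blocks, returning transformed tensors and state."""
    xs, x_state = _standardize_block(
        tensors.X, tensors.x_times, spec.x, spec.zero_variance, "X"
    )
    ys, y_state = _standardize_block(
        tensors.Y, tensors.y_times, spec.y, spec.zero_variance, "Y"
    )
    out = TensorPair(
        X=xs, Y=ys, conditions=tensors.conditions,
        x_times=tensors.x_times, x_vars=tensors.x_vars,
        y_times=tensors.y_times, y_vars=tensors.y_vars,
    )
    return out, StandardizationState(x=x_state, y=y_state)


def apply_state(
    tensors: TensorPair, state: StandardizationState
) -> tuple[TensorPair, StandardizationState]:
    """Standardize with frozen scale factors (e.g. a held-out fold).

    Baseline subtraction is a within-condition operation and is recomputed
    from the supplied tensors; scale factors are taken from ``state``.  The
    returned state carries the baselines actually subtracted, so predictions
    for these conditions can be inverted.
    """
    for block, arr, times in (("X", tensors.X, tensors.x_times), ("Y", tensors.Y, tensors.y_times)):
        bs = state.block(block)
        if bs.mode3 is not None and len(bs.mode3) != arr.shape[2]:
            raise StandardizationError(f"{block}: variable axis does not match state")
        if bs.mode2 is not None and len(bs.mode2) != arr.shape[1]:
            raise StandardizationError(f"{block}: time axis does not match state")
    xs, x_state = _standardize_block(
        tensors.X, tensors.x_times, state.x.spec, "lenient", "X", frozen=state.x
    )
    ys, y_state = _standardize_block(
        tensors.Y, tensors.y_times, state.y.spec, "lenient", "Y", frozen=state.y
    )
    out = TensorPair(
        X=xs, Y=ys, conditions=tensors.conditions,
        x_times=tensors.x_times, x_vars=tensors.x_vars,
        y_times=tensors.y_times, y_vars=tensors.y_vars,
    )
    return out, StandardizationState(x=x_state, y=y_state)


def invert_predictions(y_hat_std: np.ndarray, state: StandardizationState) -> np.ndarray:
    """Map standardized Y-block predictions back to the measurement scale."""
    bs = state.y
    out = np.array(y_hat_std, dtype=float, copy=True)
    if bs.mode2 is not None:
        if out.shape[1] != len(bs.mode2):
            raise StandardizationError("prediction time axis does not match state")
        out *= bs.mode2[None, :, None]
    if bs.mode3 is not None:
        if out.shape[2] != len(bs.mode3):
            raise StandardizationError("prediction variable axis does not match state")
        out *= bs.mode3[None, None, :]
    if bs.baseline is not None:
        if out.shape[0] != bs.baseline.shape[0]:
            raise StandardizationError("prediction condition axis does not match state")
        out += bs.baseline[:, None, :]
    return out
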