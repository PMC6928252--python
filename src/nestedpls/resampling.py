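"""Nesting-preserving replicate resampling: jackknife and subsample ensembles.

Whole biological replicates (animals) are resampled per condition x time
cell: jackknifing removes one randomly chosen replicate from every cell and
re-averages, subsampling keeps exactly one replicate per cell (an n-of-one
dataset).  Because a replicate groups all of an animal's observations in its
cell, the nesting hierarchy is never broken.  Paired mode couples the draw
between the X and Y blocks through pairing_ids so the same animal is chosen
(or dropped) in both.

Each of the ``n_iter`` draws is averaged, standardized, fitted with the LV
count of the global-average model, optionally crossvalidated, and
sign-aligned to the global model.  Per-coordinate means and SDs over the
ensemble classify weights as robust (mean +/- SD strictly excludes zero) or
fragile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .crossval import CVResult, loo_crossvalidate
from .dataset import BLOCKS, DatasetError, NestedDataset, TensorPair, average_replicates
from .npls import FitSettings, NPLSError, NPLSModel, fit
from .standardize import StandardizationSpec, standardize
from .weights import alignment_signs, apply_signs, axis_labels, weight_coordinates

__all__ = [
    "ResamplingScheme",
    "ResamplingEnsemble",
    "jackknife_draw",
    "subsample_draw",
    "paired_draw",
    "run_ensemble",
    "align_signs",
    "summarize_robustness",
    "robust_fractions",
    "rmse_comparison",
]

WEIGHT_AXES = ("x_time", "x_var", "y_time", "y_var", "x_combined", "y_combined")

DrawLog = list[tuple[str, str, float, str]]  # (block, condition, time, replicate_id)


@dataclass(frozen=True)
class ResamplingScheme:
    method: Literal["jackknife", "subsample"]
    pairing: Literal["paired", "unpaired"] = "unpaired"
    n_iter: int = 500
    seed: int = 0
    n_lvs: int = 1  # fixed to the global-average model's optimum

    def __post_init__(self) -> None:
        if self.method not in ("jackknife", "subsample"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.pairing not in ("paired", "unpaired"):
            raise ValueError(f"unknown pairing {self.pairing!r}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _cells(dataset: NestedDataset):
    d = dataset.design
    for block in BLOCKS:
        for cond in d.conditions:
            for t in d.block(block).times:
                yield block, cond, t


def jackknife_draw(
    dataset: NestedDataset, rng: np.random.Generator
) -> tuple[NestedDataset, DrawLog]:
    """Remove one uniformly chosen replicate from every cell (leave-one-out)."""
    rep_map = dataset.replicate_map()
    removals: DrawLog = []
    for block, cond, t in _cells(dataset):
        ids = rep_map[(block, cond, t)]
        if len(ids) < 2:
            raise DatasetError(
                f"jackknife undefined for cell with a single replicate: "
                f"block={block}, condition={cond}, time={t}"
            )
        removals.append((block, cond, t, ids[rng.integers(len(ids))]))
    return dataset.drop_replicates(removals, validate=False), removals


def subsample_draw(
    dataset: NestedDataset, rng: np.random.Generator
) -> tuple[NestedDataset, DrawLog]:
    """Keep exactly one uniformly chosen replicate per cell (leave-one-in)."""
    rep_map = dataset.replicate_map()
    keeps: DrawLog = []
    for block, cond, t in _cells(dataset):
        ids = rep_map[(block, cond, t)]
        keeps.append((block, cond, t, ids[rng.integers(len(ids))]))
    return dataset.keep_replicates(keeps, validate=False), keeps


def paired_draw(
    dataset: NestedDataset, method: str, rng: np.random.Generator
) -> tuple[NestedDataset, DrawLog]:
    """Couple the draw between blocks: the same pairing_id per cell in X and Y.

    Requires identical X and Y time grids (restrict the Y design with
    ``subset_design`` first) and full pairing coverage in every cell.
    """
    d = dataset.design
    if d.x.times != d.y.times:
        raise DatasetError(
            "paired resampling requires matching X and Y time grids; "
            "restrict the Y design with subset_design first "
            f"(X times {d.x.times}, Y times {d.y.times})"
        )
    rep_map = dataset.replicate_map()
    pair_map = dataset.pairing_map()
    chosen: DrawLog = []
    for cond in d.conditions:
        for t in d.x.times:
            maps = {b: pair_map.get((b, cond, t), {}) for b in BLOCKS}
            for b in BLOCKS:
                if len(maps[b]) != len(rep_map[(b, cond, t)]):
                    raise DatasetError(
                        f"cell lacks full pairing coverage: block={b}, "
                        f"condition={cond}, time={t}"
                    )
            common = sorted(set(maps["X"]) & set(maps["Y"]))
            if not common:
                raise DatasetError(
                    f"no shared pairing_ids in cell condition={cond}, time={t}"
                )
            if method == "jackknife" and len(common) < 2:
                raise DatasetError(
                    f"jackknife undefined for paired cell with a single pairing: "
                    f"condition={cond}, time={t}"
                )
            pid = common[rng.integers(len(common))]
            for b in BLOCKS:
                chosen.append((b, cond, t, maps[b][pid]))
    if method == "jackknife":
        return dataset.drop_replicates(chosen, validate=False), chosen
    return dataset.keep_replicates(chosen, validate=False), chosen


@dataclass
class ResamplingEnsemble:
    scheme: ResamplingScheme
    reference: dict[str, np.ndarray]  # global-model coordinates, axis -> n_lvs x dim
    members: dict[str, np.ndarray]  # axis -> n_members x n_lvs x dim (sign-aligned)
    signs: np.ndarray  # n_members x n_lvs alignment flips applied
    cv_curves: np.ndarray | None  # n_members x max_lvs standardized RMSE
    iteration_log: list[DrawLog]
    n_failed: int
    failures: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return next(iter(self.members.values())).shape[0]

    def mean(self, axis: str) -> np.ndarray:
        return self.members[axis].mean(axis=0)

    def sd(self, axis: str) -> np.ndarray:
        return self.members[axis].std(axis=0)

    def robust(self, axis: str) -> np.ndarray:
        """Mean +/- SD interval strictly excludes zero."""
        return np.abs(self.mean(axis)) > self.sd(axis)


def align_signs(
    member_coords: dict[str, np.ndarray], reference: dict[str, np.ndarray]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Sign-align one member's coordinates to the reference model's."""
    signs = alignment_signs(member_coords, reference)
    return apply_signs(member_coords, signs), signs


def run_ensemble(
    dataset: NestedDataset,
    scheme: ResamplingScheme,
    spec: StandardizationSpec,
    settings: FitSettings,
    reference_model: NPLSModel | None = None,
    compute_cv: bool = True,
    max_lvs: int | None = None,
    max_failure_fraction: float = 0.2,
) -> ResamplingEnsemble:
    """Draw, refit and summarize ``scheme.n_iter`` resampled models.

    ``settings.n_lvs`` is overridden by ``scheme.n_lvs`` (the fixed LV count
    of the corresponding global-average model).  Standardization inside the
    loop is lenient so an n-of-one draw with a constant slab does not abort
    the ensemble; individual failures are logged and excluded, and more than
    ``max_failure_fraction`` failures aborts with diagnostics.
    """
    fit_settings = FitSettings(
        n_lvs=scheme.n_lvs, tol=settings.tol,
        max_iterations=settings.max_iterations, seed=settings.seed,
    )
    if reference_model is None:
        tensors, _ = standardize(average_replicates(dataset), spec)
        reference_model = fit(tensors.X, tensors.Y, fit_settings)
    if reference_model.n_lvs != scheme.n_lvs:
        raise NPLSError(
            f"reference model has {reference_model.n_lvs} LVs, scheme fixes {scheme.n_lvs}"
        )
    ref_coords = weight_coordinates(reference_model)
    lenient = spec.with_zero_variance("lenient")
    cv_max = max_lvs if max_lvs is not None else scheme.n_lvs

    member_arrays: dict[str, list[np.ndarray]] = {}
    sign_rows: list[np.ndarray] = []
    cv_rows: list[np.ndarray] = []
    logs: list[DrawLog] = []
    failures: list[str] = []

    seeds = np.random.SeedSequence(scheme.seed).spawn(scheme.n_iter)
    for it in range(scheme.n_iter):
        rng = np.random.default_rng(seeds[it])
        try:
            if scheme.pairing == "paired":
                draw, log = paired_draw(dataset, scheme.method, rng)
            elif scheme.method == "jackknife":
                draw, log = jackknife_draw(dataset, rng)
            else:
                draw, log = subsample_draw(dataset, rng)
            raw = average_replicates(draw)
            std, _ = standardize(raw, lenient)
            model = fit(std.X, std.Y, fit_settings)
            if compute_cv:
                cv = loo_crossvalidate(raw, lenient, fit_settings, cv_max)
                cv_rows.append(cv.rmse)
        except (DatasetError, NPLSError, ValueError) as exc:
            if isinstance(exc, DatasetError) and "undefined" in str(exc):
                raise  # structural problem, not a degenerate draw
            failures.append(f"iteration {it}: {exc}")
            continue
        coords, signs = align_signs(weight_coordinates(model), ref_coords)
        for axis, arr in coords.items():
            member_arrays.setdefault(axis, []).append(arr)
        sign_rows.append(signs)
        logs.append(log)

    n_failed = len(failures)
    if n_failed > max_failure_fraction * scheme.n_iter:
        raise NPLSError(
            f"{n_failed}/{scheme.n_iter} resampling iterations failed; "
            f"first failures: {failures[:3]}"
        )
    if not sign_rows:
        raise NPLSError("no successful resampling iterations")
    return ResamplingEnsemble(
        scheme=scheme,
        reference=ref_coords,
        members={axis: np.array(rows) for axis, rows in member_arrays.items()},
        signs=np.array(sign_rows),
        cv_curves=np.array(cv_rows) if cv_rows else None,
        iteration_log=logs,
        n_failed=n_failed,
        failures=failures,
    )


def summarize_robustness(
    ensemble: ResamplingEnsemble,
    tensors: TensorPair,
    significance_mask: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-coordinate mean, SD and robustness flags as a long table."""
    if ensemble.n_members == 0:
        raise NPLSError("empty ensemble")
    rows = []
    for axis in WEIGHT_AXES:
        labels = axis_labels(
            axis, tensors.x_times, tensors.x_vars, tensors.y_times, tensors.y_vars
        )
        mean = ensemble.mean(axis)
        sd = ensemble.sd(axis)
        robust = ensemble.robust(axis)
        block = "X" if axis.startswith("x") else "Y"
        for n in range(mean.shape[0]):
            for idx, label in enumerate(labels):
                row = {
                    "block": block,
                    "lv": n + 1,
                    "axis": axis,
                    "label": label,
                    "mean": mean[n, idx],
                    "sd": sd[n, idx],
                    "robust": bool(robust[n, idx]),
                }
                if significance_mask is not None:
                    row["significant"] = bool(significance_mask[axis][n, idx])
                    row["retained"] = row["significant"] and row["robust"]
                rows.append(row)
    return pd.DataFrame(rows)


def robust_fractions(
    ensemble: ResamplingEnsemble,
    axis: str,
    significance_mask: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-LV robust fraction on one axis, with both denominators.

    ``robust_fraction`` uses all coordinates; ``retained_fraction`` uses only
    the coordinates flagged significant by the randomization null.
    """
    robust = ensemble.robust(axis)
    n_lvs, dim = robust.shape
    rows = []
    for n in range(n_lvs):
        row = {
            "lv": n + 1,
            "axis": axis,
            "robust_fraction": float(robust[n].mean()),
        }
        if significance_mask is not None:
            sig = significance_mask[axis][n]
            row["n_significant"] = int(sig.sum())
            row["retained_fraction"] = (
                float(robust[n][sig].mean()) if sig.any() else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def rmse_comparison(
    global_cv: CVResult, ensembles: dict[str, ResamplingEnsemble]
) -> pd.DataFrame:
    """Global vs. resampled-mean crossvalidated RMSE per LV count."""
    out = pd.DataFrame(
        {
            "lv_count": np.arange(1, global_cv.max_lvs + 1),
            "global_rmse": global_cv.rmse,
        }
    )
    for name, ens in ensembles.items():
        if ens.cv_curves is None:
            raise NPLSError(f"ensemble {name!r} was run without crossvalidation")
        if ens.cv_curves.shape[1] != global_cv.max_lvs:
            raise NPLSError(
                f"ensemble {name!r} CV curve length {ens.cv_curves.shape[1]} "
                f"does not match global {global_cv.max_lvs}"
            )
        out[f"{name}_mean_rmse"] = ens.cv_curves.mean(axis=0)
    return out
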