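"""Generator of nested-replicate datasets with planted tri-linear structure.

Cell-level means are sums of rank-1 latent contributions; each replicate adds
an animal-level normal offset shared across every variable it contributes in
that cell (which is what makes the nesting statistically real) plus i.i.d.
measurement noise.  Ground truth is returned so recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crossval import loo_crossvalidate
from .dataset import OBS_COLUMNS, NestedDataset, TensorPair, average_replicates, dataset_from_frame
from .npls import FitSettings, fit
from .nullmodel import build_null, classify_significant
from .resampling import ResamplingScheme, robust_fractions, rmse_comparison, run_ensemble
from .standardize import StandardizationSpec, modes23_spec, standardize

__all__ = [
    "PlantedModel",
    "random_planted",
    "generate",
    "planted_tensors",
    "paper_shaped_fixture",
    "regime_sweep",
]


@dataclass(frozen=True)
class PlantedModel:
    conditions: tuple[str, ...]
    x_times: tuple[float, ...]
    x_vars: tuple[str, ...]
    y_times: tuple[float, ...]
    y_vars: tuple[str, ...]
    t: np.ndarray  # n_lvs x i condition scores
    w_time: np.ndarray  # n_lvs x j, unit norm
    w_var: np.ndarray  # n_lvs x k, unit norm
    q_time: np.ndarray  # n_lvs x l, unit norm
    q_var: np.ndarray  # n_lvs x m, unit norm
    b: np.ndarray  # n_lvs inner coefficients
    replicate_noise_sd: float = 0.0
    measurement_noise_sd: float = 0.0
    x_replicates: int = 3
    y_replicates: int = 3
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_noise_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.paired and self.x_replicates != self.y_replicates:
            raise ValueError("paired generation requires equal replicate counts")

    @property
    def n_lvs_true(self) -> int:
        return self.t.shape[0]

    def with_noise(self, replicate_sd: float, measurement_sd: float | None = None,
                   seed: int | None = None) -> "PlantedModel":
        return replace(
            self,
            replicate_noise_sd=replicate_sd,
            measurement_noise_sd=(self.measurement_noise_sd if measurement_sd is None
                                  else measurement_sd),
            seed=self.seed if seed is None else seed,
        )


def _unit_rows(mat: np.ndarray) -> np.ndarray:
    return mat / np.linalg.norm(mat, axis=1, keepdims=True)


def random_planted(
    n_conditions: int,
    n_x_times: int,
    n_x_vars: int,
    n_y_times: int,
    n_y_vars: int,
    n_lvs: int,
    strengths: tuple[float, ...] | None = None,
    seed: int = 0,
    **kwargs,
) -> PlantedModel:
    """Random planted model with orthogonal loadings and decreasing strengths.

    Orthogonality across LVs (per factor) makes the planted components
    identifiable; ``strengths`` scales the condition scores of each LV.
    """
    rng = np.random.default_rng(seed)
    if strengths is None:
        strengths = tuple(2.0 ** (-n) for n in range(n_lvs))
    if len(strengths) != n_lvs:
        raise ValueError("strengths must have one entry per LV")

    def ortho(rows: int, dim: int) -> np.ndarray:
        # orthogonal rows when the dimension allows (identifiability);
        # random unit rows otherwise (e.g. few output variables)
        if rows > dim:
            return _unit_rows(rng.standard_normal((rows, dim)))
        q, _ = np.linalg.qr(rng.standard_normal((dim, rows)))
        return q.T

    t = ortho(n_lvs, n_conditions) * np.array(strengths)[:, None] * np.sqrt(n_conditions)
    return PlantedModel(
        conditions=tuple(f"c{i + 1}" for i in range(n_conditions)),
        x_times=tuple(float(j) for j in range(n_x_times)),
        x_vars=tuple(f"x{v + 1}" for v in range(n_x_vars)),
        y_times=tuple(float(j) for j in range(n_y_times)),
        y_vars=tuple(f"y{v + 1}" for v in range(n_y_vars)),
        t=t,
        w_time=ortho(n_lvs, n_x_times),
        w_var=ortho(n_lvs, n_x_vars),
        q_time=ortho(n_lvs, n_y_times),
        q_var=ortho(n_lvs, n_y_vars),
        b=np.ones(n_lvs),
        seed=seed,
        **kwargs,
    )


def planted_tensors(planted: PlantedModel) -> TensorPair:
    """Noise-free cell-mean tensors implied by the planted structure."""
    X = np.einsum("ni,nj,nk->ijk", planted.t, planted.w_time, planted.w_var)
    Y = np.einsum("n,ni,nl,nm->ilm", planted.b, planted.t, planted.q_time, planted.q_var)
    return TensorPair(
        X=X, Y=Y, conditions=planted.conditions,
        x_times=planted.x_times, x_vars=planted.x_vars,
        y_times=planted.y_times, y_vars=planted.y_vars,
    )


def generate(planted: PlantedModel) -> tuple[NestedDataset, dict]:
    """Draw a replicated long-format dataset around the planted cell means."""
    rng = np.random.default_rng(planted.seed)
    means = planted_tensors(planted)
    rows = []
    for block, arr, times, variables, n_rep in (
        ("X", means.X, planted.x_times, planted.x_vars, planted.x_replicates),
        ("Y", means.Y, planted.y_times, planted.y_vars, planted.y_replicates),
    ):
        for ci, cond in enumerate(planted.conditions):
            for ti, t in enumerate(times):
                offsets = rng.normal(0.0, planted.replicate_noise_sd, size=n_rep)
                for r in range(n_rep):
                    rid = f"{block.lower()}a{r + 1}"
                    pid = f"animal{r + 1}" if planted.paired else pd.NA
                    noise = rng.normal(0.0, planted.measurement_noise_sd, size=len(variables))
                    for vi, v in enumerate(variables):
                        rows.append(
                            (cond, float(t), "", v, block, rid, pid,
                             arr[ci, ti, vi] + offsets[r] + noise[vi])
                        )
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    truth = {
        "n_lvs_true": planted.n_lvs_true,
        "t": planted.t.tolist(),
        "w_time": planted.w_time.tolist(),
        "w_var": planted.w_var.tolist(),
        "q_time": planted.q_time.tolist(),
        "q_var": planted.q_var.tolist(),
        "b": planted.b.tolist(),
        "replicate_noise_sd": planted.replicate_noise_sd,
        "measurement_noise_sd": planted.measurement_noise_sd,
        "seed": planted.seed,
    }
    return dataset_from_frame(obs), truth


_STUDY_SHAPES = {
    # (i, j, k, l, m, n_lvs, x replicates, y replicates, x times, y times)
    "bersi": dict(
        conditions=("ATA", "DTA", "SAA", "IAA"),
        x_times=(0.0, 4.0, 14.0, 28.0),
        y_times=(0.0, 4.0, 7.0, 14.0, 21.0, 28.0),
        n_x_vars=17, n_y_vars=12, n_lvs=4, x_replicates=2, y_replicates=4,
    ),
    "lau": dict(
        conditions=("duodenum-5ug", "duodenum-10ug", "ileum-5ug", "ileum-10ug"),
        x_times=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
        y_times=(0.0, 0.5, 1.0, 2.0, 4.0, 8.0),
        n_x_vars=12, n_y_vars=2, n_lvs=3, x_replicates=5, y_replicates=5,
    ),
    "chit": dict(
        conditions=tuple(f"stim{i + 1}" for i in range(10)),
        x_times=(0.0, 5 / 60, 0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0),
        y_times=(4.0, 8.0, 16.0),
        n_x_vars=19, n_y_vars=9, n_lvs=4, x_replicates=3, y_replicates=2,
    ),
}


def paper_shaped_fixture(study: str, seed: int = 0, **overrides) -> PlantedModel:
    """Dimension template matching one of the three source studies.

    ``bersi``: 4 aortic regions, 17 input / 12 output variables, N=2 / N=4;
    ``lau``: intestinal segments x doses, 12 inputs / 2 outputs, N=5;
    ``chit``: 10 stimulus conditions, 19 inputs / 9 gene clusters, N=3 / N=2.
    The planted structure is a seeded placeholder; only shapes and replicate
    counts mirror the studies.
    """
    if study not in _STUDY_SHAPES:
        raise KeyError(f"unknown study {study!r}; choose from {sorted(_STUDY_SHAPES)}")
    shape = dict(_STUDY_SHAPES[study])
    base = random_planted(
        n_conditions=len(shape["conditions"]),
        n_x_times=len(shape["x_times"]),
        n_x_vars=shape["n_x_vars"],
        n_y_times=len(shape["y_times"]),
        n_y_vars=shape["n_y_vars"],
        n_lvs=shape["n_lvs"],
        seed=seed,
        x_replicates=shape["x_replicates"],
        y_replicates=shape["y_replicates"],
    )
    base = replace(
        base,
        conditions=shape["conditions"],
        x_times=shape["x_times"],
        y_times=shape["y_times"],
    )
    return replace(base, **overrides) if overrides else base


def regime_sweep(
    base: PlantedModel,
    noise_grid: tuple[float, ...],
    n_repeats: int = 1,
    seed: int = 0,
    spec: StandardizationSpec | None = None,
    n_iter_null: int = 100,
    n_iter_resample: int = 100,
    compute_cv: bool = True,
    robust_axis: str = "y_var",
) -> pd.DataFrame:
    """Run the full pipeline across replicate-noise levels.

    For each noise level and repeat: generate data, fit the global model at
    the planted LV count, crossvalidate, build the randomization null, run
    jackknife and subsample ensembles, and record per-LV robust fractions and
    the RMSE gap between resampled and global curves.
    """
    if not noise_grid:
        raise ValueError("noise_grid must be non-empty")
    if spec is None:
        spec = modes23_spec(zero_variance="lenient")
    n_lvs = base.n_lvs_true
    max_lvs = min(len(base.conditions) - 1, n_lvs)
    rows = []
    ss = np.random.SeedSequence(seed)
    for noise in noise_grid:
        for rep in range(n_repeats):
            run_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            planted = base.with_noise(noise, seed=run_seed)
            dataset, _ = generate(planted)
            raw = average_replicates(dataset)
            std, _ = standardize(raw, spec)
            settings = FitSettings(n_lvs=max_lvs, seed=run_seed)
            model = fit(std.X, std.Y, settings)
            cv = loo_crossvalidate(raw, spec, settings, max_lvs)
            null = build_null(raw, spec, settings, model,
                              n_iter=n_iter_null, seed=run_seed)
            mask = classify_significant(model, null)
            for method in ("jackknife", "subsample"):
                scheme = ResamplingScheme(
                    method=method, n_iter=n_iter_resample,
                    seed=run_seed, n_lvs=max_lvs,
                )
                ensemble = run_ensemble(
                    dataset, scheme, spec, settings,
                    reference_model=model, compute_cv=compute_cv, max_lvs=max_lvs,
                )
                fractions = robust_fractions(ensemble, robust_axis, significance_mask=mask)
                if compute_cv:
                    comparison = rmse_comparison(cv, {method: ensemble})
                for _, frac in fractions.iterrows():
                    n = int(frac["lv"])
                    row = {
                        "noise": noise,
                        "repeat": rep,
                        "method": method,
                        "lv": n,
                        "axis": robust_axis,
                        "robust_fraction": frac["robust_fraction"],
                        "retained_fraction": frac.get("retained_fraction", float("nan")),
                        "global_rmse": cv.rmse[n - 1],
                    }
                    if compute_cv:
                        row["resampled_mean_rmse"] = comparison[f"{method}_mean_rmse"][n - 1]
                    rows.append(row)
    return pd.DataFrame(rows)
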