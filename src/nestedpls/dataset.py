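"""Data model and I/O for replicated, nested, fully crossed condition x time studies.

The canonical on-disk format is a long (tidy) CSV with one row per observation:

    condition,time,time_unit,variable,block,replicate_id,pairing_id,value

Observations are nested: a ``replicate_id`` groups every measurement one
animal contributed within one condition x time cell of one block, so removing
a replicate removes all of its observations together.  ``pairing_id``
optionally links the X- and Y-block observations of the same animal.
"""

from __future__ import annotations

import io
from dataclasses import InitVar, dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockDesign",
    "Design",
    "NestedDataset",
    "TensorPair",
    "DatasetError",
    "read_long_csv",
    "write_long_csv",
    "dataset_from_frame",
    "average_replicates",
    "simulate_replicates_from_summary",
    "subset_design",
]

OBS_COLUMNS = [
    "condition",
    "time",
    "time_unit",
    "variable",
    "block",
    "replicate_id",
    "pairing_id",
    "value",
]

BLOCKS = ("X", "Y")


class DatasetError(ValueError):
    """Raised when a long table violates the nested-design contract."""


@dataclass(frozen=True)
class BlockDesign:
    """Time grid and variable list of one data block."""

    times: tuple[float, ...]
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise DatasetError("block has an empty time grid")
        if len(self.variables) == 0:
            raise DatasetError("block has an empty variable list")
        if list(self.times) != sorted(self.times):
            object.__setattr__(self, "times", tuple(sorted(self.times)))


@dataclass(frozen=True)
class Design:
    """Fully crossed design: shared conditions, per-block time/variable grids."""

    conditions: tuple[str, ...]
    x: BlockDesign
    y: BlockDesign
    time_unit: str = ""

    def block(self, name: str) -> BlockDesign:
        if name == "X":
            return self.x
        if name == "Y":
            return self.y
        raise KeyError(name)


@dataclass
class TensorPair:
    """Dense i x j x k independent and i x l x m dependent arrays with labels."""

    X: np.ndarray
    Y: np.ndarray
    conditions: tuple[str, ...]
    x_times: tuple[float, ...]
    x_vars: tuple[str, ...]
    y_times: tuple[float, ...]
    y_vars: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        i = len(self.conditions)
        if self.X.shape != (i, len(self.x_times), len(self.x_vars)):
            raise DatasetError(
                f"X shape {self.X.shape} does not match labels "
                f"({i}, {len(self.x_times)}, {len(self.x_vars)})"
            )
        if self.Y.shape != (i, len(self.y_times), len(self.y_vars)):
            raise DatasetError(
                f"Y shape {self.Y.shape} does not match labels "
                f"({i}, {len(self.y_times)}, {len(self.y_vars)})"
            )
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise DatasetError("tensors must be dense and finite")

    def block(self, name: str) -> np.ndarray:
        return self.X if name == "X" else self.Y

    def copy(self) -> "TensorPair":
        return TensorPair(
            self.X.copy(), self.Y.copy(), self.conditions,
            self.x_times, self.x_vars, self.y_times, self.y_vars,
        )


@dataclass
class NestedDataset:
    """Replicated long-format observations plus the design they fill."""

    obs: pd.DataFrame
    design: Design
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        self.obs = self.obs.reset_index(drop=True)
        if validate:
            _validate(self.obs, self.design)

    # -- introspection -------------------------------------------------

    def replicate_map(self) -> dict[tuple[str, str, float], list[str]]:
        """(block, condition, time) -> sorted replicate ids, in one pass."""
        grouped = self.obs.groupby(["block", "condition", "time"], sort=False)[
            "replicate_id"
        ].unique()
        return {key: sorted(ids) for key, ids in grouped.items()}

    def pairing_map(self) -> dict[tuple[str, str, float], dict[str, str]]:
        """(block, condition, time) -> {pairing_id: replicate_id}, paired rows only."""
        paired = self.obs[self.obs["pairing_id"].notna()]
        out: dict[tuple[str, str, float], dict[str, str]] = {}
        sub = paired[["block", "condition", "time", "pairing_id", "replicate_id"]].drop_duplicates()
        for row in sub.itertuples(index=False):
            out.setdefault((row.block, row.condition, row.time), {})[row.pairing_id] = (
                row.replicate_id
            )
        return out

    def replicate_counts(self) -> pd.DataFrame:
        """Unique replicates per (block, condition, time) cell."""
        counts = (
            self.obs.groupby(["block", "condition", "time"], sort=True)["replicate_id"]
            .nunique()
            .rename("n_replicates")
            .reset_index()
        )
        return counts

    def cell_replicates(self, block: str, condition: str, time: float) -> list[str]:
        m = (
            (self.obs["block"] == block)
            & (self.obs["condition"] == condition)
            & (self.obs["time"] == time)
        )
        return sorted(self.obs.loc[m, "replicate_id"].unique())

    def cell_pairings(self, block: str, condition: str, time: float) -> dict[str, str]:
        """pairing_id -> replicate_id map for one cell (paired rows only)."""
        m = (
            (self.obs["block"] == block)
            & (self.obs["condition"] == condition)
            & (self.obs["time"] == time)
            & self.obs["pairing_id"].notna()
        )
        sub = self.obs.loc[m, ["pairing_id", "replicate_id"]].drop_duplicates()
        return dict(zip(sub["pairing_id"], sub["replicate_id"]))

    def _row_keys(self) -> pd.Series:
        return pd.Series(
            list(
                zip(
                    self.obs["block"],
                    self.obs["condition"],
                    self.obs["time"],
                    self.obs["replicate_id"],
                )
            ),
            index=self.obs.index,
        )

    def drop_replicates(
        self, removals: Iterable[tuple[str, str, float, str]], validate: bool = True
    ) -> "NestedDataset":
        """Remove whole replicates given (block, condition, time, replicate_id) keys."""
        removals = set(removals)
        if not removals:
            return NestedDataset(self.obs.copy(), self.design, validate=validate)
        mask = ~self._row_keys().isin(removals)
        return NestedDataset(self.obs.loc[mask].copy(), self.design, validate=validate)

    def keep_replicates(
        self, keeps: Iterable[tuple[str, str, float, str]], validate: bool = True
    ) -> "NestedDataset":
        mask = self._row_keys().isin(set(keeps))
        return NestedDataset(self.obs.loc[mask].copy(), self.design, validate=validate)

    def equals(self, other: "NestedDataset") -> bool:
        a = self.obs.sort_values(OBS_COLUMNS).reset_index(drop=True)
        b = other.obs.sort_values(OBS_COLUMNS).reset_index(drop=True)
        return a.equals(b) and self.design == other.design


def _validate(obs: pd.DataFrame, design: Design) -> None:
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    bad_block = set(obs["block"].unique()) - set(BLOCKS)
    if bad_block:
        raise DatasetError(f"unknown block labels: {sorted(bad_block)}")
    if not np.isfinite(obs["value"].to_numpy(dtype=float)).all():
        raise DatasetError("non-finite values in 'value' column")

    # duplicate measurement for one replicate
    dup = obs.duplicated(["block", "condition", "time", "variable", "replicate_id"])
    if dup.any():
        rows = obs.index[dup].tolist()[:5]
        raise DatasetError(
            f"duplicate (cell, replicate_id, variable) rows, e.g. rows {rows}"
        )

    conds = set(obs["condition"].unique())
    if conds - set(design.conditions):
        raise DatasetError(
            f"conditions outside the design: {sorted(conds - set(design.conditions))}"
        )

    for block in BLOCKS:
        sub = obs[obs["block"] == block]
        bd = design.block(block)
        extra_t = set(sub["time"].unique()) - set(bd.times)
        if extra_t:
            raise DatasetError(f"{block}: times outside the design: {sorted(extra_t)}")
        extra_v = set(sub["variable"].unique()) - set(bd.variables)
        if extra_v:
            raise DatasetError(f"{block}: variables outside the design: {sorted(extra_v)}")
        # full crossing with >=1 replicate, and rectangular replicates within a cell
        for cond in design.conditions:
            for t in bd.times:
                cell = sub[(sub["condition"] == cond) & (sub["time"] == t)]
                if cell.empty:
                    raise DatasetError(
                        f"designed cell has no replicates: block={block}, "
                        f"condition={cond}, time={t}"
                    )
                per_rep = cell.groupby("replicate_id")["variable"].apply(set)
                want = set(bd.variables)
                for rid, got in per_rep.items():
                    if got != want:
                        raise DatasetError(
                            f"replicate {rid!r} in cell (block={block}, condition={cond}, "
                            f"time={t}) is missing variables {sorted(want - got)}"
                        )
                # pairing consistency within the cell
                paired = cell[cell["pairing_id"].notna()]
                if not paired.empty:
                    by_pair = paired.groupby("pairing_id")["replicate_id"].nunique()
                    if (by_pair > 1).any():
                        bad = by_pair[by_pair > 1].index.tolist()
                        raise DatasetError(
                            f"pairing_id collision in cell (block={block}, condition={cond}, "
                            f"time={t}): pairing_ids {bad} map to multiple replicate_ids"
                        )
                    by_rep = paired.groupby("replicate_id")["pairing_id"].nunique()
                    if (by_rep > 1).any():
                        bad = by_rep[by_rep > 1].index.tolist()
                        raise DatasetError(
                            f"replicate under two pairing_ids in cell (block={block}, "
                            f"condition={cond}, time={t}): replicate_ids {bad}"
                        )


def _design_from_frame(obs: pd.DataFrame) -> Design:
    conds = tuple(pd.unique(obs["condition"]))
    units = [u for u in pd.unique(obs["time_unit"]) if isinstance(u, str) and u]
    unit = units[0] if units else ""
    blocks = {}
    for block in BLOCKS:
        sub = obs[obs["block"] == block]
        if sub.empty:
            raise DatasetError(f"no observations for block {block}")
        blocks[block] = BlockDesign(
            times=tuple(sorted(sub["time"].unique())),
            variables=tuple(pd.unique(sub["variable"])),
        )
    return Design(conditions=conds, x=blocks["X"], y=blocks["Y"], time_unit=unit)


def dataset_from_frame(obs: pd.DataFrame, design: Design | None = None) -> NestedDataset:
    obs = obs.copy()
    obs["time"] = obs["time"].astype(float)
    obs["value"] = obs["value"].astype(float)
    obs["condition"] = obs["condition"].astype(str)
    obs["variable"] = obs["variable"].astype(str)
    obs["replicate_id"] = obs["replicate_id"].astype(str)
    if "pairing_id" not in obs.columns:
        obs["pairing_id"] = pd.NA
    obs["pairing_id"] = obs["pairing_id"].astype(object).where(
        obs["pairing_id"].notna(), pd.NA
    )
    if "time_unit" not in obs.columns:
        obs["time_unit"] = ""
    if design is None:
        design = _design_from_frame(obs)
    return NestedDataset(obs[OBS_COLUMNS], design)


def read_long_csv(path, schema: Mapping[str, str] | None = None) -> NestedDataset:
    """Read a long-format CSV into a validated :class:`NestedDataset`.

    ``schema`` optionally maps canonical column names to the file's column
    names, e.g. ``{"condition": "region"}``.
    """
    df = pd.read_csv(
        path,
        dtype={"replicate_id": str, "pairing_id": str},
        float_precision="round_trip",
    )
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in ("condition", "time", "variable", "block", "replicate_id", "value")
               if c not in df.columns]
    if missing:
        raise DatasetError(f"CSV is missing required columns: {missing}")
    return dataset_from_frame(df)


def write_long_csv(dataset: NestedDataset, path) -> None:
    out = dataset.obs.sort_values(OBS_COLUMNS).reset_index(drop=True)
    # %.17g guarantees an exact float round trip through the decimal text
    out.to_csv(path, index=False, float_format="%.17g")


def average_replicates(dataset: NestedDataset) -> TensorPair:
    """Global averages: the mean among replicates for every designed cell."""
    d = dataset.design
    means = (
        dataset.obs.groupby(["block", "condition", "time", "variable"], sort=False)["value"]
        .mean()
    )
    arrays = {}
    for block in BLOCKS:
        bd = d.block(block)
        index = pd.MultiIndex.from_product(
            [[block], d.conditions, bd.times, bd.variables],
            names=["block", "condition", "time", "variable"],
        )
        cell_means = means.reindex(index)
        if cell_means.isna().any():
            missing = cell_means.index[cell_means.isna()][0]
            raise DatasetError(
                f"designed cell has zero replicates: block={missing[0]}, "
                f"condition={missing[1]}, time={missing[2]}, variable={missing[3]}"
            )
        arrays[block] = cell_means.to_numpy().reshape(
            len(d.conditions), len(bd.times), len(bd.variables)
        )
    return TensorPair(
        X=arrays["X"], Y=arrays["Y"], conditions=d.conditions,
        x_times=d.x.times, x_vars=d.x.variables,
        y_times=d.y.times, y_vars=d.y.variables,
    )


def simulate_replicates_from_summary(
    table: pd.DataFrame, n_sim: int, rng_seed: int
) -> NestedDataset:
    """Simulate per-animal replicates from summary statistics.

    ``table`` holds one row per condition x time x variable with columns
    ``condition, time, variable, block, mean, sd`` (optional ``time_unit``).
    For each cell, ``n_sim`` normal draws are generated; draws for one
    synthetic animal share a replicate_id across the cell's variables.
    """
    if n_sim < 1:
        raise DatasetError("n_sim must be >= 1")
    for col in ("condition", "time", "variable", "block", "mean", "sd"):
        if col not in table.columns:
            raise DatasetError(f"summary table is missing column {col!r}")
    if (table["sd"].astype(float) < 0).any():
        bad = table.index[table["sd"].astype(float) < 0].tolist()[:5]
        raise DatasetError(f"negative sd in summary rows {bad}")
    rng = np.random.default_rng(rng_seed)
    unit = str(table["time_unit"].iloc[0]) if "time_unit" in table.columns else ""
    rows = []
    for (block, cond, t), cell in table.groupby(["block", "condition", "time"], sort=True):
        for r in range(n_sim):
            rid = f"sim{r + 1}"
            for _, row in cell.iterrows():
                val = rng.normal(float(row["mean"]), float(row["sd"]))
                rows.append((str(cond), float(t), unit, str(row["variable"]),
                             block, rid, pd.NA, val))
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return dataset_from_frame(obs)


def subset_design(
    dataset: NestedDataset,
    keep_X_times: Sequence[float] | None = None,
    keep_Y_times: Sequence[float] | None = None,
) -> NestedDataset:
    """Restrict the time grids, dropping observations outside the kept times."""
    d = dataset.design
    new_blocks = {}
    for block, keep in (("X", keep_X_times), ("Y", keep_Y_times)):
        bd = d.block(block)
        if keep is None:
            new_blocks[block] = bd
            continue
        keep = tuple(float(t) for t in keep)
        unknown = set(keep) - set(bd.times)
        if unknown:
            raise DatasetError(
                f"{block}: requested times not in the design: {sorted(unknown)}"
            )
        if not keep:
            raise DatasetError(f"{block}: empty resulting time grid")
        new_blocks[block] = BlockDesign(
            times=tuple(sorted(keep)), variables=bd.variables
        )
    new_design = Design(
        conditions=d.conditions, x=new_blocks["X"], y=new_blocks["Y"],
        time_unit=d.time_unit,
    )
    keep_mask = pd.Series(False, index=dataset.obs.index)
    for block in BLOCKS:
        bd = new_design.block(block)
        keep_mask |= (dataset.obs["block"] == block) & dataset.obs["time"].isin(bd.times)
    return NestedDataset(dataset.obs.loc[keep_mask].copy(), new_design)
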