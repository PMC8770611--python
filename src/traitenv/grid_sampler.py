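"""Spatial subsampling of plot sets to limit spatial autocorrelation.

The survey design places three one-hectare sets of one hundred contiguous
10 m x 10 m plots plus 69 scattered plots.  Using every plot of a set would
induce strong spatial autocorrelation, so each modelling dataset keeps only
a thinned subsample: a 3 x 3 grid is laid over each 10 x 10 set and 3 plots
are drawn without replacement from each grid cell, giving 27 plots per set
and 27 x 3 + 69 = 150 plots in total.  Repeating the draw yields replicate
datasets whose fits are later aggregated.

Because 10 rows (columns) do not divide evenly into 3, rows and columns are
partitioned 4/3/3 by default, producing contiguous cells of sizes
{16, 12, 12, 12, 9, 9, 12, 9, 9}.  The partition is configurable and the
seed of every replicate is recorded, so any dataset can be rebuilt exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default split of 10 rows (and columns) into 3 contiguous bands.
DEFAULT_BANDS = (4, 3, 3)


@dataclass
class SampleDataset:
    """One replicate modelling dataset: the selected plot ids and its seed."""

    replicate_id: int
    plot_ids: list = field(default_factory=list)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.plot_ids)


def _band_edges(bands: tuple[int, ...]) -> np.ndarray:
    return np.concatenate([[0], np.cumsum(bands)])


def subsample_plot_set(
    plots: pd.DataFrame,
    *,
    k: int = 3,
    rng_seed: int | np.random.Generator = 0,
    row_bands: tuple[int, ...] = DEFAULT_BANDS,
    col_bands: tuple[int, ...] = DEFAULT_BANDS,
) -> list:
    """Draw ``k`` plots without replacement from each grid cell of one set.

    ``plots`` must carry ``plot_id, row, col`` with row/col in 0..9 for the
    standard 10 x 10 layout.  Returns the selected plot ids (cell by cell,
    row-major).  A cell holding fewer than ``k`` plots raises ``ValueError``
    naming the cell.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rows = plots["row"].to_numpy()
    cols = plots["col"].to_numpy()
    redges = _band_edges(row_bands)
    cedges = _band_edges(col_bands)
    if rows.min() < 0 or rows.max() >= redges[-1] or cols.min() < 0 or cols.max() >= cedges[-1]:
        raise ValueError("row/col indices outside the grid layout")
    selected: list = []
    for ri in range(len(row_bands)):
        for ci in range(len(col_bands)):
            in_cell = (
                (rows >= redges[ri]) & (rows < redges[ri + 1])
                & (cols >= cedges[ci]) & (cols < cedges[ci + 1])
            )
            ids = plots.loc[in_cell, "plot_id"].to_numpy()
            if len(ids) < k:
                raise ValueError(
                    f"grid cell (row band {ri}, col band {ci}) holds {len(ids)} plots; "
                    f"cannot draw {k}"
                )
            pick = rng.choice(len(ids), size=k, replace=False)
            selected.extend(ids[np.sort(pick)].tolist())
    return selected


def assemble_modelling_dataset(
    sets: list[pd.DataFrame],
    scattered: pd.DataFrame,
    *,
    rng_seed: int = 0,
    replicate_id: int = 0,
    k: int = 3,
) -> SampleDataset:
    """Union the grid subsamples of each set with every scattered plot.

    With the standard layout (3 sets, k=3) this yields 150 unique plot ids.
    Duplicate plot ids across the inputs are an error.
    """
    all_ids: list = []
    for s in sets:
        all_ids.extend(s["plot_id"].tolist())
    all_ids.extend(scattered["plot_id"].tolist())
    if len(set(all_ids)) != len(all_ids):
        dupes = sorted({i for i in all_ids if all_ids.count(i) > 1})
        raise ValueError(f"duplicate plot ids across inputs: {dupes}")

    rng = np.random.default_rng(rng_seed)
    chosen: list = []
    for s in sets:
        chosen.extend(subsample_plot_set(s, k=k, rng_seed=rng))
    chosen.extend(scattered["plot_id"].tolist())
    return SampleDataset(replicate_id=replicate_id, plot_ids=chosen, seed=rng_seed)


def generate_replicates(
    sets: list[pd.DataFrame],
    scattered: pd.DataFrame,
    *,
    n_replicates: int = 10,
    base_seed: int = 0,
    k: int = 3,
) -> list[SampleDataset]:
    """Repeat the sampling design, deriving replicate seeds as base_seed + i."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [
        assemble_modelling_dataset(
            sets, scattered, rng_seed=base_seed + i, replicate_id=i + 1, k=k
        )
        for i in range(n_replicates)
    ]


def split_plot_table(plots: pd.DataFrame) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Split a full plot table into per-set frames and the scattered plots.

    Plots with a non-null ``set_id`` belong to a set; the rest are scattered.
    Sets are returned in sorted set_id order.
    """
    in_set = plots["set_id"].notna() & (plots["set_id"].astype(str) != "")
    sets = [
        g.reset_index(drop=True)
        for _, g in plots[in_set].groupby("set_id", sort=True)
    ]
    return sets, plots[~in_set].reset_index(drop=True)
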