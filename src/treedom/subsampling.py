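"""Spatially balanced grid subsampling of inventory plots.

Plots cluster in space, so ranking species over all plots can favour
locally clumped taxa. To probe this, plots are binned into equal-area
square grid cells (default 100 km) and repeated subsamples draw one plot
uniformly at random from each occupied cell; dominance is re-identified in
each subsample and compared with the complete-data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dominance as dom
from .geo import equal_area_xy
from .io import InventoryTable


@dataclass
class GridAssignment:
    """plot_id -> integer (col, row) cell in an equal-area plane."""

    cells: pd.DataFrame  # index plot_id; columns cell_col, cell_row, cell_id
    cell_km: float
    projection: str = "lambert_cylindrical_equal_area(centroid)"

    def cell_of(self, plot_id: str) -> tuple[int, int]:
        r = self.cells.loc[plot_id]
        return int(r["cell_col"]), int(r["cell_row"])


@dataclass
class SubsampleSet:
    habitat: str
    n_replicates: int
    seed: int
    replicates: list = field(default_factory=list)  # list of plot-id lists


def assign_grid_cells(plots: pd.DataFrame, cell_km: float = 100.0) -> GridAssignment:
    """Assign every plot to a square cell in the projected plane.

    One grid covers the whole study window (habitats filter occupied cells
    afterwards). The origin is the projected bounding-box minimum; cells are
    half-open, so a plot exactly on an edge goes to the increasing side.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    x, y = equal_area_xy(plots["lat"].to_numpy(), plots["lon"].to_numpy())
    col = np.floor((x - x.min()) / cell_km).astype(int)
    row = np.floor((y - y.min()) / cell_km).astype(int)
    cells = pd.DataFrame(
        {"cell_col": col, "cell_row": row, "cell_id": [f"{c}_{r}" for c, r in zip(col, row)]},
        index=plots.index,
    )
    return GridAssignment(cells=cells, cell_km=float(cell_km))


def draw_subsamples(
    table: InventoryTable,
    grid: GridAssignment,
    habitat: str,
    n: int = 100,
    seed: int = 0,
) -> SubsampleSet:
    """Draw ``n`` one-plot-per-occupied-cell subsamples for a habitat.

    Each replicate uses an independent child stream of the master seed, so
    replicates are individually reproducible.
    """
    plot_ids = table.habitat_plots(habitat).index
    if len(plot_ids) == 0:
        raise ValueError(f"habitat {habitat!r} has no plots")
    cells = grid.cells.loc[plot_ids, "cell_id"]
    groups = {cid: list(ids) for cid, ids in cells.groupby(cells).groups.items()}
    group_plots = [sorted(cells.index[cells == cid].tolist()) for cid in sorted(groups)]
    streams = np.random.SeedSequence(seed).spawn(n)
    reps = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        reps.append([plots[rng.integers(len(plots))] for plots in group_plots])
    return SubsampleSet(habitat=habitat, n_replicates=n, seed=seed, replicates=reps)


def subsample_dominance(
    table: InventoryTable,
    grid: GridAssignment,
    habitat: str,
    n: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Dominance robustness under spatially balanced subsampling.

    Returns the complete-data dominant set, per-replicate dominant sets,
    their union and intersection, and per-species fraction of replicates in
    which the species ranked as dominant.
    """
    m_full = dom.relative_abundances(table, habitat)
    full = dom.identify_dominants(dom.accumulated_abundance(m_full), threshold)
    full_set = set(full.loc[full["dominant"], "species"])

    subs = draw_subsamples(table, grid, habitat, n=n, seed=seed)
    rep_sets = []
    for plots in subs.replicates:
        sub = table.subset_plots(plots)
        m = dom.relative_abundances(sub, habitat)
        ranked = dom.identify_dominants(dom.accumulated_abundance(m), threshold)
        rep_sets.append(set(ranked.loc[ranked["dominant"], "species"]))

    union = set().union(*rep_sets) if rep_sets else set()
    inter = set.intersection(*rep_sets) if rep_sets else set()
    frac = pd.Series(
        {s: sum(s in rs for rs in rep_sets) / len(rep_sets) for s in sorted(union | full_set)},
        name="replicate_dominance_fraction",
    )
    return {
        "habitat": habitat,
        "complete_dominants": full_set,
        "replicate_dominants": rep_sets,
        "union": union,
        "intersection": inter,
        "fraction": frac,
        "subsamples": subs,
    }
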