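"""Dominant-species identification from plot-level relative abundances.

Within a habitat, each species' counts n_ij are converted to within-plot
relative abundances p_ij = n_ij / n_j; the accumulated relative abundance
d_i = sum_j p_ij ranks species, and the dominant set is the minimal rank
prefix reaching a fraction (default 50%) of D = sum_i d_i. D equals the
number of plots exactly, which conservation tests exploit.

Per-species summaries are the two axes of the dominance classification:
mean local abundance (p_ij averaged over occupied plots only) and regional
frequency (occupied plots / habitat plots). Dominants are cross-classified
into 16 classes by the quartiles of the two axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HABITATS, InventoryTable

#: Cumulative-share thresholds for the sequential (rarer-species) sweep.
SEQUENTIAL_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.925, 0.95, 0.975, 1.0)


class EmptyHabitatError(ValueError):
    """Habitat has no plots with individuals."""


@dataclass
class AbundanceMatrix:
    """Plots x species counts and relative abundances for one habitat."""

    habitat: str
    plot_ids: list
    species: list
    counts: np.ndarray  # integer, plots x species
    rel: np.ndarray  # p_ij, rows sum to 1

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)


@dataclass
class DominanceResult:
    """Ranked d_i table with dominant flags and per-species summaries."""

    habitat: str
    table: pd.DataFrame  # species, d, rank, cum_share, dominant, summaries
    D: float
    threshold: float = 0.5

    @property
    def dominants(self) -> list:
        return self.table.loc[self.table["dominant"], "species"].tolist()

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df.insert(0, "habitat", self.habitat)
        return df


def relative_abundances(table: InventoryTable, habitat: str) -> AbundanceMatrix:
    """Build the plots x species matrix of p_ij = n_ij / n_j for one habitat.

    Plots with zero individuals (e.g. emptied by identification filtering)
    are dropped; species absent from the habitat are dropped.
    """
    if habitat not in HABITATS:
        raise ValueError(f"unknown habitat {habitat!r}")
    plot_ids = table.habitat_plots(habitat).index
    recs = table.records[table.records["plot_id"].isin(plot_ids)]
    if recs.empty:
        raise EmptyHabitatError(f"habitat {habitat!r} has no occupied plots")
    wide = (
        recs.pivot_table(index="plot_id", columns="species", values="count", aggfunc="sum", fill_value=0)
        .sort_index()
    )
    wide = wide[sorted(wide.columns)]
    counts = wide.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    keep = totals > 0
    counts = counts[keep]
    rel = counts / counts.sum(axis=1, keepdims=True)
    return AbundanceMatrix(
        habitat=habitat,
        plot_ids=wide.index[keep].tolist(),
        species=wide.columns.tolist(),
        counts=counts,
        rel=rel,
    )


def accumulated_abundance(m: AbundanceMatrix) -> pd.Series:
    """d_i = sum_j p_ij per species; sums to the plot count exactly."""
    return pd.Series(m.rel.sum(axis=0), index=m.species, name="d")


def identify_dominants(d: pd.Series, threshold: float = 0.5) -> pd.DataFrame:
    """Rank species by decreasing d_i and flag the minimal prefix >= threshold*D.

    Ties in d_i break by species name (stable, input-order independent). The
    species whose inclusion first reaches the threshold is included.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(d) == 0:
        raise ValueError("empty abundance vector")
    df = d.rename("d").rename_axis("species").reset_index()
    df = df.sort_values(["d", "species"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    D = float(df["d"].sum())
    df["rank"] = np.arange(1, len(df) + 1)
    df["cum_share"] = df["d"].cumsum() / D
    m = int(np.searchsorted(df["cum_share"].to_numpy(), threshold - 1e-12) + 1)
    df["dominant"] = df["rank"] <= m
    return df


def species_summaries(m: AbundanceMatrix) -> pd.DataFrame:
    """Mean local abundance (over occupied plots) and regional frequency."""
    occ = m.counts > 0
    n_occ = occ.sum(axis=0)
    mean_local = np.where(n_occ > 0, (m.rel * occ).sum(axis=0) / np.maximum(n_occ, 1), np.nan)
    freq = n_occ / m.n_plots
    return pd.DataFrame(
        {"species": m.species, "mean_local_abundance": mean_local, "regional_frequency": freq}
    )


def classify_quartiles(
    summaries: pd.DataFrame,
    abundance_col: str = "mean_local_abundance",
    frequency_col: str = "regional_frequency",
) -> pd.Series:
    """16-class cross-classification by quartiles of abundance and frequency.

    Quartile boundaries are sample quantiles (linear interpolation) computed
    among the given species only; values exactly on a boundary go to the
    lower quartile (right-closed intervals). Class = 4*(abundance quartile - 1)
    + frequency quartile, so class 16 is the high-abundance/high-frequency
    "oligarch" corner. Requires >= 4 species; otherwise returns all-NA with
    a warning.
    """
    if len(summaries) < 4:
        import warnings

        warnings.warn("fewer than 4 species: quartile classification skipped")
        return pd.Series(pd.NA, index=summaries.index, name="quartile_class", dtype="Int64")

    def quartile(v: np.ndarray) -> np.ndarray:
        qs = np.quantile(v, [0.25, 0.5, 0.75])
        return 1 + (v[:, None] > qs[None, :]).sum(axis=1)

    qa = quartile(summaries[abundance_col].to_numpy(float))
    qf = quartile(summaries[frequency_col].to_numpy(float))
    return pd.Series(4 * (qa - 1) + qf, index=summaries.index, name="quartile_class", dtype="Int64")


def dominance_result(
    m: AbundanceMatrix, threshold: float = 0.5, classify: bool = True
) -> DominanceResult:
    """Full per-habitat dominance table: ranking, flags, summaries, classes."""
    d = accumulated_abundance(m)
    ranked = identify_dominants(d, threshold)
    summ = species_summaries(m)
    df = ranked.merge(summ, on="species", how="left")
    df["quartile_class"] = pd.array([pd.NA] * len(df), dtype="Int64")
    if classify:
        dom = df[df["dominant"]]
        if len(dom) >= 4:
            df.loc[dom.index, "quartile_class"] = classify_quartiles(dom).to_numpy()
    return DominanceResult(habitat=m.habitat, table=df, D=float(d.sum()), threshold=threshold)


def sequential_dominance(
    m: AbundanceMatrix, thresholds=SEQUENTIAL_THRESHOLDS
) -> dict[float, list]:
    """Species sets at an ascending sweep of cumulative-share thresholds.

    Sets are nested; at threshold 1.0 the set is all species in the habitat.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    d = accumulated_abundance(m)
    ranked = identify_dominants(d, thresholds[0])
    cum = ranked["cum_share"].to_numpy()
    out = {}
    for t in thresholds:
        k = int(np.searchsorted(cum, t - 1e-12) + 1)
        k = min(k, len(ranked))
        out[t] = ranked["species"].iloc[:k].tolist()
    return out


def rank_abundance_profiles(m: AbundanceMatrix, species=None) -> dict[str, pd.DataFrame]:
    """Per-species descending p_ij over occupied plots (rank-abundance panels)."""
    if species is None:
        species = m.species
    idx = {s: i for i, s in enumerate(m.species)}
    out = {}
    for s in species:
        if s not in idx:
            raise KeyError(f"species {s!r} not present in habitat {m.habitat!r}")
        col = m.rel[:, idx[s]]
        occ = col > 0
        df = pd.DataFrame({"plot_id": np.asarray(m.plot_ids)[occ], "p": col[occ]})
        out[s] = df.sort_values(["p", "plot_id"], ascending=[False, True], kind="mergesort").reset_index(
            drop=True
        )
    return out
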