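"""Inventory data model: plots, species records, validation and filters.

The canonical exchange format is long-format CSV/TSV: one row per
plot x species with an individual count, plus plot metadata (habitat,
WGS84 coordinates, plot area in ha) either merged into the same table or
supplied as a second file. Column names are remappable via a small config
mapping so files from different inventory networks load without editing.

Identification filtering mirrors standard inventory practice: only records
determined to species level are analysed; doubtful determinations
("cf.", "aff."), morphospecies and genus-level records are removed, and the
removed fraction per plot is reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

HABITATS = ("terra_firme", "floodplain", "swamp", "white_sand")

ID_STATUSES = ("species", "cf", "aff", "morphospecies", "genus_only")

#: Default column names for plot metadata and records.
DEFAULT_COLUMNS = {
    "plot_id": "plot_id",
    "habitat": "habitat",
    "lat": "lat",
    "lon": "lon",
    "area": "area_ha",
    "species": "species",
    "count": "count",
    "id_status": "id_status",
}


class FormatError(ValueError):
    """A required column is missing or unmappable."""


class ValidationError(ValueError):
    """The table violates a data-model invariant."""


@dataclass
class InventoryTable:
    """Long-format inventory: plot metadata plus per plot x species counts.

    plots: DataFrame indexed by plot_id with columns habitat, lat, lon, area_ha.
    records: DataFrame with columns plot_id, species, id_status, count.
    """

    plots: pd.DataFrame
    records: pd.DataFrame

    def habitat_plots(self, habitat: str) -> pd.DataFrame:
        return self.plots[self.plots["habitat"] == habitat]

    @property
    def n_individuals(self) -> int:
        return int(self.records["count"].sum())

    def subset_plots(self, plot_ids) -> "InventoryTable":
        ids = pd.Index(plot_ids)
        return InventoryTable(
            plots=self.plots.loc[ids],
            records=self.records[self.records["plot_id"].isin(ids)].reset_index(drop=True),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, InventoryTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.plots.sort_index(), other.plots.sort_index())
            a = self.records.sort_values(["plot_id", "species"]).reset_index(drop=True)
            b = other.records.sort_values(["plot_id", "species"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)
        except AssertionError:
            return False
        return True


@dataclass
class ValidationReport:
    n_plots: int = 0
    n_species: int = 0
    n_individuals: int = 0
    per_habitat: dict = field(default_factory=dict)
    violations: list = field(default_factory=list)
    removed_per_plot: pd.Series | None = None
    mean_removed_fraction: float | None = None

    @property
    def ok(self) -> bool:
        return not self.violations


_CF_RE = re.compile(r"(^|\s)cf\.?(\s|$)", re.IGNORECASE)
_AFF_RE = re.compile(r"(^|\s)aff\.?(\s|$)", re.IGNORECASE)
_SP_RE = re.compile(r"\ssp{1,2}\.?\s*\d*$", re.IGNORECASE)


def infer_id_status(name: str) -> str:
    """Heuristic determination level from a taxon-name string.

    "cf."/"aff." qualifiers flag doubtful determinations; a trailing
    "sp."/"sp. 1" marks a morphospecies; a single token is genus-only.
    Overridable by supplying an explicit id_status column.
    """
    name = str(name).strip()
    if _CF_RE.search(name):
        return "cf"
    if _AFF_RE.search(name):
        return "aff"
    if _SP_RE.search(name):
        return "morphospecies"
    if len(name.split()) < 2:
        return "genus_only"
    return "species"


def _remap(df: pd.DataFrame, colmap: dict, needed: list[str], what: str) -> pd.DataFrame:
    rename = {colmap[k]: k for k in colmap if colmap[k] in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")
    return df


def load_inventory(
    path: str | Path,
    plots_path: str | Path | None = None,
    colmap: dict | None = None,
    sep: str | None = None,
    exclusions: set[str] | None = None,
) -> InventoryTable:
    """Read a long-format inventory table and validate it.

    If ``plots_path`` is given, plot metadata is read from it; otherwise the
    metadata columns must be present (repeated) in the main table. Duplicate
    (plot, species) rows are summed. ``exclusions`` drops species by exact
    name (e.g. a user-supplied checklist-exclusion list).
    """
    cm = dict(DEFAULT_COLUMNS)
    if colmap:
        cm.update(colmap)
    colmap = {k: v for k, v in cm.items()}

    kw = {} if sep is None else {"sep": sep}
    raw = pd.read_csv(path, **({"sep": None, "engine": "python"} if sep is None else kw))
    raw = _remap(raw, colmap, ["plot_id", "species", "count"], str(path))

    if plots_path is not None:
        meta = pd.read_csv(plots_path, **({"sep": None, "engine": "python"} if sep is None else kw))
        meta = _remap(meta, colmap, ["plot_id", "habitat", "lat", "lon", "area"], str(plots_path))
    else:
        meta = _remap(raw, colmap, ["plot_id", "habitat", "lat", "lon", "area"], str(path))
        meta = meta[["plot_id", "habitat", "lat", "lon", "area"]].drop_duplicates("plot_id")

    plots = (
        meta[["plot_id", "habitat", "lat", "lon", "area"]]
        .rename(columns={"area": "area_ha"})
        .astype({"plot_id": str})
        .set_index("plot_id")
    )

    recs = raw[["plot_id", "species", "count"] + (["id_status"] if "id_status" in raw else [])].copy()
    recs["plot_id"] = recs["plot_id"].astype(str)
    recs["species"] = recs["species"].astype(str)

    bad = recs[~(recs["count"] > 0) | (recs["count"] % 1 != 0)]
    if len(bad):
        rows = bad.index.tolist()[:20]
        raise ValidationError(f"non-positive or non-integer counts at rows {rows}")
    recs["count"] = recs["count"].astype(int)

    if exclusions:
        recs = recs[~recs["species"].isin(exclusions)]

    if "id_status" not in recs:
        recs["id_status"] = recs["species"].map(infer_id_status)
    else:
        recs["id_status"] = recs["id_status"].fillna(recs["species"].map(infer_id_status))
        unknown = set(recs["id_status"]) - set(ID_STATUSES)
        if unknown:
            raise ValidationError(f"unknown id_status values {sorted(unknown)}")

    # duplicate (plot, species) rows are summed; status of the first kept
    recs = (
        recs.groupby(["plot_id", "species"], as_index=False, sort=True)
        .agg(count=("count", "sum"), id_status=("id_status", "first"))
        [["plot_id", "species", "id_status", "count"]]
    )

    table = InventoryTable(plots=plots, records=recs.reset_index(drop=True))
    report = validate(table)
    if not report.ok:
        raise ValidationError("; ".join(f"{c}: {m}" for c, m in report.violations))
    return table


def validate(table: InventoryTable) -> ValidationReport:
    """Check data-model invariants and tally the table."""
    rep = ValidationReport()
    plots, recs = table.plots, table.records
    if plots.index.duplicated().any():
        rep.violations.append(("duplicate_plot", "duplicate plot_id in plot metadata"))
    if not plots["habitat"].isin(HABITATS).all():
        bad = sorted(set(plots["habitat"]) - set(HABITATS))
        rep.violations.append(("bad_habitat", f"unknown habitat(s) {bad}"))
    if ((plots["lat"].abs() > 90) | (plots["lon"].abs() > 180)).any():
        rep.violations.append(("bad_coords", "coordinates outside WGS84 bounds"))
    if (plots["area_ha"] <= 0).any():
        rep.violations.append(("bad_area", "non-positive plot area"))
    orphan = ~recs["plot_id"].isin(plots.index)
    if orphan.any():
        rep.violations.append(
            ("orphan_record", f"records reference unknown plots {sorted(set(recs.loc[orphan, 'plot_id']))[:5]}")
        )
    if (recs["count"] <= 0).any():
        rep.violations.append(("bad_count", "non-positive count"))
    if recs.duplicated(["plot_id", "species"]).any():
        rep.violations.append(("dup_record", "duplicate (plot, species) after aggregation"))

    rep.n_plots = len(plots)
    rep.n_species = recs["species"].nunique()
    rep.n_individuals = int(recs["count"].sum())
    merged = recs.merge(plots["habitat"], left_on="plot_id", right_index=True, how="left")
    rep.per_habitat = {
        h: {
            "n_plots": int((plots["habitat"] == h).sum()),
            "n_species": int(merged.loc[merged["habitat"] == h, "species"].nunique()),
            "n_individuals": int(merged.loc[merged["habitat"] == h, "count"].sum()),
        }
        for h in HABITATS
    }
    return rep


def filter_identifications(table: InventoryTable) -> tuple[InventoryTable, ValidationReport]:
    """Keep only species-level records; report per-plot removed fractions.

    The removed fraction for a plot is (individuals dropped) / (individuals
    before filtering); the report's ``mean_removed_fraction`` averages this
    over plots that held at least one individual.
    """
    recs = table.records
    keep = recs["id_status"] == "species"
    totals = recs.groupby("plot_id")["count"].sum()
    kept_tot = recs[keep].groupby("plot_id")["count"].sum().reindex(totals.index, fill_value=0)
    removed = (totals - kept_tot) / totals
    out = InventoryTable(plots=table.plots, records=recs[keep].reset_index(drop=True))
    rep = validate(out)
    rep.removed_per_plot = removed
    rep.mean_removed_fraction = float(removed.mean()) if len(removed) else 0.0
    if out.records.empty:
        rep.violations.append(("empty_after_filter", "no species-level records remain"))
    return out, rep


def write_results(results, path: str | Path) -> Path:
    """Write any pipeline product to CSV with deterministic column order.

    Accepts a DataFrame, a mapping of name -> DataFrame (written as
    ``<stem>_<name>.csv`` files), or an object with a ``to_frame()`` method.
    Reloading with :func:`pandas.read_csv` reproduces the values.
    """
    path = Path(path)
    if isinstance(results, dict):
        written = []
        for name, df in results.items():
            p = path.with_name(f"{path.stem}_{name}{path.suffix or '.csv'}")
            written.append(write_results(df, p))
        return path
    if hasattr(results, "to_frame") and not isinstance(results, (pd.Series, pd.DataFrame)):
        results = results.to_frame()
    if isinstance(results, pd.Series):
        results = results.rename_axis(results.index.name or "key").reset_index()
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False)
    return path
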