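"""End-to-end orchestration: filter -> dominance -> subsampling -> models ->
threshold sweep -> aggregation, with all tables written as long CSV.

`run_full_analysis` is the single entry point used by the CLI, the analysis
drivers and the acceptance script. Every stage logs row counts and seeds;
a stage failure aborts with the stage name while earlier outputs remain on
disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation as agg
from . import betareg
from . import dominance as dom
from . import io as tdio
from . import subsampling as subs
from . import synthetic

log = logging.getLogger("treedom")


@dataclass
class RunConfig:
    """Everything a full run needs; synthetic config or input paths."""

    out_dir: str | Path = "results/run"
    seed: int = 0
    input_path: str | Path | None = None
    plots_path: str | Path | None = None
    synthetic_config: synthetic.SyntheticConfig | None = None
    habitats: tuple = tdio.HABITATS
    threshold: float = 0.5
    thresholds: tuple = dom.SEQUENTIAL_THRESHOLDS
    n_subsamples: int = 100
    cell_km: float = 100.0
    curve_species: str = "dominant"  # or "all"
    n_grid: int = 100
    skip_curves: bool = False
    skip_subsampling: bool = False
    make_plots: bool = False
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        skip = {"extra", "out_dir"}  # scientific settings only
        payload = {k: str(v) for k, v in self.__dict__.items() if k not in skip}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _load_or_simulate(cfg: RunConfig):
    if cfg.input_path is not None:
        table = tdio.load_inventory(cfg.input_path, plots_path=cfg.plots_path)
        truth = None
    else:
        scfg = cfg.synthetic_config or synthetic.SyntheticConfig(seed=cfg.seed)
        table, truth, _ = synthetic.generate(scfg)
    return table, truth


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage in order and write result tables under ``cfg.out_dir``.

    Returns a dict of in-memory products keyed by stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    products: dict = {"config": cfg}
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    stage = "load"
    try:
        t0 = time.time()
        log.info("run start seed=%s hash=%s", cfg.seed, meta["config_hash"])

        table, truth = _load_or_simulate(cfg)
        table, filt_report = tdio.filter_identifications(table)
        products["table"], products["truth"] = table, truth
        products["filter_report"] = filt_report
        log.info("load: %d plots, %d records, mean removed fraction %.3f",
                 len(table.plots), len(table.records), filt_report.mean_removed_fraction)
        if truth is not None:
            tdio.write_results(truth, out / "truth.csv")

        stage = "dominance"
        dom_results, matrices = [], {}
        for h in cfg.habitats:
            try:
                m = dom.relative_abundances(table, h)
            except dom.EmptyHabitatError:
                log.warning("habitat %s empty, skipped", h)
                continue
            matrices[h] = m
            dom_results.append(dom.dominance_result(m, threshold=cfg.threshold))
        products["matrices"] = matrices
        products["dominance"] = dom_results
        dom_table = pd.concat([r.to_frame() for r in dom_results], ignore_index=True)
        for k, v in meta.items():
            dom_table[k] = v
        tdio.write_results(dom_table, out / "dominance.csv")
        log.info("dominance: %s", {r.habitat: len(r.dominants) for r in dom_results})

        stage = "subsampling"
        if not cfg.skip_subsampling:
            grid = subs.assign_grid_cells(table.plots, cell_km=cfg.cell_km)
            rows = []
            sub_results = {}
            for h in matrices:
                res = subs.subsample_dominance(
                    table, grid, h, n=cfg.n_subsamples, seed=cfg.seed, threshold=cfg.threshold
                )
                sub_results[h] = res
                f = res["fraction"].rename_axis("species").reset_index()
                f.insert(0, "habitat", h)
                f["in_complete"] = f["species"].isin(res["complete_dominants"])
                rows.append(f)
            products["subsampling"] = sub_results
            tdio.write_results(pd.concat(rows, ignore_index=True), out / "subsample_fractions.csv")
            log.info("subsampling: %d replicates per habitat", cfg.n_subsamples)

        stage = "models"
        model_ok = [r for r in dom_results if r.table["dominant"].sum() >= 4]
        if model_ok:
            afm = betareg.abundance_frequency_model(model_ok)
            products["abundance_frequency"] = afm
            tdio.write_results(afm["ranking"], out / "model_ranking.csv")
            tdio.write_results(afm["predictions"], out / "model_predictions.csv")
            summary = afm["best"].params.rename("estimate").rename_axis("term").reset_index()
            summary["se"] = afm["best"].bse.to_numpy()
            summary["z"] = summary["estimate"] / summary["se"]
            tdio.write_results(summary, out / "model_best_terms.csv")
            log.info("models: best=%s", afm["best"].name)
        else:
            log.warning("models skipped: no habitat with >=4 dominants")

        stage = "threshold_sweep"
        traj_rows = []
        trajectories = {}
        for h, m in matrices.items():
            tr = betareg.slope_sign_trajectory(m, cfg.thresholds)
            trajectories[h] = tr
            t = tr.table.copy()
            t.insert(0, "habitat", h)
            traj_rows.append(t)
        products["trajectories"] = trajectories
        tdio.write_results(pd.concat(traj_rows, ignore_index=True), out / "slope_trajectory.csv")

        stage = "aggregation_k"
        ks_frames = []
        for h, m in matrices.items():
            r = next(x for x in dom_results if x.habitat == h)
            species = r.dominants if cfg.curve_species == "dominant" else None
            ks_frames.append(agg.k_for_dominants(table, h, species=species))
        ks_frames = [f for f in ks_frames if len(f)]
        ks = (pd.concat(ks_frames, ignore_index=True) if ks_frames
              else pd.DataFrame(columns=["habitat", "species", "k", "mean", "estimator", "converged"]))
        products["k_estimates"] = ks
        tdio.write_results(ks, out / "k_estimates.csv")

        stage = "k_regressions"
        try:
            kreg = agg.k_regressions(dom_results, ks)
            products["k_regressions"] = kreg
            tdio.write_results(kreg["abundance"]["ranking"], out / "k_model_abundance.csv")
            tdio.write_results(kreg["frequency"]["ranking"], out / "k_model_frequency.csv")
        except ValueError as e:
            log.warning("k regressions skipped: %s", e)

        stage = "codominance_curves"
        if not cfg.skip_curves:
            curve_rows = []
            curves = {}
            for h, m in matrices.items():
                if m.n_plots < 2:
                    log.warning("curves skipped for %s: <2 plots", h)
                    continue
                r = next(x for x in dom_results if x.habitat == h)
                species = r.dominants if cfg.curve_species == "dominant" else m.species
                d = agg.pairwise_distances(table.plots.loc[m.plot_ids])
                c = agg.aggregation_curves(m, d, species=species, n_grid=cfg.n_grid, seed=cfg.seed)
                c = agg.relativize_curves(c)
                curves[h] = c
                curve_rows.append(c.to_long())
            products["curves"] = curves
            if curve_rows:
                tdio.write_results(pd.concat(curve_rows, ignore_index=True), out / "codominance_curves.csv")

        stage = "recovery"
        if truth is not None:
            slopes = {}
            for h in matrices:
                r = next(x for x in dom_results if x.habitat == h)
                sub = r.table[r.table["dominant"]]
                if len(sub) >= 4:
                    try:
                        f = betareg.fit_beta_logit(
                            "mean_local_abundance ~ regional_frequency", sub, name=h
                        )
                        slopes[h] = f.slope("regional_frequency")
                    except Exception:
                        pass
            scfg = cfg.synthetic_config or synthetic.SyntheticConfig(seed=cfg.seed)
            rec = synthetic.truth_recovery_report(
                dom_results, ks, truth, table=table, fitted_slopes=slopes, rho_configured=scfg.rho
            )
            products["recovery"] = rec
            (out / "recovery.json").write_text(json.dumps(rec, indent=2, default=str))

        stage = "figures"
        if cfg.make_plots:
            _make_figures(products, out)

        log.info("run complete in %.1fs", time.time() - t0)
    except Exception as e:
        log.error("stage %r failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        log.removeHandler(fh)
        fh.close()
    return products


def _make_figures(products: dict, out: Path) -> None:
    """Optional summary figures; CSV tables remain the canonical artifact."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    afm = products.get("abundance_frequency")
    if afm is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        for h, sub in afm["predictions"].groupby("habitat"):
            line, = ax.plot(sub.iloc[:, 0], sub["fit"], label=h)
            if sub["lo"].notna().all():
                ax.fill_between(sub.iloc[:, 0], sub["lo"], sub["hi"],
                                alpha=0.2, color=line.get_color())
        for h, sub in afm["data"].groupby("habitat"):
            ax.scatter(sub["regional_frequency"], sub["mean_local_abundance"], s=8, alpha=0.5)
        ax.set_xlabel("regional frequency")
        ax.set_ylabel("mean local abundance")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "abundance_frequency.png", dpi=150)
        plt.close(fig)

    curves = products.get("curves")
    if curves:
        fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3.2), squeeze=False)
        for ax, (h, c) in zip(axes[0], curves.items()):
            if c.F_rel is not None:
                for sp in c.F_rel.columns:
                    ax.plot(c.distance_km, c.F_rel[sp], lw=0.7, alpha=0.7)
            ax.set_title(h, fontsize=9)
            ax.set_xlabel("distance (km)")
            ax.set_ylabel("relative F")
        fig.tight_layout()
        fig.savefig(out / "codominance_curves.png", dpi=150)
        plt.close(fig)
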