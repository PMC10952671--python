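"""Quantify spatial aggregation of dominant species.

Counts are standardized to each habitat's smallest plot area; the negative
binomial dispersion k is estimated per dominant (small k = strong
clumping), regressed against abundance and frequency, and the pairwise
co-dominance index F is smoothed against distance and relativized across
species. Writes k estimates, the k model rankings and the curve tables.
"""

from pathlib import Path

import pandas as pd

from treedom import aggregation as agg
from treedom import dominance as dom
from treedom import io as tdio

DATA = Path("results/data")
SEED = 1


def main():
    table = tdio.load_inventory(DATA / "inventory.csv", plots_path=DATA / "plots.csv")
    table, _ = tdio.filter_identifications(table)
    results, ks_frames, curve_rows = [], [], []
    for h in tdio.HABITATS:
        m = dom.relative_abundances(table, h)
        r = dom.dominance_result(m)
        results.append(r)
        ks = agg.k_for_dominants(table, h, species=r.dominants)
        ks_frames.append(ks)
        share = ((ks["k"] > 0) & (ks["k"] <= 1)).mean()
        print(f"{h}: {len(ks)} dominant k estimates, {share:.0%} in (0, 1]")

        dmat = agg.pairwise_distances(table.plots.loc[m.plot_ids])
        curves = agg.relativize_curves(
            agg.aggregation_curves(m, dmat, species=r.dominants, seed=SEED)
        )
        curve_rows.append(curves.to_long())

    ks = pd.concat(ks_frames, ignore_index=True)
    tdio.write_results(ks, Path("results/k_estimates.csv"))
    kreg = agg.k_regressions(results, ks[ks["k"] < 1e5])
    for label in ("abundance", "frequency"):
        slope = kreg[label]["fits"]["x"].slope("k")
        best = kreg[label]["ranking"]["model"].iloc[0]
        print(f"{label} ~ k: slope {slope:+.3f}, best model by AIC: {best}")
        tdio.write_results(kreg[label]["ranking"], Path(f"results/k_model_{label}.csv"))
    tdio.write_results(pd.concat(curve_rows, ignore_index=True),
                       Path("results/codominance_curves.csv"))
    print("wrote results/k_estimates.csv, k_model_*.csv, codominance_curves.csv")


if __name__ == "__main__":
    main()
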