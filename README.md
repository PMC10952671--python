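# treedom

Dominance patterns in forest inventory plots: who dominates a tropical
tree community, and are dominants locally abundant, regionally widespread,
or both?

Plot networks across western Amazonia show that a small set of species
accounts for half of all stems, but those dominant species differ sharply
in *how* they dominate: some form dense local stands (local dominants),
some occur thinly across many plots (widespread dominants), and a few do
both (oligarchs). `treedom` implements the full analysis pipeline for
long-format plot × species inventories, together with a synthetic
community generator with known ground truth, so every stage has a recovery
test.

## The statistics

For species *i* in plot *j* with count *n<sub>ij</sub>* and plot total
*n<sub>j</sub>*:

- relative abundance *p<sub>ij</sub> = n<sub>ij</sub> / n<sub>j</sub>*;
- accumulated relative abundance *d<sub>i</sub> = Σ<sub>j</sub> p<sub>ij</sub>*,
  with *D = Σ<sub>i</sub> d<sub>i</sub>* equal to the number of plots;
- **dominants**: the minimal set of species, ranked by decreasing
  *d<sub>i</sub>*, whose cumulative share reaches 50% of *D* (a sweep of
  thresholds up to 100% adds progressively rarer species);
- **mean local abundance**: *p<sub>ij</sub>* averaged over the plots where
  the species occurs; **regional frequency**: occupied plots / habitat
  plots. Their relationship is fitted by beta regression with a logit link,
  Beta(μφ, (1−μ)φ) with logit(μ) = Xβ, candidates compared by AIC
  (ΔAIC > 2 ⇒ no support);
- **spatial aggregation**: the negative-binomial dispersion *k* of
  area-standardized counts (small *k* = strong clumping; *k* → ∞ is the
  Poisson limit), and the co-dominance index
  *F<sub>i,jk</sub> = (n<sub>ij</sub> n<sub>ik</sub>) / (N<sub>j</sub> N<sub>k</sub>)*
  — the probability that one stem drawn from each of two plots both belong
  to species *i* — smoothed against pair distance and relativized so that
  species' curves sum to 1 at every distance;
- **robustness**: plots assigned to 100 × 100 km equal-area grid cells;
  repeated subsamples draw one plot per occupied cell and dominants are
  re-identified.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
community (503 plots split 383/54/35/31 across terra firme, floodplain,
swamp and white-sand habitats; abundance–occupancy correlation ρ = −0.8):

```sh
python analysis/01_simulate.py
python analysis/02_dominance.py
python analysis/04_abundance_frequency.py
```

prints

```
terra_firme: 89 dominant species (22% of 405 species, 383 plots, D = 383)
floodplain: 26 dominant species (14% of 185 species, 54 plots, D = 54)
swamp: 11 dominant species (9% of 125 species, 35 plots, D = 35)
white_sand: 9 dominant species (9% of 105 species, 31 plots, D = 31)
...
AIC ranking of candidate models (dominants, pooled across habitats):
      model  k_params         aic  delta_aic  supported
   additive         6 -707.324086   0.000000       True
interaction         9 -706.237632   1.086454       True
    habitat         5 -642.437811  64.886274      False
...
  terra_firme: frequency slope -2.18 (logit scale)
```

Read: a few percent of species accumulate half of all relative abundance
in every habitat, and among those dominants the frequency slope is
negative — the more locally abundant a dominant is, the fewer plots it
occupies, exactly the trade-off planted in the generator.
`analysis/03_subsampling.py` confirms the dominant sets are robust to
spatially balanced subsampling; `analysis/05_aggregation.py` estimates the
clumping *k* per dominant (negative abundance~k and positive frequency~k
slopes) and the relativized co-dominance curves;
`analysis/06_recovery.py` checks everything against the generator's truth
(Spearman k recovery 0.72, all planted oligarchs in the high–high quartile
corner).

The same pipeline runs on real data: `treedom all --input records.csv
--plots plots.csv --out results/run`, where the CSVs are long-format
plot × species counts and plot metadata (habitat, WGS84 lat/lon, area in
ha; column names remappable via `--config`).

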