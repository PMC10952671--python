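"""Synthetic forest-inventory communities with known generating parameters.

The generator emulates the structure of a western-Amazonian plot network:
four habitat strata with very uneven plot counts (default 383/54/35/31),
plot areas concentrated at 0.1 ha within 0.025-0.213 ha, spatially
clustered plot locations (Thomas process), and a species pool whose
occupancy and conditional local abundance are coupled through a Gaussian
copula with a controllable correlation rho — the abundance-occupancy
trade-off dial. Per-species negative-binomial clumping k drives both the
count dispersion and the spatial range of occupancy (low-k species occupy
plots near a species-specific cluster centre).

Planted archetypes put known species at the corners of the
abundance-frequency plane (local dominants, widespread dominants,
oligarchs) so classification and curve-shape tests have ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geo import inverse_equal_area
from .io import HABITATS, InventoryTable

#: Study-window anchor (south-western Amazonia, degrees).
LAT0, LON0 = -6.0, -73.0

#: Habitat plot tallies of the emulated network.
DEFAULT_N_PLOTS = {"terra_firme": 383, "floodplain": 54, "swamp": 35, "white_sand": 31}


@dataclass
class SpeciesGroup:
    """One stratum of the species pool sharing a trade-off correlation.

    Species are drawn from a bivariate lognormal on (occupancy, conditional
    abundance) parameterized through the dominance mass m = occupancy *
    abundance: log m has standard deviation ``mass_sd`` (fixing the shape of
    the rank-abundance distribution), and an orthogonal trade-off component
    splits log m between the two axes so that corr(log occupancy,
    log abundance) equals ``rho`` exactly.
    """

    n_species: int
    rho: float = -0.8  # corr(log-occupancy, log-conditional-abundance)
    mass_sd: float = 1.1  # sd of log dominance mass
    occ0: float = 0.25  # median occupancy fraction
    mass0: float = 0.26  # median occupancy x (stems per 0.1 ha)
    k_range: tuple = (0.05, 2.0)  # log-uniform clumping


@dataclass
class HabitatConfig:
    n_plots: int
    n_species: int
    extent_km: float = 1000.0
    n_parents: int = 12
    offspring_sd_km: float = 35.0
    groups: list = None  # list[SpeciesGroup]; default: one group with `rho`


@dataclass
class SyntheticConfig:
    """All generator knobs. Defaults emulate the study network's shape."""

    seed: int = 0
    rho: float = -0.8
    habitats: dict = field(default_factory=dict)
    n_planted: dict = field(default_factory=lambda: {"local": 2, "widespread": 2, "oligarch": 1})
    min_plot_total: int = 20
    area_mix: tuple = (0.72, 0.266, 0.014)  # at 0.1 ha / small / large
    #: per-plot fractions of individuals left unidentified (morphospecies)
    #: or doubtfully determined (cf./aff.) — removed by the pipeline filter
    id_noise: tuple = (0.14, 0.03)

    def __post_init__(self):
        if not self.habitats:
            n_sp = {"terra_firme": 400, "floodplain": 180, "swamp": 120, "white_sand": 100}
            ext = {"terra_firme": 1200.0, "floodplain": 800.0, "swamp": 500.0, "white_sand": 500.0}
            par = {"terra_firme": 25, "floodplain": 8, "swamp": 6, "white_sand": 6}
            self.habitats = {
                h: HabitatConfig(
                    n_plots=DEFAULT_N_PLOTS[h], n_species=n_sp[h], extent_km=ext[h], n_parents=par[h]
                )
                for h in HABITATS
            }
        for h, hc in self.habitats.items():
            if hc.groups is None:
                # median mass scaled so a 0.1-ha plot holds ~160 stems
                # regardless of habitat richness (realistic stem density)
                mass0 = 160.0 / (hc.n_species * np.exp(0.5 * 1.1**2))
                hc.groups = [SpeciesGroup(n_species=hc.n_species, rho=self.rho, mass0=mass0)]


def sign_flip_config(seed: int = 0, **kw) -> SyntheticConfig:
    """A pool whose abundant tier trades off while the rare tail follows a
    positive abundance-occupancy relationship — the structure behind a
    negative-to-positive slope flip along the threshold sweep."""
    cfg = SyntheticConfig(seed=seed, n_planted={"local": 0, "widespread": 0, "oligarch": 0}, **kw)
    for h, hc in cfg.habitats.items():
        n_top = max(6, hc.n_species // 10)
        hc.groups = [
            SpeciesGroup(n_species=n_top, rho=-0.9, mass_sd=0.7, occ0=0.45, mass0=3.0),
            SpeciesGroup(n_species=hc.n_species - n_top, rho=0.9, mass_sd=1.2,
                         occ0=0.25, mass0=0.15),
        ]
    return cfg


#: Archetype positions as z-scores on the habitat pool's (log-occupancy,
#: log-abundance) margins, plus the clumping k: corners of the
#: dominance-pattern continuum relative to whatever the pool looks like.
ARCHETYPES = {
    "local": (-0.7, 2.0, 0.08),
    "widespread": (2.0, -0.7, 3.0),
    "oligarch": (2.0, 2.0, 0.5),
}


def generate_landscape(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Plot metadata: Thomas-clustered locations per habitat, areas, lat/lon.

    Each habitat draws parent points uniformly in its own window (windows
    share the origin, so habitats are spatially interspersed as in real
    landscapes) and plots scatter around parents with Gaussian dispersion.
    Planar km coordinates are back-projected to WGS84 around the window
    anchor. Returns a plots DataFrame indexed by plot_id.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for h in HABITATS:
        if h not in config.habitats:
            continue
        hc = config.habitats[h]
        parents = rng.uniform(0, hc.extent_km, size=(max(hc.n_parents, 1), 2))
        which = rng.integers(len(parents), size=hc.n_plots)
        xy = parents[which] + rng.normal(0, hc.offspring_sd_km, size=(hc.n_plots, 2))
        xy = np.clip(xy, 0, hc.extent_km)
        u = rng.random(hc.n_plots)
        p_std, p_small, _ = config.area_mix
        area = np.where(
            u < p_std, 0.1,
            np.where(u < p_std + p_small, rng.uniform(0.025, 0.08, hc.n_plots),
                     rng.uniform(0.128, 0.213, hc.n_plots)),
        )
        lat, lon = inverse_equal_area(xy[:, 0], xy[:, 1], LAT0, LON0)
        for i in range(hc.n_plots):
            rows.append(
                {"plot_id": f"{h[:2]}_{i:04d}", "habitat": h, "lat": lat[i], "lon": lon[i],
                 "area_ha": float(area[i]), "x_km": xy[i, 0], "y_km": xy[i, 1]}
            )
    return pd.DataFrame(rows).set_index("plot_id")


def _draw_group(grp: SpeciesGroup, rng) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-lognormal (occupancy, conditional abundance) with
    corr(log occ, log abund) = rho via the mass decomposition."""
    rho = float(np.clip(grp.rho, -0.99, 0.99))
    v_d = grp.mass_sd**2
    v_u = (v_d / 4.0) * (1.0 - rho) / (1.0 + rho)
    d = rng.normal(0.0, grp.mass_sd, grp.n_species)
    u = rng.normal(0.0, np.sqrt(v_u), grp.n_species)
    log_occ = 0.5 * d + u
    log_ab = d - log_occ
    occ = np.clip(grp.occ0 * np.exp(log_occ), 0.005, 0.95)
    abund = np.clip((grp.mass0 / grp.occ0) * np.exp(log_ab), 0.3, 300.0)
    return occ, abund


def _species_params(config: SyntheticConfig, habitat: str, rng) -> pd.DataFrame:
    hc = config.habitats[habitat]
    frames = []
    tag = habitat[:2]
    counter = 0
    # planted archetypes: positioned relative to the primary group's margins
    g0 = hc.groups[0]
    rho_c = float(np.clip(g0.rho, -0.99, 0.99))
    v_d = g0.mass_sd**2
    v_u = (v_d / 4.0) * (1.0 - rho_c) / (1.0 + rho_c)
    sd_margin = float(np.sqrt(v_d / 4.0 + v_u))
    for arch, n in config.n_planted.items():
        z_occ, z_ab, k = ARCHETYPES[arch]
        for _ in range(n):
            jitter = rng.lognormal(0, 0.1, 3)
            occ = float(np.clip(g0.occ0 * np.exp(z_occ * sd_margin) * jitter[0], 0.005, 0.95))
            mu = float(np.clip((g0.mass0 / g0.occ0) * np.exp(z_ab * sd_margin) * jitter[1], 0.3, 300.0))
            frames.append(
                {"species": f"{tag}_{arch}_{counter:03d}", "occupancy": occ,
                 "cond_mean": mu, "k_true": k * jitter[2], "archetype": arch, "group": -1}
            )
            counter += 1
    for gi, grp in enumerate(hc.groups):
        occ, mu = _draw_group(grp, rng)
        klo, khi = grp.k_range
        k = np.exp(rng.uniform(np.log(klo), np.log(khi), grp.n_species))
        for i in range(grp.n_species):
            frames.append(
                {"species": f"{tag}_sp_{counter:04d}", "occupancy": float(occ[i]),
                 "cond_mean": float(mu[i]), "k_true": float(k[i]),
                 "archetype": "none", "group": gi}
            )
            counter += 1
    df = pd.DataFrame(frames)
    df["habitat"] = habitat
    return df


def generate_community(
    config: SyntheticConfig, landscape: pd.DataFrame, seed: int | None = None
) -> tuple[InventoryTable, pd.DataFrame]:
    """Realize counts for every habitat's species pool on the landscape.

    Occupancy: each species has a cluster centre at a random landscape
    point; plots are occupied with probability proportional to
    exp(-distance / range), the range scaling with k (strong clumping =
    short range), normalized so the expected occupied fraction equals the
    species' occupancy parameter. Counts in occupied plots are NB with mean
    scaled by plot area (floored at 1, since occupied means present). A
    background pool of rare species tops every plot up to
    ``min_plot_total`` individuals so relative abundances are well defined.

    Returns the inventory and the truth table (one row per species).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    rec_frames = []
    truth_frames = []
    for h in HABITATS:
        if h not in config.habitats:
            continue
        hc = config.habitats[h]
        plots = landscape[landscape["habitat"] == h]
        J = len(plots)
        xy = plots[["x_km", "y_km"]].to_numpy()
        areas = plots["area_ha"].to_numpy()
        params = _species_params(config, h, rng)
        truth_frames.append(params)

        counts = np.zeros((J, len(params)), dtype=np.int64)
        for si, row in enumerate(params.itertuples()):
            centre = xy[rng.integers(J)] + rng.normal(0, 20, 2)
            d = np.hypot(xy[:, 0] - centre[0], xy[:, 1] - centre[1])
            # clumping controls how far occupancy reaches from the centre
            range_km = 40.0 + 250.0 * row.k_true / (1.0 + row.k_true)
            w = np.exp(-d / range_km)
            target = max(row.occupancy * J, 1.0)
            p = np.minimum(w * target / w.sum(), 1.0)
            # renormalize the clipped probabilities toward the target
            for _ in range(3):
                shortfall = target - p.sum()
                if shortfall <= 1e-9:
                    break
                room = (p < 1.0)
                if not room.any():
                    break
                p[room] = np.minimum(p[room] * (1 + shortfall / p[room].sum()), 1.0)
            occ = rng.random(J) < p
            if not occ.any():
                occ[np.argmin(d)] = True
            mean = row.cond_mean * areas[occ] / 0.1
            k = row.k_true
            draws = rng.negative_binomial(k, k / (k + mean))
            counts[occ, si] = np.maximum(draws, 1)  # occupied means >= 1 stem

        # background pool: top up plots below the minimum stem count
        totals = counts.sum(axis=1)
        n_bg = max(hc.n_species // 2, 30)
        bg = np.zeros((J, n_bg), dtype=np.int64)
        for j in range(J):
            deficit = config.min_plot_total - totals[j]
            while deficit > 0:
                s = rng.integers(n_bg)
                c = int(rng.integers(1, 3))
                bg[j, s] += c
                deficit -= c
        sp_names = params["species"].tolist() + [f"{h[:2]}_bg_{i:03d}" for i in range(n_bg)]
        all_counts = np.concatenate([counts, bg], axis=1)
        nz = np.nonzero(all_counts)
        rec_frames.append(
            pd.DataFrame(
                {
                    "plot_id": plots.index.to_numpy()[nz[0]],
                    "species": np.asarray(sp_names)[nz[1]],
                    "id_status": "species",
                    "count": all_counts[nz],
                }
            )
        )

        # unidentified / doubtful individuals (dropped by the id filter)
        f_morpho, f_cf = config.id_noise
        if f_morpho + f_cf > 0:
            plot_tot = all_counts.sum(axis=1)
            noise_rows = []
            keep_frac = 1.0 - f_morpho - f_cf
            for j in range(J):
                for frac, status, pool in (
                    (f_morpho, "morphospecies", 25),
                    (f_cf, "cf", 8),
                ):
                    extra = int(np.floor(plot_tot[j] * frac / keep_frac + 0.5))
                    while extra > 0:
                        s = int(rng.integers(pool))
                        c = min(int(rng.integers(1, 4)), extra)
                        noise_rows.append(
                            {"plot_id": plots.index[j],
                             "species": f"{h[:2]}_{status}_{s:03d}",
                             "id_status": status, "count": c}
                        )
                        extra -= c
            if noise_rows:
                rec_frames.append(pd.DataFrame(noise_rows))

    records = (
        pd.concat(rec_frames, ignore_index=True)
        .groupby(["plot_id", "species"], as_index=False, sort=True)
        .agg(id_status=("id_status", "first"), count=("count", "sum"))
        [["plot_id", "species", "id_status", "count"]]
        .reset_index(drop=True)
    )
    truth = pd.concat(truth_frames, ignore_index=True)
    table = InventoryTable(
        plots=landscape[["habitat", "lat", "lon", "area_ha"]].copy(), records=records
    )
    return table, truth


def generate(config: SyntheticConfig) -> tuple[InventoryTable, pd.DataFrame, pd.DataFrame]:
    """Landscape + community in one call; returns (table, truth, landscape)."""
    landscape = generate_landscape(config)
    table, truth = generate_community(config, landscape)
    return table, truth, landscape


def k_recovery(
    table: InventoryTable,
    truth: pd.DataFrame,
    habitat: str = "terra_firme",
    min_occupied: int = 20,
    min_mean: float = 2.0,
    modal_area: float = 0.1,
) -> tuple[float, int]:
    """Spearman correlation between estimated and generating clumping k.

    The estimate uses raw counts in occupied plots of the modal area only:
    the generating k parameterizes count dispersion where the species is
    present, so zero-inclusive or area-rescaled estimates (which mostly
    reflect occupancy and rounding) are not comparable to it. Species need
    ``min_occupied`` occupied plots with mean count >= ``min_mean`` for the
    dispersion to be identifiable.
    """
    from scipy import stats as _st

    from . import aggregation as agg
    from . import dominance as dom

    m = dom.relative_abundances(table, habitat)
    areas = table.plots.loc[m.plot_ids, "area_ha"].to_numpy()
    sel = np.isclose(areas, modal_area)
    rows = []
    for i, s in enumerate(m.species):
        pos = m.counts[sel, i]
        pos = pos[pos > 0]
        if len(pos) >= min_occupied and pos.mean() >= min_mean:
            rows.append({"species": s, "k_hat": agg.estimate_k(pos, species=s).k})
    d = pd.DataFrame(rows).merge(
        truth[truth["habitat"] == habitat][["species", "k_true"]], on="species"
    )
    d = d[d["k_hat"] < 1e5]
    if len(d) < 5:
        return float("nan"), len(d)
    rho, _ = _st.spearmanr(d["k_hat"], d["k_true"])
    return float(rho), int(len(d))


def truth_recovery_report(
    dom_results: list,
    ks: pd.DataFrame,
    truth: pd.DataFrame,
    table: InventoryTable | None = None,
    fitted_slopes: dict | None = None,
    rho_configured: float | None = None,
) -> dict:
    """Compare pipeline outputs against generating parameters.

    Reports Spearman correlation between estimated and true k, the fraction
    of planted oligarchs landing in the high-high quartile corner (classes
    11/12/15/16), and per-habitat agreement between the fitted
    abundance-frequency slope sign and the configured trade-off sign.
    """
    out = {}
    dom_tables = pd.concat(
        [r.table.assign(habitat=r.habitat) for r in dom_results], ignore_index=True
    )
    merged = ks.merge(truth, on=["habitat", "species"], how="inner") if len(ks) else pd.DataFrame()
    if len(merged):
        kvals = merged["k"].astype(float)
        finite = merged[(kvals < 1e5) & np.isfinite(kvals)]
    else:
        finite = merged
    if len(finite) >= 5:
        rho_k, _ = stats.spearmanr(finite["k"], finite["k_true"])
        out["spearman_k_pipeline"] = float(rho_k)
        out["n_k"] = int(len(finite))
    if table is not None:
        rho_c, n_c = k_recovery(table, truth)
        out["spearman_k_conditional"] = rho_c
        out["n_k_conditional"] = n_c
    classed = dom_tables.dropna(subset=["quartile_class"]).merge(
        truth[["habitat", "species", "archetype"]], on=["habitat", "species"], how="left"
    )
    olig = classed[classed["archetype"] == "oligarch"]
    if len(olig):
        out["oligarch_corner_rate"] = float(olig["quartile_class"].isin([11, 12, 15, 16]).mean())
        out["n_oligarchs_classified"] = int(len(olig))
    if fitted_slopes is not None and rho_configured is not None:
        want = np.sign(rho_configured)
        agree = {h: bool(np.sign(s) == want) for h, s in fitted_slopes.items() if np.isfinite(s)}
        out["slope_sign_agreement"] = agree
        out["slope_sign_agreement_rate"] = float(np.mean(list(agree.values()))) if agree else np.nan
    return out
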