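"""Spatial aggregation: negative-binomial clumping and co-dominance decay.

Two complementary views of how clumped a species is:

* At the plot grain, counts standardized to the smallest plot area in the
  habitat are fitted with a negative binomial; the dispersion parameter k
  measures clumping (small k = strongly aggregated, k -> infinity recovers
  the Poisson, i.e. spatial randomness).
* Across the study extent, the co-dominance index
  F_i,jk = (n_ij * n_ik) / (N_j * N_k) — the probability that one
  individual drawn from each of two plots both belong to species i — is
  related to the pair's geographic distance, smoothed with a data-driven
  span local-linear smoother, and relativized across species so curves sum
  to 1 at every distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import betareg
from . import dominance as dom
from .geo import pairwise_km
from .io import InventoryTable

K_POISSON_CAP = 1e6


@dataclass
class StandardizedCounts:
    habitat: str
    min_area: float
    plot_ids: list
    species: list
    counts: np.ndarray  # integer, plots x species, rescaled to min_area


@dataclass
class KEstimate:
    species: str
    k: float
    mean: float
    estimator: str  # "ml" | "moment" | "poisson_cap"
    converged: bool


@dataclass
class CodominanceCurves:
    """Smoothed F(distance) per species on a shared grid, plus relativized values."""

    habitat: str
    distance_km: np.ndarray
    F_abs: pd.DataFrame  # rows = grid distances, columns = species
    F_rel: pd.DataFrame | None = None

    def to_long(self) -> pd.DataFrame:
        out = self.F_abs.copy()
        out.index.name = "distance_km"
        long = out.reset_index().melt(id_vars="distance_km", var_name="species", value_name="F_abs")
        if self.F_rel is not None:
            rel = (
                self.F_rel.rename_axis("distance_km")
                .reset_index()
                .melt(id_vars="distance_km", var_name="species", value_name="F_rel")
            )
            long = long.merge(rel, on=["distance_km", "species"])
        long.insert(0, "habitat", self.habitat)
        return long


def standardize_counts(table: InventoryTable, habitat: str) -> StandardizedCounts:
    """Rescale each plot's counts to the smallest plot area in the habitat.

    count' = round(n_ij * A_min / A_j), half-up rounding; counts can round
    to zero (the species is effectively absent at the min-area grain).
    """
    m = dom.relative_abundances(table, habitat)
    areas = table.plots.loc[m.plot_ids, "area_ha"].to_numpy(dtype=float)
    if np.any(areas <= 0):
        raise ValueError("non-positive plot area")
    a_min = float(areas.min())
    scaled = m.counts * (a_min / areas[:, None])
    counts = np.floor(scaled + 0.5).astype(np.int64)  # round half-up
    return StandardizedCounts(
        habitat=habitat, min_area=a_min, plot_ids=m.plot_ids, species=m.species, counts=counts
    )


def nb_loglik(counts: np.ndarray, mean: float, k: float) -> float:
    """Negative-binomial log-likelihood in the (mean, k) parameterisation."""
    x = np.asarray(counts)
    return float(
        np.sum(
            gammaln(x + k)
            - gammaln(k)
            - gammaln(x + 1)
            + k * np.log(k / (k + mean))
            + x * np.log(mean / (k + mean) + (mean == 0))
        )
    )


def estimate_k(counts: np.ndarray, species: str = "", include_zeros: bool = True) -> KEstimate:
    """ML estimate of the NB dispersion k from a vector of plot counts.

    Zeros count (aggregation is about absences too) unless
    ``include_zeros=False``. The NB mean MLE is the sample mean for any k,
    so the fit profiles the likelihood over log k, started at the moment
    estimator k = m^2/(s^2 - m). When the sample variance does not exceed
    the mean there is no evidence of clumping and k is capped at 1e6
    (Poisson limit).
    """
    x = np.asarray(counts, dtype=np.int64)
    if not include_zeros:
        x = x[x > 0]
    if len(x) < 5:
        raise ValueError("need at least 5 plots")
    if x.sum() == 0:
        raise ValueError("all-zero count vector: k undefined")
    m = float(x.mean())
    s2 = float(x.var(ddof=1))
    if s2 <= m:
        return KEstimate(species=species, k=K_POISSON_CAP, mean=m, estimator="poisson_cap", converged=True)

    k_mom = m * m / (s2 - m)
    res = minimize_scalar(
        lambda logk: -nb_loglik(x, m, np.exp(logk)),
        bounds=(np.log(1e-6), np.log(K_POISSON_CAP)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if res.success and np.isfinite(res.fun):
        k_hat = float(np.exp(res.x))
        if k_hat >= K_POISSON_CAP * 0.99:
            return KEstimate(species=species, k=K_POISSON_CAP, mean=m, estimator="poisson_cap", converged=True)
        return KEstimate(species=species, k=k_hat, mean=m, estimator="ml", converged=True)
    return KEstimate(species=species, k=float(k_mom), mean=m, estimator="moment", converged=False)


def k_for_dominants(
    table: InventoryTable,
    habitat: str,
    species: list[str] | None = None,
    include_zeros: bool = True,
) -> pd.DataFrame:
    """k estimates for (by default) all species of a habitat, standardized counts."""
    std = standardize_counts(table, habitat)
    cols = ["habitat", "species", "k", "mean", "estimator", "converged"]
    if len(std.plot_ids) < 5:  # dispersion unidentifiable
        return pd.DataFrame(columns=cols)
    idx = {s: i for i, s in enumerate(std.species)}
    if species is None:
        species = std.species
    rows = []
    for s in species:
        if s not in idx:
            continue
        col = std.counts[:, idx[s]]
        if col.sum() == 0 or (not include_zeros and (col > 0).sum() < 5):
            continue
        est = estimate_k(col, species=s, include_zeros=include_zeros)
        rows.append(
            {"habitat": habitat, "species": s, "k": est.k, "mean": est.mean,
             "estimator": est.estimator, "converged": est.converged}
        )
    return pd.DataFrame(rows, columns=cols)


def k_regressions(dom_results: list[dom.DominanceResult], ks: pd.DataFrame) -> dict:
    """Beta regressions of abundance and frequency on k x habitat.

    Two candidate sets (response = mean local abundance; response =
    regional frequency), each over {1, k, habitat, k+habitat, k*habitat},
    ranked by AIC. Also reports per-habitat simple-k slopes.
    """
    frames = []
    for r in dom_results:
        t = r.table[r.table["dominant"]][["species", "mean_local_abundance", "regional_frequency"]]
        t = t.assign(habitat=r.habitat)
        frames.append(t)
    data = pd.concat(frames, ignore_index=True).merge(ks, on=["habitat", "species"], how="inner")
    if data.empty:
        raise ValueError("no dominant species with a k estimate")
    out = {"data": data}
    one_habitat = data["habitat"].nunique() < 2
    for resp, label in [("mean_local_abundance", "abundance"), ("regional_frequency", "frequency")]:
        names = ["intercept", "x"] if one_habitat else list(betareg.CANDIDATE_FORMULAS)
        fits = [
            betareg.fit_beta_logit(betareg.CANDIDATE_FORMULAS[n].format(y=resp, x="k"), data, name=n)
            for n in names
        ]
        ranking = betareg.compare_models(fits)
        slopes = {}
        for h, sub in data.groupby("habitat"):
            if len(sub) >= 4:
                try:
                    f = betareg.fit_beta_logit(f"{resp} ~ k", sub, name=f"{label}~k|{h}")
                    slopes[h] = f.slope("k")
                except Exception:
                    slopes[h] = np.nan
        out[label] = {"fits": {f.name: f for f in fits}, "ranking": ranking, "per_habitat_slope": slopes}
    return out


def codominance_F(n_ij, n_ik, N_j, N_k):
    """F = (n_ij / N_j) * (n_ik / N_k): probability a random individual from
    each of two plots both belong to the focal species. Vectorized."""
    n_ij, n_ik = np.asarray(n_ij, float), np.asarray(n_ik, float)
    N_j, N_k = np.asarray(N_j, float), np.asarray(N_k, float)
    if np.any(N_j < 1) or np.any(N_k < 1):
        raise ValueError("plot totals must be >= 1")
    if np.any(n_ij > N_j) or np.any(n_ik > N_k) or np.any(n_ij < 0) or np.any(n_ik < 0):
        raise ValueError("species counts must lie in [0, plot total]")
    return (n_ij / N_j) * (n_ik / N_k)


def pairwise_distances(plots: pd.DataFrame) -> np.ndarray:
    """Great-circle distance matrix (km) between plots (rows of metadata)."""
    return pairwise_km(plots["lat"].to_numpy(), plots["lon"].to_numpy())


def _cv_span(x: np.ndarray, y: np.ndarray, spans, rng: np.random.Generator, max_cv_n: int = 4000) -> float:
    """Pick a lowess span by 5-fold cross-validated squared error."""
    n = len(x)
    if n > max_cv_n:
        idx = rng.choice(n, max_cv_n, replace=False)
        x, y = x[idx], y[idx]
        n = max_cv_n
    folds = rng.permutation(n) % 5
    best, best_err = spans[0], np.inf
    for frac in spans:
        err = 0.0
        ok = True
        for f in range(5):
            tr, te = folds != f, folds == f
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = lowess(y[tr], x[tr], frac=frac, it=0, delta=0.01 * np.ptp(x[tr]), return_sorted=True)
            if not np.all(np.isfinite(fit[:, 1])):
                ok = False
                break
            pred = np.interp(x[te], fit[:, 0], fit[:, 1])
            err += float(np.sum((y[te] - pred) ** 2))
        if ok and err < best_err:
            best, best_err = frac, err
    return best


def aggregation_curves(
    m: dom.AbundanceMatrix,
    distances: np.ndarray,
    species: list[str] | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    include_zero_pairs: bool = True,
    spans=(0.2, 0.35, 0.5, 0.75),
    seed: int = 0,
) -> CodominanceCurves:
    """Smoothed F(distance) per species over all plot pairs of a habitat.

    For every unordered plot pair the co-dominance F is computed (zeros
    included by default: pairs where the species is absent carry real
    information about range limits) and smoothed against pair distance with
    a cross-validated-span local-linear smoother, evaluated on a common
    grid spanning the 1st-99th percentile of pair distances. Negative
    smoothed values are floored at 0. With fewer than 10 pairs, unsmoothed
    binned means are returned with a warning.
    """
    if m.n_plots < 2:
        raise ValueError("need at least 2 plots")
    rng = np.random.default_rng(seed)
    if species is None:
        species = m.species
    iu, ju = np.triu_indices(m.n_plots, k=1)
    dist = np.asarray(distances)[iu, ju]
    totals = m.counts.sum(axis=1)
    if grid is None:
        lo, hi = np.percentile(dist, [1, 99])
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)

    idx = {s: i for i, s in enumerate(m.species)}
    curves = {}
    few_pairs = len(dist) < 10
    if few_pairs:
        warnings.warn("fewer than 10 plot pairs: returning binned means, no smoothing")
    for s in species:
        col = m.counts[:, idx[s]]
        F = codominance_F(col[iu], col[ju], totals[iu], totals[ju])
        if not include_zero_pairs:
            keep = (col[iu] > 0) | (col[ju] > 0)
            Fd, dd = F[keep], dist[keep]
        else:
            Fd, dd = F, dist
        if len(Fd) == 0:
            curves[s] = np.zeros_like(grid)
            continue
        if few_pairs or len(np.unique(dd)) < 5:
            edges = np.linspace(dd.min(), dd.max() + 1e-9, min(6, len(grid)))
            which = np.clip(np.digitize(dd, edges) - 1, 0, len(edges) - 2)
            means = np.array([Fd[which == b].mean() if np.any(which == b) else 0.0
                              for b in range(len(edges) - 1)])
            centers = 0.5 * (edges[:-1] + edges[1:])
            fitted = np.interp(grid, centers, means)
        else:
            if np.ptp(Fd) == 0:
                fitted = np.full_like(grid, Fd[0])  # constant preserved exactly
            else:
                frac = _cv_span(dd, Fd, spans, rng)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fitted = lowess(Fd, dd, frac=frac, it=0, xvals=grid)
                if not np.all(np.isfinite(fitted)):  # CV-degenerate: fixed-span fallback
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fitted = lowess(Fd, dd, frac=0.3, it=0, xvals=grid)
        curves[s] = np.maximum(np.nan_to_num(fitted, nan=0.0), 0.0)

    F_abs = pd.DataFrame(curves, index=grid)
    return CodominanceCurves(habitat=m.habitat, distance_km=grid, F_abs=F_abs)


def relativize_curves(curves: CodominanceCurves) -> CodominanceCurves:
    """F_rel(d) = F_abs(d) / sum_species F_abs(d); rows sum to 1 exactly.

    Grid distances where every species' smoothed F is zero are masked (NaN).
    """
    total = curves.F_abs.sum(axis=1)
    rel = curves.F_abs.div(total.where(total > 0), axis=0)
    return CodominanceCurves(
        habitat=curves.habitat, distance_km=curves.distance_km, F_abs=curves.F_abs, F_rel=rel
    )
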