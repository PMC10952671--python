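"""Beta regression with a logit link, AIC model comparison, slope sweeps.

Bounded responses (mean local abundance, regional frequency, both in (0,1])
are modelled as Beta(mu*phi, (1-mu)*phi) with logit(mu) = X beta and a
single precision phi estimated by maximum likelihood. Fitting is delegated
to :class:`statsmodels.othermod.betareg.BetaModel`; this module owns the
response boundary handling, the candidate-set bookkeeping, the AIC support
rule (delta AIC > 2 means no support) and the sequential-threshold
slope-sign sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.othermod.betareg import BetaModel

from . import dominance as dom

#: Candidate mean-submodel formulas for a response on one continuous
#: predictor ``x`` and the habitat factor, from intercept-only up to the
#: full interaction.
CANDIDATE_FORMULAS = {
    "intercept": "{y} ~ 1",
    "x": "{y} ~ {x}",
    "habitat": "{y} ~ habitat",
    "additive": "{y} ~ {x} + habitat",
    "interaction": "{y} ~ {x} * habitat",
}

AIC_SUPPORT_DELTA = 2.0


def squeeze_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Compress [0, 1] responses into (0, 1): y' = (y*(n-1) + 0.5) / n.

    Applied only when boundary values are present; interior values move by
    at most 1/(2n). Mean local abundance can be exactly 1 for monodominant
    single-plot species, which makes this necessary.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("response outside [0, 1]")
    if n is None:
        n = len(y)
    if np.any((y <= 0) | (y >= 1)):
        y = (y * (n - 1) + 0.5) / n
    return y


@dataclass
class ModelFit:
    """A fitted beta-logit model plus the scalars used for comparison."""

    name: str
    formula: str
    params: pd.Series
    bse: pd.Series
    phi: float
    loglik: float
    aic: float
    nobs: int
    converged: bool
    result: object = field(repr=False, default=None)
    response_key: tuple = field(repr=False, default=None)

    def slope(self, term: str) -> float:
        return float(self.params[term])

    def slope_se(self, term: str) -> float:
        return float(self.bse[term])


def fit_beta_logit(formula: str, data: pd.DataFrame, name: str | None = None) -> ModelFit:
    """ML fit of a beta regression (logit mean link, constant precision).

    The response named on the left of ``formula`` is boundary-compressed
    first if it touches 0 or 1. Non-convergence is flagged, not raised.
    """
    data = data.copy()
    yname = formula.split("~")[0].strip()
    y = data[yname].to_numpy(dtype=float)
    if len(data) == 0:
        raise ValueError("empty data")
    data[yname] = squeeze_unit_interval(y)
    model = BetaModel.from_formula(formula, data)
    with np.errstate(all="ignore"):
        res = model.fit(disp=False)
    k_mean = len(res.params) - 1  # last parameter is log-precision
    params = res.params.iloc[:k_mean]
    bse = res.bse.iloc[:k_mean]
    phi = float(np.exp(res.params.iloc[-1]))
    fit = ModelFit(
        name=name or formula,
        formula=formula,
        params=params,
        bse=bse,
        phi=phi,
        loglik=float(res.llf),
        aic=float(res.aic),
        nobs=int(res.nobs),
        converged=bool(res.mle_retvals.get("converged", True)),
        result=res,
        response_key=(yname, len(data), round(float(np.sum(data[yname])), 12)),
    )
    return fit


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits by AIC; flag models with delta AIC > 2 as unsupported."""
    if not fits:
        raise ValueError("no fits to compare")
    keys = {f.response_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits are not on an identical response vector")
    df = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "formula": [f.formula for f in fits],
            "k_params": [len(f.params) + 1 for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values("aic", kind="mergesort").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["supported"] = df["delta_aic"] <= AIC_SUPPORT_DELTA
    return df


def _pooled_dominant_table(results: list[dom.DominanceResult], min_per_habitat: int = 3) -> pd.DataFrame:
    frames = []
    for r in results:
        t = r.table[r.table["dominant"]]
        if len(t) < min_per_habitat:
            import warnings

            warnings.warn(f"habitat {r.habitat}: <{min_per_habitat} dominants, excluded from model")
            continue
        frames.append(t.assign(habitat=r.habitat))
    if not frames:
        raise ValueError("no habitat has enough dominant species to model")
    return pd.concat(frames, ignore_index=True)


def abundance_frequency_model(
    results: list[dom.DominanceResult],
    x: str = "regional_frequency",
    y: str = "mean_local_abundance",
    n_grid: int = 50,
) -> dict:
    """Fit the candidate set for abundance ~ frequency x habitat, pick by AIC.

    Pools dominant species across habitats with a habitat factor; fits
    {intercept, x, habitat, additive, interaction}, selects the lowest-AIC
    model, and emits per-habitat prediction curves with 95% delta-method
    confidence bands over each habitat's observed frequency range.
    """
    data = _pooled_dominant_table(results)
    one_habitat = data["habitat"].nunique() < 2
    names = ["intercept", "x"] if one_habitat else list(CANDIDATE_FORMULAS)
    fits = [
        fit_beta_logit(CANDIDATE_FORMULAS[n].format(y=y, x=x), data, name=n) for n in names
    ]
    ranking = compare_models(fits)
    best = next(f for f in fits if f.name == ranking["model"].iloc[0])

    grids = []
    for h, sub in data.groupby("habitat"):
        g = pd.DataFrame(
            {x: np.linspace(sub[x].min(), sub[x].max(), n_grid), "habitat": h, y: 0.5}
        )
        eta, lo, hi = _predict_eta_ci(best, g)
        g["fit"] = expit(eta)
        g["lo"] = expit(lo)
        g["hi"] = expit(hi)
        grids.append(g.drop(columns=[y]))
    return {
        "data": data,
        "fits": {f.name: f for f in fits},
        "ranking": ranking,
        "best": best,
        "predictions": pd.concat(grids, ignore_index=True),
    }


def _predict_eta_ci(fit: ModelFit, newdata: pd.DataFrame, z: float = 1.96):
    """Delta-method CI on the linear predictor of the mean submodel."""
    from patsy import dmatrix

    design_info = fit.result.model.data.design_info
    X = np.asarray(dmatrix(design_info, newdata, return_type="matrix"))
    beta = fit.params.to_numpy()
    eta = X @ beta
    try:
        cov = np.asarray(fit.result.cov_params())[: len(beta), : len(beta)]
        se = np.sqrt(np.abs(np.einsum("ij,jk,ik->i", X, cov, X)))
    except (ValueError, np.linalg.LinAlgError):  # singular Hessian: no bands
        se = np.full(len(eta), np.nan)
    return eta, eta - z * se, eta + z * se


def per_habitat_slopes(fit: ModelFit, x: str, habitats: list[str]) -> dict[str, float]:
    """Per-habitat slope of the linear predictor in ``x`` implied by a fit.

    With no interaction term every habitat shares the main-effect slope;
    with an interaction, the reference level keeps the main effect and the
    others add their interaction coefficient.
    """
    base = float(fit.params.get(x, 0.0))
    out = {}
    for h in habitats:
        extra = 0.0
        for name in (f"{x}:habitat[T.{h}]", f"habitat[T.{h}]:{x}"):
            if name in fit.params.index:
                extra = float(fit.params[name])
        out[h] = base + extra
    return out


@dataclass
class SlopeTrajectory:
    """Frequency-slope sign across an ascending threshold sweep (one habitat)."""

    habitat: str
    table: pd.DataFrame  # threshold, n_species, slope, se, sign
    first_positive: float | None

    def sign_at(self, threshold: float) -> str:
        row = self.table[np.isclose(self.table["threshold"], threshold)]
        return row["sign"].iloc[0] if len(row) else "?"


def slope_sign_trajectory(
    m: dom.AbundanceMatrix, thresholds=dom.SEQUENTIAL_THRESHOLDS
) -> SlopeTrajectory:
    """Refit abundance ~ frequency on each threshold's species set.

    For each cumulative-abundance threshold, the species accounting for that
    share of total relative abundance are kept and the beta-logit slope of
    mean local abundance on regional frequency is recorded; the trajectory
    reports the first threshold at which the slope turns positive. Fit
    failures become gaps (sign "?"), never aborts.
    """
    sets = dom.sequential_dominance(m, thresholds)
    summ = dom.species_summaries(m).set_index("species")
    rows = []
    for t, species in sets.items():
        sub = summ.loc[species].reset_index()
        rec = {"threshold": t, "n_species": len(sub), "slope": np.nan, "se": np.nan, "sign": "?"}
        if len(sub) >= 4:
            try:
                fit = fit_beta_logit(
                    "mean_local_abundance ~ regional_frequency", sub, name=f"t{t}"
                )
                rec["slope"] = fit.slope("regional_frequency")
                rec["se"] = fit.slope_se("regional_frequency")
                if np.isfinite(rec["slope"]):
                    rec["sign"] = "+" if rec["slope"] > 0 else ("-" if rec["slope"] < 0 else "0")
            except Exception:
                pass
        rows.append(rec)
    table = pd.DataFrame(rows)
    pos = table.loc[table["sign"] == "+", "threshold"]
    return SlopeTrajectory(
        habitat=m.habitat, table=table, first_positive=float(pos.iloc[0]) if len(pos) else None
    )
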